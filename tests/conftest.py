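import warnings

import numpy as np
import pytest

import phenotrace as pt
from phenotrace.synthetic import panel_from_simulation


@pytest.fixture(autouse=True)
def _quiet_small_panel_warning():
    # many unit fixtures use deliberately small panels; the low-M estimation
    # warning is itself tested explicitly in test_traitcorr
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="trait correlation estimated from only"
        )
        yield


@pytest.fixture(scope="session")
def sim8():
    """K=8 panel with two well-separated planted loci (>1 Mb apart)."""
    cfg = pt.SimulationConfig(
        seed=42,
        n_individuals=2000,
        n_variants=1500,
        n_traits=8,
        maf_range=(0.2, 0.5),
        trait_corr=0.4,
        planted=(
            pt.PlantedEffect(150, (0, 1, 2), (0.3, 0.3, 0.3)),
            pt.PlantedEffect(1100, (4, 5), (0.35, 0.35)),
        ),
    )
    return pt.simulate(cfg)


@pytest.fixture(scope="session")
def panel8(sim8):
    return panel_from_simulation(sim8)


@pytest.fixture(scope="session")
def corr8(panel8):
    return pt.estimate_trait_corr(panel8)


@pytest.fixture(scope="session")
def null_panel():
    """Pure-noise panel for calibration-style checks."""
    cfg = pt.SimulationConfig(
        seed=7, n_individuals=2000, n_variants=2000, n_traits=5,
        trait_corr=0.4,
    )
    return panel_from_simulation(pt.simulate(cfg))


@pytest.fixture(scope="session")
def null_corr(null_panel):
    return pt.estimate_trait_corr(null_panel)
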