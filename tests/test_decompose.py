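"""Trace building, driver/optimal/central extraction."""
import itertools
import logging
import math

import numpy as np
import pytest

import phenotrace as pt
from phenotrace.assoc import SubsetAssociation, subset_association
from phenotrace.decompose import (
    SubsetScorer,
    build_traces,
    central_traits,
    decompose_variant,
    exhaustive_minimum_bic,
    find_drivers,
    find_optimal,
)
from phenotrace.sumstats import VariantKey
from phenotrace.synthetic import panel_from_simulation
from phenotrace.traitcorr import condition_psd, estimate_trait_corr

THR_NLP = -math.log10(5e-8)


def _fake_step(trace, idx, subset, dropped, nlp, bic=0.0):
    from phenotrace.decompose import TraceStep

    a = SubsetAssociation(
        variant=VariantKey("rsX", "1", 100, "A", "G"),
        traits=tuple(subset), r1=0.1, r_squared=0.01,
        neg_log10_p=nlp, bic=bic, n_used=2000,
    )
    return TraceStep(trace, idx, tuple(subset), dropped, a)


@pytest.fixture(scope="module")
def panel5():
    cfg = pt.SimulationConfig(
        seed=77, n_individuals=2000, n_variants=1200, n_traits=5,
        maf_range=(0.2, 0.5), trait_corr=0.4,
        planted=(pt.PlantedEffect(600, (0, 1), (0.3, 0.3)),),
    )
    return panel_from_simulation(pt.simulate(cfg))


@pytest.fixture(scope="module")
def corr5(panel5):
    return estimate_trait_corr(panel5)


class TestTraces:
    def test_k2_enumerates_three_subsets(self):
        cfg = pt.SimulationConfig(seed=5, n_variants=1200, n_traits=2,
                                  trait_corr=0.3)
        panel = panel_from_simulation(pt.simulate(cfg))
        S = estimate_trait_corr(panel)
        scorer = SubsetScorer(panel, 0, S)
        hi, lo, inv = build_traces(panel, 0, S, scorer=scorer)
        assert [len(s.subset) for s in hi] == [2, 1]
        assert [len(s.subset) for s in lo] == [2, 1]
        assert [len(s.subset) for s in inv] == [1]
        # evaluated: full model + both singletons (shared across traces)
        assert scorer.evaluations == 3

    def test_kept_subsets_are_bruteforce_optima(self, panel5, corr5):
        """Each greedy step matches exhaustive arg-max/arg-min."""
        for i in (600, 17, 893):
            hi, lo, _ = build_traces(panel5, i, corr5)
            for steps, pick in ((hi, max), (lo, min)):
                current = steps[0].subset
                for step in steps[1:]:
                    cand = {
                        sub: subset_association(panel5, i, sub, corr5).r1
                        for sub in itertools.combinations(current, len(current) - 1)
                    }
                    best = pick(cand.values())
                    assert cand[tuple(step.subset)] == pytest.approx(best, abs=1e-15)
                    current = step.subset

    def test_inverted_trace_aggregates_lowest_drops(self, panel5, corr5):
        _, lo, inv = build_traces(panel5, 600, corr5)
        dropped = [s.dropped_trait for s in lo[1:]]
        for t, step in enumerate(inv, start=1):
            assert set(step.subset) == set(dropped[:t])

    def test_evaluation_count_bounded_by_k_squared(self, panel8, corr8):
        k = panel8.n_traits
        scorer = SubsetScorer(panel8, 150, corr8)
        build_traces(panel8, 150, corr8, scorer=scorer)
        assert k * (k + 1) // 2 <= scorer.evaluations <= k * k + k

    def test_duplicate_trait_dropped_first_with_no_r2_loss(self):
        """A perfectly replaceable (duplicated) trait goes first on the
        highest trace, at essentially zero cost in R^2."""
        cfg = pt.SimulationConfig(
            seed=9, n_individuals=2000, n_variants=1200, n_traits=6,
            maf_range=(0.2, 0.5), trait_corr=0.3,
            planted=(pt.PlantedEffect(600, (0, 1), (0.3, 0.3)),),
        )
        sim = pt.simulate(cfg)
        sim.traits[:, 5] = sim.traits[:, 0]  # T6 becomes a copy of T1
        panel = panel_from_simulation(sim)
        S = condition_psd(estimate_trait_corr(panel),
                          eigen_floor=1e-8, shrink_step=0.9999999)
        hi, _, _ = build_traces(panel, 600, S)
        assert hi[1].dropped_trait in {"T1", "T6"}
        assert abs(hi[1].assoc.r_squared - hi[0].assoc.r_squared) < 1e-6


class TestDrivers:
    def test_walks_until_first_nonsignificant_step(self):
        # full model P = 1e-13; dropping CE14 -> 3e-9 (still significant);
        # then PCO23 -> 1.8e-6 (not significant): both are drivers
        traits = ("CE14", "PCO23", "PC36", "PI9")
        lo = [
            _fake_step("lowest", 0, traits, None, 13.0),
            _fake_step("lowest", 1, traits[1:], "CE14", -math.log10(3e-9)),
            _fake_step("lowest", 2, traits[2:], "PCO23", -math.log10(1.8e-6)),
            _fake_step("lowest", 3, traits[3:], "PC36", 1.0),
        ]
        drivers, pwo = find_drivers(lo, threshold=5e-8)
        assert drivers == ("CE14", "PCO23")
        assert pwo == pytest.approx(-math.log10(1.8e-6))

    def test_significance_to_singleton_means_all_drivers(self):
        traits = ("A", "B", "C")
        lo = [
            _fake_step("lowest", 0, traits, None, 50.0),
            _fake_step("lowest", 1, ("B", "C"), "A", 30.0),
            _fake_step("lowest", 2, ("C",), "B", 20.0),
        ]
        drivers, pwo = find_drivers(lo, threshold=5e-8)
        assert set(drivers) == {"A", "B", "C"}
        assert pwo is None

    def test_nonsignificant_full_model_gives_empty_drivers(self, caplog):
        lo = [
            _fake_step("lowest", 0, ("A", "B"), None, 2.0),
            _fake_step("lowest", 1, ("B",), "A", 1.0),
        ]
        with caplog.at_level(logging.WARNING):
            drivers, pwo = find_drivers(lo, threshold=5e-8)
        assert drivers == () and pwo is None
        assert "not genome-wide significant" in caplog.text


class TestOptimal:
    def test_null_variant_prefers_single_trait(self, null_panel, null_corr):
        res = decompose_variant(null_panel, 123, null_corr)
        assert len(res.optimal_set) == 1

    def test_trace_pool_close_to_global_minimum(self, panel5, corr5):
        """The trace candidate pool usually contains the exhaustive optimum."""
        agree = 0
        checked = 10
        for i in range(0, 1200, 1200 // checked):
            scorer = SubsetScorer(panel5, i, corr5)
            hi, lo, inv = build_traces(panel5, i, corr5, scorer=scorer)
            opt_set, opt_bic, _ = find_optimal(hi, inv, hi[0].assoc)
            exh_set, exh_bic = exhaustive_minimum_bic(scorer)
            assert opt_bic >= exh_bic - 1e-9
            agree += set(opt_set) == set(exh_set)
        assert agree >= int(0.8 * checked)

    def test_tie_breaks_prefer_smaller_then_lexicographic(self):
        mk = lambda subset, bic: _fake_step("highest", 0, subset, None, 1.0, bic)
        hi = [mk(("A", "B"), 5.0), mk(("B",), 5.0)]
        inv = [mk(("C",), 5.0)]
        opt_set, _, _ = find_optimal(hi, inv)
        assert opt_set == ("B",)  # smallest size, then lexicographic


class TestDecomposition:
    def test_central_is_union(self):
        assert central_traits(("CE14", "PCO23"), ("CE14", "PC36", "PCO23")) == (
            "CE14", "PC36", "PCO23",
        )
        assert central_traits((), ("A",)) == ("A",)
        assert central_traits(("A",), ("A",)) == ("A",)

    def test_planted_variant_decomposition(self, panel8, corr8):
        res = decompose_variant(panel8, panel8.variant_index("rs151"), corr8)
        assert set(res.drivers) <= set(res.central)
        assert set(res.optimal_set) <= set(res.central)
        assert set(res.central) == set(res.drivers) | set(res.optimal_set)
        # drop ranks are a bijection onto 1..K
        assert sorted(res.drop_rank.values()) == list(range(1, 9))
        # the planted traits carry the signal: first lowest-trace drop is one
        assert res.lowest_trace[1].dropped_trait in {"T1", "T2", "T3"}

    def test_trace_r2_nonincreasing_on_highest(self, panel8, corr8):
        res = decompose_variant(panel8, panel8.variant_index("rs1101"), corr8)
        r2 = [s.assoc.r_squared for s in res.highest_trace]
        assert all(b <= a + 1e-8 for a, b in zip(r2, r2[1:]))
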