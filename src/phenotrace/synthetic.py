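"""Synthetic genotype/trait simulator and individual-level test oracle.

Emulates the input contract of the pipeline: individual-level genotypes
(independent biallelic variants, dosages ~ Binomial(2, maf)) and K
correlated quantitative traits (multivariate normal noise plus optional
planted per-allele effects on chosen trait subsets), reduced per trait to
the univariate simple-regression summary statistics the pipeline consumes.

It also exposes direct individual-level computations (OLS R^2, first
canonical correlation, maximized-likelihood BIC, F-test P) that serve as
the independent ground truth against which the summary-statistic engine is
validated.  Linkage disequilibrium, population structure and binary traits
are deliberately out of scope: the association engine is a single-variant
method and inherits none of them.
"""
from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import assoc
from .sumstats import DEFAULT_COLUMNS, harmonize, read_sumstats

log = logging.getLogger(__name__)

_VARIANT_BLOCK = 2048  # summary-stat computation block (memory bound)


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedEffect:
    """Per-allele effects (in trait-SD units) of one variant on a trait subset."""

    variant_index: int
    trait_indices: tuple[int, ...]
    betas: tuple[float, ...]

    def __post_init__(self):
        if len(self.trait_indices) != len(self.betas):
            raise SimulationError("one beta per planted trait required")
        if not all(np.isfinite(self.betas)):
            raise SimulationError("planted effects must be finite")


@dataclass
class SimulationConfig:
    """Study conditions for one simulated data set.

    Defaults mirror a small lipidomics-style cohort: a few thousand
    individuals, a handful of correlated traits with exchangeable
    correlation, and common variants.
    """

    seed: int
    n_individuals: int = 2000
    n_variants: int = 5000
    n_traits: int = 8
    maf_range: tuple[float, float] = (0.05, 0.5)
    trait_corr: float | np.ndarray = 0.4
    planted: tuple[PlantedEffect, ...] = ()
    missing_rate: float = 0.0
    bp_spacing: int = 5000
    chrom: str = "1"

    def __post_init__(self):
        if self.seed is None:
            raise SimulationError("a seed is mandatory")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise SimulationError("maf_range must lie within (0, 0.5]")
        if not (0 <= self.missing_rate < 1):
            raise SimulationError("missing_rate must lie in [0, 1)")
        for pe in self.planted:
            if not 0 <= pe.variant_index < self.n_variants:
                raise SimulationError("planted variant index out of range")
            if any(j < 0 or j >= self.n_traits for j in pe.trait_indices):
                raise SimulationError("planted trait index out of range")
        np.linalg.cholesky(self.corr_matrix())  # raises if not PD

    @property
    def trait_names(self) -> list[str]:
        return [f"T{j + 1}" for j in range(self.n_traits)]

    def corr_matrix(self) -> np.ndarray:
        if np.isscalar(self.trait_corr):
            rho = float(self.trait_corr)
            c = np.full((self.n_traits, self.n_traits), rho)
            np.fill_diagonal(c, 1.0)
            return c
        c = np.asarray(self.trait_corr, dtype=float)
        if c.shape != (self.n_traits, self.n_traits):
            raise SimulationError("trait_corr shape must be K x K")
        return c


@dataclass
class SimulatedData:
    config: SimulationConfig
    genotypes: np.ndarray  # n x M dosages (int8)
    traits: np.ndarray  # n x K (NaN where masked missing)
    mafs: np.ndarray
    variant_table: pd.DataFrame  # id chrom pos ea oa
    truth: dict


def simulate(config: SimulationConfig) -> SimulatedData:
    """Draw genotypes and correlated traits with planted effects.

    Bit-identical for identical configs: all randomness flows through one
    seeded generator.
    """
    rng = np.random.default_rng(config.seed)
    n, m, k = config.n_individuals, config.n_variants, config.n_traits
    mafs = rng.uniform(*config.maf_range, size=m)
    G = rng.binomial(2, mafs, size=(n, m)).astype(np.int8)
    L = np.linalg.cholesky(config.corr_matrix())
    Y = rng.standard_normal((n, k)) @ L.T
    for pe in config.planted:
        g = G[:, pe.variant_index].astype(float)
        for j, b in zip(pe.trait_indices, pe.betas):
            Y[:, j] += b * g
    if config.missing_rate > 0:
        Y[rng.random((n, k)) < config.missing_rate] = np.nan

    names = config.trait_names
    variant_table = pd.DataFrame(
        {
            "id": [f"rs{i + 1}" for i in range(m)],
            "chrom": config.chrom,
            "pos": (np.arange(m, dtype=np.int64) + 1) * config.bp_spacing,
            "ea": "A",
            "oa": "G",
        }
    )
    truth = {
        "seed": config.seed,
        "n_individuals": n,
        "trait_names": names,
        "planted": [
            {
                "variant": variant_table["id"].iloc[pe.variant_index],
                "variant_index": pe.variant_index,
                "traits": [names[j] for j in pe.trait_indices],
                "betas": list(pe.betas),
            }
            for pe in config.planted
        ],
    }
    return SimulatedData(config, G, Y, mafs, variant_table, truth)


def summarize(
    genotypes: np.ndarray,
    traits: np.ndarray,
    variant_table: pd.DataFrame,
    trait_names: list[str],
) -> dict[str, pd.DataFrame]:
    """Univariate simple-regression GWAS per trait.

    For every (variant, trait) pair, the slope and standard error of the
    OLS regression of trait on dosage (intercept fitted, residual df
    n - 2) and the number of non-missing individuals.  Monomorphic
    variants, whose slope is undefined, are dropped with a log notice.
    Output tables use the :func:`read_sumstats` schema.
    """
    n, m = genotypes.shape
    out = {}
    for j, trait in enumerate(trait_names):
        y = traits[:, j]
        mask = np.isfinite(y)
        nj = int(mask.sum())
        if nj < 3:
            raise SimulationError(f"trait {trait}: fewer than 3 observations")
        yv = y[mask]
        yc = yv - yv.mean()
        syy = float(yc @ yc)
        beta = np.empty(m)
        sxx_all = np.empty(m)
        for a in range(0, m, _VARIANT_BLOCK):
            b = min(a + _VARIANT_BLOCK, m)
            g = genotypes[mask, a:b].astype(np.float64)
            gm = g.mean(axis=0)
            sxx = np.einsum("ij,ij->j", g, g) - nj * gm * gm
            sxy = yc @ g
            with np.errstate(divide="ignore", invalid="ignore"):
                beta[a:b] = sxy / sxx
            sxx_all[a:b] = sxx
        with np.errstate(divide="ignore", invalid="ignore"):
            sse = syy - beta * beta * sxx_all
            se = np.sqrt(np.maximum(sse, 0.0) / (nj - 2) / sxx_all)
        ok = np.isfinite(beta) & np.isfinite(se) & (se > 0)
        dropped = int((~ok).sum())
        if dropped:
            log.info("trait %s: %d variants dropped (undefined regression)",
                     trait, dropped)
        tab = variant_table.loc[ok, ["id", "chrom", "pos", "ea", "oa"]].copy()
        tab["beta"] = beta[ok]
        tab["se"] = se[ok]
        tab["n"] = float(nj)
        out[trait] = tab.reset_index(drop=True)
    return out


def panel_from_simulation(sim: SimulatedData):
    """Convenience: simulate -> summarise -> harmonised panel."""
    tables = summarize(sim.genotypes, sim.traits, sim.variant_table,
                       sim.config.trait_names)
    panel, _ = harmonize(tables)
    return panel


def write_sumstats(tables: dict[str, pd.DataFrame], out_dir) -> dict[str, str]:
    """Write per-trait files in the default input dialect; returns paths."""
    os.makedirs(out_dir, exist_ok=True)
    rename = {k: v for k, v in DEFAULT_COLUMNS.items()}
    paths = {}
    for trait, tab in tables.items():
        path = os.path.join(out_dir, f"{trait}.sumstats.tsv")
        tab.rename(columns=rename).to_csv(path, sep="\t", index=False,
                                          float_format="%.17g")
        paths[trait] = path
    return paths


def write_truth(sim: SimulatedData, out_dir) -> str:
    os.makedirs(out_dir, exist_ok=True)
    path = os.path.join(out_dir, "truth.json")
    with open(path, "w") as fh:
        json.dump(sim.truth, fh, indent=2)
    return path


def block_corr(block_sizes, rhos) -> np.ndarray:
    """Block-diagonal exchangeable correlation matrix.

    Each block of ``block_sizes[i]`` traits shares correlation ``rhos[i]``;
    traits in different blocks are uncorrelated.  Useful for identifiable
    planted scenarios where signal traits must not borrow information from
    null traits.
    """
    k = int(sum(block_sizes))
    c = np.eye(k)
    start = 0
    for size, rho in zip(block_sizes, rhos):
        c[start:start + size, start:start + size] = rho
        start += size
    np.fill_diagonal(c, 1.0)
    return c


# ---------------------------------------------------------------------------
# individual-level oracle


@dataclass(frozen=True)
class OracleStats:
    r_squared: float
    r1: float
    bic: float
    neg_log10_p: float
    n: int


def oracle_subset_stats(x: np.ndarray, Y: np.ndarray) -> OracleStats:
    """Ground-truth subset statistics from individual-level data.

    Regresses the mean-centered genotype on the mean-centered trait
    columns; R^2 comes from residual sums of squares, r1 = sqrt(R^2),
    BIC = k log n + n log(1 - R^2) (constant-aligned with the summary
    engine) and P from the F(k, n - k - 1) distribution.
    """
    x = np.asarray(x, dtype=float).ravel()
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    mask = np.isfinite(x) & np.all(np.isfinite(Y), axis=1)
    x, Y = x[mask], Y[mask]
    n, k = Y.shape
    if n <= k + 1:
        raise SimulationError("sample size too small for subset dimension")
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=0)
    if np.linalg.matrix_rank(Yc) < k:
        raise SimulationError("rank-deficient trait subset")
    coef, *_ = np.linalg.lstsq(Yc, xc, rcond=None)
    resid = xc - Yc @ coef
    sst = float(xc @ xc)
    sse = float(resid @ resid)
    r2 = 1.0 - sse / sst
    r2 = min(max(r2, 0.0), assoc.R1_CLIP**2)
    r1 = math.sqrt(r2)
    return OracleStats(
        r_squared=r2,
        r1=r1,
        bic=k * math.log(n) + n * math.log1p(-r2),
        neg_log10_p=assoc.subset_pvalue(r1, k, n),
        n=n,
    )


def oracle_univariate(x: np.ndarray, y: np.ndarray) -> OracleStats:
    return oracle_subset_stats(x, np.asarray(y)[:, None])
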