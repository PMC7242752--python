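"""Phenotypic (trait-trait) correlation matrix S_YY.

The summary-statistic canonical correlation needs the K x K correlation
matrix of the traits.  With individual-level data unavailable, S_YY is
estimated as the Pearson correlation of the per-variant univariate effect
estimates across all panel variants: under the null the effect estimates of
two traits are correlated exactly as the traits themselves, and genuinely
associated variants are a negligible fraction of a genome-wide panel.

An optional shrinkage step ("plus" mode) multiplies the off-diagonal
towards zero until the smallest eigenvalue clears a floor, guarding the
downstream matrix inversion against near-singular estimates.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


class TraitCorrError(ValueError):
    pass


@dataclass
class TraitCorrelationMatrix:
    """Symmetric unit-diagonal K x K trait correlation estimate."""

    values: pd.DataFrame
    source: str = "estimated"
    shrinkage_applied: bool = False
    shrink_iterations: int = 0

    def __post_init__(self):
        v = self.values.to_numpy(dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise TraitCorrError("trait correlation matrix must be square")
        if not np.allclose(np.diag(v), 1.0, atol=1e-12):
            raise TraitCorrError("trait correlation diagonal must be 1")
        if not np.allclose(v, v.T, atol=1e-10):
            raise TraitCorrError("trait correlation matrix must be symmetric")
        if np.any(np.abs(v) > 1 + 1e-12):
            raise TraitCorrError("correlations must lie in [-1, 1]")

    @property
    def traits(self) -> list[str]:
        return list(self.values.columns)

    @property
    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values.to_numpy(dtype=float)).min())

    def subset(self, traits) -> np.ndarray:
        """Dense block for an ordered trait subset."""
        return self.values.loc[list(traits), list(traits)].to_numpy(dtype=float)


def estimate_trait_corr(panel, warn_below: int = 1000) -> TraitCorrelationMatrix:
    """Estimate S_YY as the correlation of effect-estimate columns.

    Raises on a trait whose effect estimates have zero variance (no
    correlation is defined); warns when the panel has fewer variants than
    ``warn_below`` since the estimate's sampling error scales as 1/sqrt(M).
    """
    beta = panel.beta
    sd = beta.std(axis=0)
    if np.any(sd == 0):
        bad = [t for t, s in zip(panel.traits, sd) if s == 0]
        raise TraitCorrError(
            "zero variance of effect estimates for trait(s): " + ", ".join(bad)
        )
    if panel.n_variants < warn_below:
        warnings.warn(
            f"trait correlation estimated from only {panel.n_variants} variants; "
            f"expect sampling error ~{1/np.sqrt(panel.n_variants):.3f}",
            stacklevel=2,
        )
    c = np.corrcoef(beta, rowvar=False)
    c = (c + c.T) / 2.0
    np.fill_diagonal(c, 1.0)
    values = pd.DataFrame(c, index=panel.traits, columns=panel.traits)
    return TraitCorrelationMatrix(values=values, source="estimated")


def condition_psd(
    S: TraitCorrelationMatrix,
    eigen_floor: float = 1e-4,
    shrink_step: float = 0.999,
    max_iterations: int = 500_000,
) -> TraitCorrelationMatrix:
    """Shrink off-diagonals until the minimum eigenvalue clears a floor.

    Multiplicative shrinkage is monotone and convergent: as the off-diagonal
    goes to zero the matrix approaches the identity, whose eigenvalues are
    all 1, so any floor <= 1 is eventually satisfied.  A matrix already
    meeting the floor is returned unchanged (zero iterations).
    """
    if not (0 < shrink_step < 1):
        raise TraitCorrError("shrink_step must be in (0, 1)")
    if eigen_floor <= 0:
        raise TraitCorrError("eigen_floor must be positive")
    v = S.values.to_numpy(dtype=float).copy()
    off = ~np.eye(v.shape[0], dtype=bool)
    iterations = 0
    # relative slack absorbs eigensolver rounding at the floor boundary
    target = eigen_floor * (1.0 - 1e-9)
    while np.linalg.eigvalsh(v).min() < target:
        if iterations >= max_iterations:
            raise TraitCorrError("shrinkage failed to reach the eigenvalue floor")
        v[off] *= shrink_step
        iterations += 1
    if iterations:
        log.info("shrinkage applied: %d iterations (factor %.6f)",
                 iterations, shrink_step ** iterations)
    return TraitCorrelationMatrix(
        values=pd.DataFrame(v, index=S.values.index, columns=S.values.columns),
        source=S.source,
        shrinkage_applied=iterations > 0 or S.shrinkage_applied,
        shrink_iterations=iterations,
    )


def read_trait_corr(path, traits: list[str] | None = None) -> TraitCorrelationMatrix:
    """Load a user-supplied S_YY from TSV (trait names as header and first column)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if traits is not None:
        missing = [t for t in traits if t not in df.columns]
        if missing:
            raise TraitCorrError(
                "trait correlation file lacks trait(s): " + ", ".join(missing)
            )
        df = df.loc[list(traits), list(traits)]
    return TraitCorrelationMatrix(values=df, source="user_supplied")


def write_trait_corr(S: TraitCorrelationMatrix, path) -> None:
    S.values.to_csv(path, sep="\t", float_format="%.10g")
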