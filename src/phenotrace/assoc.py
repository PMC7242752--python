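"""Canonical-correlation association statistics from summary statistics.

For a single variant x and a trait subset y_1..y_k, the first canonical
correlation r1 equals the square root of the R^2 of regressing the
(mean-centered) genotype on the traits.  Working only from univariate GWAS
summary statistics:

* each variant-trait correlation is r_j = z_j / sqrt(n_j + z_j^2), the
  sign-preserving square root of the single-trait R^2 = 1 / (1 + n/z^2);
* for the subset, r1 = sqrt(r^T S_YY^-1 r), where S_YY is the trait
  correlation matrix restricted to the subset;
* the P-value comes from the F(k, n-k-1) distribution of the regression
  R^2 (exact for the single-variant linear model), with a Bartlett-style
  chi-square approximation available as an alternative;
* BIC = k log(n) + n log(1 - R^2) up to an additive constant that cancels
  in model comparisons and is therefore dropped.

All P-values are carried on the -log10 scale and remain finite far beyond
double underflow.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import linalg, special, stats

from .sumstats import VariantKey

_LN10 = math.log(10.0)
#: clip for r1 so that log(1 - r1^2) stays finite under numerical noise
R1_CLIP = 1.0 - 1e-12


class AssociationError(ValueError):
    pass


@dataclass(frozen=True)
class SubsetAssociation:
    """Multivariate association of one variant with one trait subset."""

    variant: VariantKey
    traits: tuple[str, ...]
    r1: float
    r_squared: float
    neg_log10_p: float
    bic: float
    n_used: int


def univariate_r2(z: float, n: int) -> float:
    """Single-trait variance explained R^2 = 1 / (1 + n/z^2).

    Derived from the univariate GWAS z-score (beta / standard error); zero
    association (z = 0) gives R^2 = 0.
    """
    if n < 1:
        raise AssociationError("sample size must be >= 1")
    z = float(z)
    if z == 0.0:
        return 0.0
    return z * z / (n + z * z)


def snp_trait_corr(z, n):
    """Sign-preserving variant-trait correlation z / sqrt(n + z^2)."""
    z = np.asarray(z, dtype=float)
    n = np.asarray(n, dtype=float)
    return z / np.sqrt(n + z * z)


def subset_r1(r, S_sub) -> float:
    """First canonical correlation from per-trait correlations.

    ``r`` holds the signed variant-trait correlations for the subset and
    ``S_sub`` the matching block of the trait correlation matrix.  Returns
    sqrt(r^T S_sub^-1 r) clipped into [0, 1); for a single trait this is
    |r_1|.  The linear system is solved through a Cholesky factorisation
    (no explicit inverse).
    """
    r = np.asarray(r, dtype=float).ravel()
    k = r.size
    if k == 1:
        return float(min(abs(r[0]), R1_CLIP))
    S_sub = np.asarray(S_sub, dtype=float)
    try:
        factor = linalg.cho_factor(S_sub, lower=True)
    except linalg.LinAlgError:
        raise AssociationError(
            "trait correlation block is singular or not positive definite; "
            "rerun with --metacca-plus to shrink the correlation matrix"
        ) from None
    q = float(r @ linalg.cho_solve(factor, r))
    q = min(max(q, 0.0), R1_CLIP * R1_CLIP)
    return math.sqrt(q)


def _f_neg_log10_sf(F, k, dof2):
    """-log10 of the F(k, dof2) upper tail, safe against underflow.

    Uses scipy's log survival function; where that underflows to -inf the
    leading term of the incomplete-beta expansion at x -> 0 is used:
    sf = I_x(a, b) ~ x^a / (a B(a, b)) with a = dof2/2, b = k/2,
    x = dof2 / (dof2 + k F).
    """
    F = np.asarray(F, dtype=float)
    dof2 = np.asarray(dof2, dtype=float)
    with np.errstate(divide="ignore"):
        val = stats.f.logsf(F, k, dof2)
    bad = ~np.isfinite(val)
    if np.any(bad):
        a = dof2 / 2.0
        b = k / 2.0
        x = dof2 / (dof2 + k * F)
        approx = a * np.log(x) - np.log(a) - special.betaln(a, b)
        val = np.where(bad, approx, val)
    return -val / _LN10


def _chi2_neg_log10_sf(stat, k):
    """-log10 of the chi-square(k) upper tail with an asymptotic fallback."""
    stat = np.asarray(stat, dtype=float)
    with np.errstate(divide="ignore"):
        val = stats.chi2.logsf(stat, k)
    bad = ~np.isfinite(val)
    if np.any(bad):
        h = stat / 2.0
        a = k / 2.0
        # leading term of Gamma(a, h)/Gamma(a) for large h
        approx = -h + (a - 1.0) * np.log(h) - special.gammaln(a)
        val = np.where(bad, approx, val)
    return -val / _LN10


def subset_pvalue(r1: float, k: int, n: int, method: str = "f") -> float:
    """-log10 P for a k-trait model at first canonical correlation r1.

    ``method="f"``: exact F(k, n-k-1) test of the regression R^2 = r1^2.
    ``method="bartlett"``: -(n - 1 - (k + 2)/2) log(1 - r1^2) ~ chi^2_k.
    """
    if not 0.0 <= r1 < 1.0:
        raise AssociationError("r1 must lie in [0, 1)")
    if n <= k + 1:
        raise AssociationError("sample size too small for subset dimension")
    if r1 == 0.0:
        return 0.0
    r2 = r1 * r1
    if method == "f":
        dof2 = n - k - 1
        F = (r2 / k) * (dof2 / (1.0 - r2))
        return float(_f_neg_log10_sf(F, k, dof2))
    if method == "bartlett":
        stat = -(n - 1 - (k + 2) / 2.0) * math.log1p(-r2)
        return float(_chi2_neg_log10_sf(stat, k))
    raise AssociationError(f"unknown P-value method '{method}'")


def subset_bic(r1: float, k: int, n: int) -> float:
    """BIC up to its model-independent constant: k log(n) + n log(1 - r1^2)."""
    if r1 >= 1.0 or r1 < 0.0:
        raise AssociationError("r1 must lie in [0, 1)")
    if n < 2:
        raise AssociationError("sample size must be >= 2")
    if k < 1:
        raise AssociationError("subset size must be >= 1")
    return k * math.log(n) + n * math.log1p(-r1 * r1)


def _n_for_subset(n_row, policy: str) -> int:
    if policy == "min":
        return int(np.min(n_row))
    if policy == "mean":
        return int(round(float(np.mean(n_row))))
    raise AssociationError(f"unknown n policy '{policy}'")


def subset_association(
    panel,
    variant_index: int,
    traits,
    S_YY,
    n_policy: str = "min",
    pvalue_method: str = "f",
) -> SubsetAssociation:
    """Score one (variant, trait subset) pair from the harmonised panel."""
    traits = tuple(traits)
    idx = panel.trait_indices(traits)
    z = panel.z[variant_index, idx]
    n_row = panel.n[variant_index, idx]
    r = snp_trait_corr(z, n_row)
    if traits == tuple(panel.traits):
        S_sub = S_YY.subset(panel.traits)
    else:
        S_sub = S_YY.subset(traits)
    r1 = subset_r1(r, S_sub)
    n_used = _n_for_subset(n_row, n_policy)
    k = len(traits)
    return SubsetAssociation(
        variant=panel.variant_key(variant_index),
        traits=traits,
        r1=r1,
        r_squared=r1 * r1,
        neg_log10_p=subset_pvalue(r1, k, n_used, method=pvalue_method),
        bic=subset_bic(r1, k, n_used),
        n_used=n_used,
    )
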