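"""Genome-wide multivariate scan, significance filtering and clumping.

The full K-trait model is scored for every panel variant in deterministic
chunks (optionally across worker processes); variants below the P-value
threshold are greedily clumped by base-pair distance into independent lead
variants, each represented by the smallest-P member of its clump.
"""
from __future__ import annotations

import logging
import math
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass
from multiprocessing import get_context

import numpy as np
import pandas as pd
from scipy import linalg

from . import assoc
from .sumstats import SummaryStatPanel, VariantKey, _chrom_sort_key

log = logging.getLogger(__name__)

GENOME_WIDE_P = 5e-8
DEFAULT_WINDOW_BP = 1_000_000


@dataclass
class LeadVariant:
    """Clumped lead variant carrying its full-model statistics."""

    key: VariantKey
    full_model: assoc.SubsetAssociation
    clump_members: int
    source: str  # "scan" or "custom"


def _chunk_quadform(args):
    """Per-variant quadratic forms r^T S^-1 r for one chunk.

    Rows are processed one at a time through the same scalar path
    irrespective of chunk size, so results are bitwise identical for any
    chunking or worker count.
    """
    r_chunk, sinv = args
    out = np.empty(len(r_chunk))
    for i, row in enumerate(r_chunk):
        out[i] = row @ (sinv @ row)
    return out


def full_scan(
    panel: SummaryStatPanel,
    S_YY,
    chunk_size: int | None = None,
    workers: int = 1,
    n_policy: str = "min",
    pvalue_method: str = "f",
) -> pd.DataFrame:
    """Full-model statistics for every panel variant.

    Returns a frame with columns id, chrom, pos, r1, r_squared,
    neg_log10_p, bic, n_used in panel order.
    """
    k = panel.n_traits
    r = panel.snp_trait_corr
    S = S_YY.subset(panel.traits)
    try:
        factor = linalg.cho_factor(S, lower=True)
    except linalg.LinAlgError:
        raise assoc.AssociationError(
            "trait correlation matrix is singular or not positive definite; "
            "rerun with --metacca-plus"
        ) from None
    sinv = linalg.cho_solve(factor, np.eye(k))
    sinv = (sinv + sinv.T) / 2.0

    m = panel.n_variants
    if not chunk_size or chunk_size <= 0:
        chunk_size = m
    bounds = list(range(0, m, chunk_size)) + [m]
    jobs = [(r[a:b], sinv) for a, b in zip(bounds[:-1], bounds[1:])]

    if workers > 1 and len(jobs) > 1:
        ctx = get_context("fork")
        with ProcessPoolExecutor(max_workers=workers, mp_context=ctx) as pool:
            parts = list(pool.map(_chunk_quadform, jobs))
    else:
        parts = [_chunk_quadform(j) for j in jobs]
    q = np.concatenate(parts) if parts else np.empty(0)

    q = np.clip(q, 0.0, assoc.R1_CLIP**2)
    r1 = np.sqrt(q)
    if n_policy == "min":
        n_used = panel.n.min(axis=1)
    elif n_policy == "mean":
        n_used = np.round(panel.n.mean(axis=1))
    else:
        raise assoc.AssociationError(f"unknown n policy '{n_policy}'")
    n_used = n_used.astype(np.int64)
    if np.any(n_used <= k + 1):
        raise assoc.AssociationError("sample size too small for subset dimension")

    r2 = r1 * r1
    if pvalue_method == "f":
        dof2 = n_used - k - 1
        F = (r2 / k) * (dof2 / (1.0 - r2))
        nlp = assoc._f_neg_log10_sf(F, k, dof2)
    elif pvalue_method == "bartlett":
        stat = -(n_used - 1 - (k + 2) / 2.0) * np.log1p(-r2)
        nlp = assoc._chi2_neg_log10_sf(stat, k)
    else:
        raise assoc.AssociationError(f"unknown P-value method '{pvalue_method}'")
    nlp = np.where(r1 == 0.0, 0.0, nlp)
    bic = k * np.log(n_used) + n_used * np.log1p(-r2)

    return pd.DataFrame(
        {
            "id": panel.variants["id"].values,
            "chrom": panel.variants["chrom"].values,
            "pos": panel.variants["pos"].values,
            "r1": r1,
            "r_squared": r2,
            "neg_log10_p": nlp,
            "bic": bic,
            "n_used": n_used,
        }
    )


def _assoc_from_row(panel, i, row) -> assoc.SubsetAssociation:
    return assoc.SubsetAssociation(
        variant=panel.variant_key(i),
        traits=tuple(panel.traits),
        r1=float(row.r1),
        r_squared=float(row.r_squared),
        neg_log10_p=float(row.neg_log10_p),
        bic=float(row.bic),
        n_used=int(row.n_used),
    )


def scan(
    panel: SummaryStatPanel,
    S_YY,
    threshold: float = GENOME_WIDE_P,
    chunk_size: int | None = None,
    workers: int = 1,
    n_policy: str = "min",
    pvalue_method: str = "f",
    stats_out: list | None = None,
) -> list[assoc.SubsetAssociation]:
    """Variants whose full-model P-value is below ``threshold``.

    ``stats_out``, if given, receives the complete per-variant statistics
    frame (useful for caching / rerun modes).
    """
    if not 0.0 < threshold <= 1.0:
        raise assoc.AssociationError("threshold must lie in (0, 1]")
    table = full_scan(
        panel, S_YY, chunk_size=chunk_size, workers=workers,
        n_policy=n_policy, pvalue_method=pvalue_method,
    )
    if stats_out is not None:
        stats_out.append(table)
    nlp_threshold = -math.log10(threshold)
    hits = table.index[table["neg_log10_p"] > nlp_threshold]
    if threshold >= 1.0:  # no filtering requested
        hits = table.index
    return [_assoc_from_row(panel, int(i), table.loc[i]) for i in hits]


def clump(
    significant: list[assoc.SubsetAssociation],
    window_bp: int = DEFAULT_WINDOW_BP,
) -> list[LeadVariant]:
    """Greedy distance-based clumping of significant variants.

    Variants are taken in order of ascending P (ties: chromosome, position,
    id); each new lead absorbs all remaining variants on the same
    chromosome within ``window_bp`` of it.  Two leads are therefore always
    separated by more than ``window_bp`` within a chromosome.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    pool = sorted(
        significant,
        key=lambda a: (
            -a.neg_log10_p,
            _chrom_sort_key(a.variant.chrom),
            a.variant.pos,
            a.variant.id,
        ),
    )
    leads: list[LeadVariant] = []
    while pool:
        top = pool.pop(0)
        members = 1
        rest = []
        for a in pool:
            if (
                a.variant.chrom == top.variant.chrom
                and abs(a.variant.pos - top.variant.pos) <= window_bp
            ):
                members += 1
            else:
                rest.append(a)
        pool = rest
        leads.append(
            LeadVariant(key=top.variant, full_model=top,
                        clump_members=members, source="scan")
        )
    leads.sort(key=lambda l: (_chrom_sort_key(l.key.chrom), l.key.pos, l.key.id))
    return leads


def add_custom(
    panel: SummaryStatPanel,
    S_YY,
    ids,
    leads: list[LeadVariant] = (),
    n_policy: str = "min",
    pvalue_method: str = "f",
) -> list[LeadVariant]:
    """Append user-chosen variants to the lead list regardless of P-value.

    Unknown ids are skipped with a warning; an id already present as a scan
    lead is not duplicated (the scan record is kept).
    """
    merged = list(leads)
    present = {l.key.id for l in merged}
    for vid in ids:
        if vid in present:
            continue
        try:
            i = panel.variant_index(vid)
        except KeyError:
            log.warning("custom variant '%s' not found in panel; skipped", vid)
            continue
        fm = assoc.subset_association(
            panel, i, panel.traits, S_YY,
            n_policy=n_policy, pvalue_method=pvalue_method,
        )
        merged.append(
            LeadVariant(key=fm.variant, full_model=fm,
                        clump_members=1, source="custom")
        )
        present.add(vid)
    merged.sort(key=lambda l: (_chrom_sort_key(l.key.chrom), l.key.pos, l.key.id))
    return merged
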