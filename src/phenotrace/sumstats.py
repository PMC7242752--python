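"""Read, QC-filter and harmonise univariate GWAS summary statistics.

The multivariate association test consumes one univariate GWAS results file
per trait (whitespace- or tab-delimited text with a header line).  Each row
carries a variant identifier, genomic coordinates, the effect and other
allele, the effect estimate (beta) on the effect allele, its standard error
and, optionally, the per-variant sample size.  This module parses those
files, drops rows that cannot support the downstream statistics, and aligns
K per-trait tables into a single :class:`SummaryStatPanel` restricted to
variants present for every trait, with all betas oriented to a common
effect allele.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: default header names; overridable per input file via ``column_map``
DEFAULT_COLUMNS = {
    "id": "SNP",
    "chrom": "CHR",
    "pos": "POS",
    "ea": "EA",
    "oa": "OA",
    "beta": "BETA",
    "se": "SE",
    "n": "N",
}

_REQUIRED = ("id", "chrom", "pos", "ea", "oa", "beta", "se")
_ALLELE_RE = re.compile(r"^[ACGT]+$")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class SumStatsError(ValueError):
    """Malformed or irreconcilable summary-statistic input."""


@dataclass(frozen=True)
class VariantKey:
    """Identity of one variant: id, coordinates and allele orientation."""

    id: str
    chrom: str
    pos: int
    ea: str
    oa: str


def _chrom_sort_key(chrom: str):
    # numeric chromosomes sort numerically, then X/Y/MT etc. as strings
    c = chrom[3:] if chrom.lower().startswith("chr") else chrom
    try:
        return (0, int(c), "")
    except ValueError:
        return (1, 0, c)


def read_sumstats(
    path,
    column_map: Mapping[str, str] | None = None,
    n_default: float | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Parse one per-trait summary-statistic file.

    Parameters
    ----------
    path
        Text file (optionally gzip-compressed) with a header line.
    column_map
        Mapping from the internal field names (``id``, ``chrom``, ``pos``,
        ``ea``, ``oa``, ``beta``, ``se``, ``n``) to the column names used in
        the file.  Unspecified fields fall back to :data:`DEFAULT_COLUMNS`.
    n_default
        Sample size to use when the file has no ``n`` column (or for rows
        where it is missing).  Typical for consortium result files that
        publish a single study-wide sample size per trait.

    Returns
    -------
    (table, qc)
        ``table`` has columns ``id, chrom, pos, ea, oa, beta, se, n`` with
        validated dtypes.  ``qc`` counts rows read and rows dropped per
        reason.
    """
    cmap = dict(DEFAULT_COLUMNS)
    cmap.update(column_map or {})
    raw = pd.read_csv(path, sep=r"\s+", dtype=str, compression="infer")
    for field in _REQUIRED:
        if cmap[field] not in raw.columns:
            raise SumStatsError(
                f"required column '{cmap[field]}' not found in {path}"
            )

    qc = {
        "rows_read": len(raw),
        "dropped_missing_value": 0,
        "dropped_nonpositive_se": 0,
        "dropped_bad_allele": 0,
        "dropped_bad_pos": 0,
        "dropped_duplicate_id": 0,
        "strand_ambiguous_kept": 0,
        "n_filled_default": 0,
        "kept": 0,
    }

    tab = pd.DataFrame(
        {
            "id": raw[cmap["id"]].astype(str).str.strip(),
            "chrom": raw[cmap["chrom"]].astype(str).str.strip(),
            "pos": pd.to_numeric(raw[cmap["pos"]], errors="coerce"),
            "ea": raw[cmap["ea"]].astype(str).str.strip().str.upper(),
            "oa": raw[cmap["oa"]].astype(str).str.strip().str.upper(),
            "beta": pd.to_numeric(raw[cmap["beta"]], errors="coerce"),
            "se": pd.to_numeric(raw[cmap["se"]], errors="coerce"),
        }
    )
    if cmap["n"] in raw.columns:
        tab["n"] = pd.to_numeric(raw[cmap["n"]], errors="coerce")
        missing_n = tab["n"].isna()
        if missing_n.any() and n_default is not None:
            tab.loc[missing_n, "n"] = float(n_default)
            qc["n_filled_default"] = int(missing_n.sum())
    else:
        if n_default is None:
            tab["n"] = np.nan
        else:
            tab["n"] = float(n_default)
            qc["n_filled_default"] = len(tab)

    finite = (
        tab["beta"].notna()
        & np.isfinite(tab["beta"])
        & tab["se"].notna()
        & np.isfinite(tab["se"])
        & tab["pos"].notna()
    )
    qc["dropped_missing_value"] = int((~finite).sum())
    if qc["dropped_missing_value"]:
        log.warning(
            "%s: dropped %d rows with missing/unparseable values",
            path,
            qc["dropped_missing_value"],
        )
    tab = tab[finite]

    good_se = tab["se"] > 0
    qc["dropped_nonpositive_se"] = int((~good_se).sum())
    tab = tab[good_se]

    good_pos = tab["pos"] >= 1
    qc["dropped_bad_pos"] = int((~good_pos).sum())
    tab = tab[good_pos]

    good_allele = (
        tab["ea"].str.match(_ALLELE_RE)
        & tab["oa"].str.match(_ALLELE_RE)
        & (tab["ea"] != tab["oa"])
    )
    qc["dropped_bad_allele"] = int((~good_allele).sum())
    tab = tab[good_allele]

    dup = tab["id"].duplicated(keep="first")
    qc["dropped_duplicate_id"] = int(dup.sum())
    tab = tab[~dup]

    # A/T and C/G pairs cannot be strand-resolved from the alleles alone;
    # within one study strands agree, so they are kept but counted.
    amb = (tab["ea"].str.len() == 1) & (
        tab["oa"] == tab["ea"].map(_COMPLEMENT).fillna("")
    )
    qc["strand_ambiguous_kept"] = int(amb.sum())

    tab = tab.assign(pos=tab["pos"].astype(np.int64)).reset_index(drop=True)
    qc["kept"] = len(tab)
    return tab, qc


@dataclass
class SummaryStatPanel:
    """K-trait, M-variant grid of harmonised effect estimates.

    ``beta``, ``se`` and ``n`` are M x K arrays aligned with ``variants``
    (rows, sorted by chromosome, position, id) and ``traits`` (columns).
    """

    variants: pd.DataFrame
    traits: list[str]
    beta: np.ndarray
    se: np.ndarray
    n: np.ndarray

    def __post_init__(self):
        m, k = self.beta.shape
        if k != len(self.traits) or m != len(self.variants):
            raise SumStatsError("panel arrays inconsistent with metadata")
        if k < 2:
            raise SumStatsError("a panel requires at least two traits")
        self._id_index = {v: i for i, v in enumerate(self.variants["id"])}

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    @property
    def z(self) -> np.ndarray:
        """Per-variant, per-trait z-scores beta/se."""
        return self.beta / self.se

    @property
    def snp_trait_corr(self) -> np.ndarray:
        """Implied variant-trait correlations z / sqrt(n + z^2)."""
        z = self.z
        return z / np.sqrt(self.n + z * z)

    def variant_index(self, variant_id: str) -> int:
        try:
            return self._id_index[variant_id]
        except KeyError:
            raise KeyError(f"variant '{variant_id}' not in panel") from None

    def variant_key(self, i: int) -> VariantKey:
        row = self.variants.iloc[i]
        return VariantKey(
            id=row["id"], chrom=row["chrom"], pos=int(row["pos"]),
            ea=row["ea"], oa=row["oa"],
        )

    def trait_indices(self, traits) -> np.ndarray:
        pos = {t: j for j, t in enumerate(self.traits)}
        try:
            return np.array([pos[t] for t in traits], dtype=int)
        except KeyError as exc:
            raise KeyError(f"unknown trait {exc.args[0]!r}") from None

    def to_tables(self) -> dict[str, pd.DataFrame]:
        """Per-trait tables in the :func:`read_sumstats` output schema."""
        out = {}
        for j, t in enumerate(self.traits):
            out[t] = self.variants.assign(
                beta=self.beta[:, j], se=self.se[:, j], n=self.n[:, j]
            )
        return out


def harmonize(tables: Mapping[str, pd.DataFrame]) -> tuple[SummaryStatPanel, dict]:
    """Align K per-trait tables into one panel.

    Variants are matched on id (intersection across all tables); the first
    table fixes the effect-allele orientation and betas of swapped rows are
    sign-flipped.  Variants whose allele pair cannot be reconciled by a
    swap, or whose coordinates disagree with the first table, are dropped.
    """
    names = list(tables)
    if len(names) < 2:
        raise SumStatsError("harmonisation requires at least two traits")

    indexed = {}
    for t in names:
        df = tables[t]
        dup = df["id"].duplicated(keep="first")
        if dup.any():
            log.warning("trait %s: %d duplicate ids dropped", t, int(dup.sum()))
            df = df[~dup]
        indexed[t] = df.set_index("id", drop=False)

    common = set(indexed[names[0]].index)
    for t in names[1:]:
        common &= set(indexed[t].index)
    if not common:
        raise SumStatsError("no variants shared across all input tables")
    ids = sorted(common)

    ref = indexed[names[0]].loc[ids]
    keep = np.ones(len(ids), dtype=bool)
    qc = {t: {"dropped_allele_mismatch": 0, "dropped_position_mismatch": 0}
          for t in names}
    betas, ses, ns = [], [], []
    for t in names:
        sub = indexed[t].loc[ids]
        same = (sub["ea"].values == ref["ea"].values) & (
            sub["oa"].values == ref["oa"].values
        )
        swapped = (sub["ea"].values == ref["oa"].values) & (
            sub["oa"].values == ref["ea"].values
        )
        pos_ok = (sub["chrom"].values == ref["chrom"].values) & (
            sub["pos"].values == ref["pos"].values
        )
        allele_ok = same | swapped
        qc[t]["dropped_allele_mismatch"] = int((~allele_ok).sum())
        qc[t]["dropped_position_mismatch"] = int((pos_ok == False).sum())  # noqa: E712
        if qc[t]["dropped_allele_mismatch"]:
            log.warning(
                "trait %s: %d variants dropped (irreconcilable alleles)",
                t, qc[t]["dropped_allele_mismatch"],
            )
        if qc[t]["dropped_position_mismatch"]:
            log.warning(
                "trait %s: %d variants dropped (chrom/pos mismatch)",
                t, qc[t]["dropped_position_mismatch"],
            )
        keep &= allele_ok & pos_ok
        betas.append(np.where(swapped, -sub["beta"].values, sub["beta"].values))
        ses.append(sub["se"].values.astype(float))
        ns.append(sub["n"].values.astype(float))

    if not keep.any():
        raise SumStatsError("no variants survived harmonisation")

    beta = np.column_stack(betas)[keep]
    se = np.column_stack(ses)[keep]
    n = np.column_stack(ns)[keep]
    variants = ref.loc[keep, ["id", "chrom", "pos", "ea", "oa"]].reset_index(drop=True)

    if np.isnan(n).any():
        bad = [names[j] for j in range(len(names)) if np.isnan(n[:, j]).any()]
        raise SumStatsError(
            "sample size missing for trait(s) "
            + ", ".join(bad)
            + "; provide an n column or a per-trait default"
        )

    order = sorted(
        range(len(variants)),
        key=lambda i: (
            _chrom_sort_key(variants["chrom"].iloc[i]),
            int(variants["pos"].iloc[i]),
            variants["id"].iloc[i],
        ),
    )
    order = np.array(order, dtype=int)
    panel = SummaryStatPanel(
        variants=variants.iloc[order].reset_index(drop=True),
        traits=list(names),
        beta=beta[order],
        se=se[order],
        n=n[order],
    )
    qc["n_common_variants"] = panel.n_variants
    return panel, qc


def write_qc_report(qc_per_trait: Mapping[str, dict], path) -> None:
    rows = []
    for trait, counts in qc_per_trait.items():
        if not isinstance(counts, dict):
            continue
        rows.append({"trait": trait, **counts})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
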