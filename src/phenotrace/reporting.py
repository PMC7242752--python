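"""Tabular and graphical outputs of a decomposition run.

Every plotted number is also written to a TSV next to the figure, so plots
are reproducible views over the tables rather than primary outputs.
"""
from __future__ import annotations

import logging
from typing import Iterable, Mapping

import matplotlib

matplotlib.use("Agg")

import math

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import seaborn as sns
from scipy import stats
from scipy.cluster import hierarchy

from . import assoc
from .decompose import DecompositionResult
from .scan import LeadVariant

log = logging.getLogger(__name__)


def importance_scores(drop_rank: Mapping[str, int]) -> dict[str, float]:
    """Trait importance from the lowest-trace drop order.

    Rank 1 (dropped first, i.e. most irreplaceable) maps to 1.0 and rank K
    (last remaining trait) to 0.0 via (K - rank) / (K - 1).
    """
    k = len(drop_rank)
    if sorted(drop_rank.values()) != list(range(1, k + 1)):
        raise ValueError("drop ranks must be a bijection onto 1..K")
    return {t: (k - r) / (k - 1) for t, r in drop_rank.items()}


def importance_matrix(results: Iterable[DecompositionResult]) -> pd.DataFrame:
    rows, index = [], []
    for res in results:
        rows.append(importance_scores(res.drop_rank))
        index.append(res.variant.id)
    if not rows:
        return pd.DataFrame()
    traits = list(rows[0])
    return pd.DataFrame(rows, index=index)[traits]


def snp_similarity(drop_ranks: Mapping[str, Mapping[str, int]]) -> pd.DataFrame:
    """Spearman rank correlation of lowest-trace drop orders between variants."""
    ids = list(drop_ranks)
    if len(ids) < 2:
        raise ValueError("similarity needs at least two variants")
    traits = sorted(drop_ranks[ids[0]])
    for v in ids[1:]:
        if sorted(drop_ranks[v]) != traits:
            raise ValueError("all variants must share the same trait set")
    mat = np.eye(len(ids))
    vecs = {v: [drop_ranks[v][t] for t in traits] for v in ids}
    for i, a in enumerate(ids):
        for j in range(i + 1, len(ids)):
            rho = stats.spearmanr(vecs[a], vecs[ids[j]]).statistic
            mat[i, j] = mat[j, i] = rho
    return pd.DataFrame(mat, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# tables


def trace_table(res: DecompositionResult) -> pd.DataFrame:
    rows = []
    for steps in (res.highest_trace, res.lowest_trace, res.inverted_trace):
        for s in steps:
            rows.append(
                {
                    "trace": s.trace,
                    "step": s.step_index,
                    "n_traits": len(s.subset),
                    "subset": ",".join(s.subset),
                    "dropped": s.dropped_trait or "",
                    "r1": s.assoc.r1,
                    "r_squared": s.assoc.r_squared,
                    "neg_log10_p": s.assoc.neg_log10_p,
                    "bic": s.assoc.bic,
                }
            )
    return pd.DataFrame(rows)


def univariate_table(panel, variant_index: int) -> pd.DataFrame:
    """Per-trait single-trait statistics for one variant."""
    rows = []
    for j, t in enumerate(panel.traits):
        beta = panel.beta[variant_index, j]
        se = panel.se[variant_index, j]
        n = int(panel.n[variant_index, j])
        z = beta / se
        r1 = abs(z) / math.sqrt(n + z * z)
        rows.append(
            {
                "trait": t,
                "beta": beta,
                "se": se,
                "n": n,
                "z": z,
                "neg_log10_p": assoc.subset_pvalue(r1, 1, n),
                "direction": "+" if beta >= 0 else "-",
            }
        )
    return pd.DataFrame(rows)


def _fmt_p(neg_log10_p: float | None) -> str:
    if neg_log10_p is None:
        return "NA"
    mantissa = 10 ** (-(neg_log10_p - math.floor(neg_log10_p)))
    return f"{mantissa:.2f}e-{int(math.floor(neg_log10_p)) + 0:02d}"


def summary_table(results: Iterable[DecompositionResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        fm = res.full_model
        rows.append(
            {
                "variant": res.variant.id,
                "chrom": res.variant.chrom,
                "pos": res.variant.pos,
                "neg_log10_p_all_traits": fm.neg_log10_p,
                "drivers": ",".join(res.drivers) if res.drivers else "",
                "drivers_all": len(res.drivers) == len(fm.traits),
                "neg_log10_p_without_drivers": (
                    res.p_without_drivers
                    if res.p_without_drivers is not None
                    else np.nan
                ),
                "optimal_set": ",".join(res.optimal_set),
                "optimal_bic": res.optimal_bic,
                "neg_log10_p_optimal_set": res.optimal_assoc.neg_log10_p,
                "central_traits": ",".join(res.central),
            }
        )
    return pd.DataFrame(rows)


def leads_table(leads: Iterable[LeadVariant]) -> pd.DataFrame:
    rows = []
    for l in leads:
        rows.append(
            {
                "id": l.key.id,
                "chrom": l.key.chrom,
                "pos": l.key.pos,
                "ea": l.key.ea,
                "oa": l.key.oa,
                "r1": l.full_model.r1,
                "r_squared": l.full_model.r_squared,
                "neg_log10_p": l.full_model.neg_log10_p,
                "bic": l.full_model.bic,
                "clump_members": l.clump_members,
                "source": l.source,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# plots

_TRACE_STYLE = {
    "highest": dict(color="#1b7837", marker="o", label="highest trace"),
    "lowest": dict(color="#c51b7d", marker="s", label="lowest trace"),
    "inverted": dict(color="#542788", marker="^", label="inverted trace"),
}


def _save(fig, stem, formats):
    paths = []
    for fmt in formats:
        p = f"{stem}.{fmt}"
        fig.savefig(p, bbox_inches="tight", dpi=150)
        paths.append(p)
    plt.close(fig)
    return paths


def plot_p_traces(res: DecompositionResult, threshold: float, stem, formats):
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for steps in (res.highest_trace, res.lowest_trace, res.inverted_trace):
        x = [len(s.subset) for s in steps]
        y = [s.assoc.neg_log10_p for s in steps]
        ax.plot(x, y, **_TRACE_STYLE[steps[0].trace], lw=1.2, ms=4)
    ax.axhline(-math.log10(threshold), color="grey", ls="--", lw=1,
               label=f"P = {threshold:g}")
    ax.set_xlabel("number of traits in subset")
    ax.set_ylabel(r"$-\log_{10} P$")
    ax.set_title(f"{res.variant.id}: P-value traces")
    ax.invert_xaxis()
    ax.legend(fontsize=8)
    return _save(fig, stem, formats)


def plot_bic_traces(res: DecompositionResult, stem, formats):
    fig, ax = plt.subplots(figsize=(7, 4.5))
    for steps in (res.highest_trace, res.lowest_trace, res.inverted_trace):
        x = [len(s.subset) for s in steps]
        y = [-s.assoc.bic for s in steps]
        ax.plot(x, y, **_TRACE_STYLE[steps[0].trace], lw=1.2, ms=4)
    ax.plot(
        [len(res.optimal_set)], [-res.optimal_bic],
        marker="*", ms=14, color="goldenrod", ls="none",
        label=f"optimal: {','.join(res.optimal_set)}"[:60],
    )
    ax.set_xlabel("number of traits in subset")
    ax.set_ylabel("negative BIC (higher is better)")
    ax.set_title(f"{res.variant.id}: BIC traces")
    ax.invert_xaxis()
    ax.legend(fontsize=7)
    return _save(fig, stem, formats)


def plot_univariate(uni: pd.DataFrame, variant_id: str, threshold: float,
                    stem, formats):
    fig, ax = plt.subplots(figsize=(max(5, 0.35 * len(uni)), 4))
    colors = ["#d6604d" if d == "+" else "#4393c3" for d in uni["direction"]]
    ax.bar(uni["trait"], uni["neg_log10_p"], color=colors)
    ax.axhline(-math.log10(threshold), color="grey", ls="--", lw=1)
    ax.set_ylabel(r"univariate $-\log_{10} P$")
    ax.set_title(f"{variant_id}: univariate associations "
                 "(red +, blue - effect direction)")
    ax.tick_params(axis="x", rotation=90, labelsize=7)
    return _save(fig, stem, formats)


def plot_importance(imp: pd.DataFrame, stem, formats):
    if len(imp) > 1:
        row_link = hierarchy.linkage(imp.values, method="average",
                                     metric="euclidean")
        col_link = hierarchy.linkage(imp.values.T, method="average",
                                     metric="euclidean")
        grid = sns.clustermap(
            imp, row_linkage=row_link, col_linkage=col_link,
            cmap="Blues", vmin=0, vmax=1,
            figsize=(max(6, 0.35 * imp.shape[1]), max(4, 0.5 * imp.shape[0])),
        )
        fig = grid.fig
    else:
        fig, ax = plt.subplots(figsize=(max(6, 0.35 * imp.shape[1]), 2.5))
        sns.heatmap(imp, cmap="Blues", vmin=0, vmax=1, ax=ax)
    paths = []
    for fmt in formats:
        p = f"{stem}.{fmt}"
        fig.savefig(p, bbox_inches="tight", dpi=150)
        paths.append(p)
    plt.close(fig)
    return paths


def plot_similarity(sim: pd.DataFrame, stem, formats):
    fig, ax = plt.subplots(figsize=(max(4, 0.6 * len(sim)),) * 2)
    sns.heatmap(sim, cmap="vlag", vmin=-1, vmax=1, square=True,
                annot=len(sim) <= 10, fmt=".2f", ax=ax)
    ax.set_title("variant similarity (Spearman of lowest-trace ranks)")
    return _save(fig, stem, formats)


# ---------------------------------------------------------------------------
# orchestrated output


def render_outputs(
    results: list[DecompositionResult],
    leads: list[LeadVariant],
    panel,
    out_dir,
    threshold: float = 5e-8,
    formats: tuple[str, ...] = ("png", "pdf"),
) -> dict[str, list[str]]:
    """Write all tables and figures for a finished run; returns file paths."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    trace_dir = os.path.join(out_dir, "traces")
    os.makedirs(trace_dir, exist_ok=True)
    written: dict[str, list[str]] = {"tables": [], "plots": []}

    summary = summary_table(results)
    p = os.path.join(out_dir, "summary.tsv")
    summary.to_csv(p, sep="\t", index=False, float_format="%.10g")
    written["tables"].append(p)

    p = os.path.join(out_dir, "leads.tsv")
    leads_table(leads).to_csv(p, sep="\t", index=False, float_format="%.10g")
    written["tables"].append(p)

    if not results:
        log.info("no lead variants: summary written, no plots produced")
        return written

    for res in results:
        vid = res.variant.id
        stem = os.path.join(trace_dir, vid)
        trace_table(res).to_csv(f"{stem}.trace.tsv", sep="\t", index=False,
                                float_format="%.10g")
        written["tables"].append(f"{stem}.trace.tsv")
        uni = univariate_table(panel, panel.variant_index(vid))
        uni.to_csv(f"{stem}.univariate.tsv", sep="\t", index=False,
                   float_format="%.10g")
        written["tables"].append(f"{stem}.univariate.tsv")
        written["plots"] += plot_p_traces(res, threshold, f"{stem}.ptrace", formats)
        written["plots"] += plot_bic_traces(res, f"{stem}.bictrace", formats)
        written["plots"] += plot_univariate(uni, vid, threshold,
                                            f"{stem}.univariate", formats)

    imp = importance_matrix(results)
    p = os.path.join(out_dir, "importance_matrix.tsv")
    imp.to_csv(p, sep="\t", float_format="%.10g")
    written["tables"].append(p)
    written["plots"] += plot_importance(imp, os.path.join(out_dir, "importance_heatmap"), formats)

    if len(results) >= 2:
        sim = snp_similarity({r.variant.id: r.drop_rank for r in results})
        p = os.path.join(out_dir, "similarity_matrix.tsv")
        sim.to_csv(p, sep="\t", float_format="%.10g")
        written["tables"].append(p)
        written["plots"] += plot_similarity(sim, os.path.join(out_dir, "similarity_heatmap"), formats)
    else:
        log.info("similarity map skipped: needs at least two lead variants")
    return written
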