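"""End-to-end orchestration: read -> harmonise -> correlate -> scan ->
clump -> decompose -> report, with a machine-readable run manifest.

Also implements the decompose-only rerun mode, which reuses the cached
full-scan statistics of a previous run so that adding custom variants does
not trigger a genome-wide rescan.
"""
from __future__ import annotations

import json
import logging
import math
import os
import time
from dataclasses import dataclass, field, asdict

import pandas as pd

from . import __version__
from . import assoc, decompose, reporting, sumstats, traitcorr
from .scan import add_custom, clump
from .scan import scan as scan_panel

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    """Everything needed to reproduce one run."""

    sumstats: dict[str, str]  # trait -> path, insertion-ordered
    out_dir: str
    column_map: dict[str, str] | None = None
    n_default: dict[str, float] | float | None = None
    trait_corr_file: str | None = None
    metacca_plus: bool = False
    eigen_floor: float = 1e-4
    shrink_step: float = 0.999
    p_threshold: float = 5e-8
    clump_window_bp: int = 1_000_000
    custom_snps: list[str] = field(default_factory=list)
    threads: int = 1
    chunk_size: int = 100_000
    n_policy: str = "min"
    pvalue_method: str = "f"
    plot_formats: tuple[str, ...] = ("png",)
    corr_exclude_significant: bool = False

    def validate(self):
        if len(self.sumstats) < 2:
            raise PipelineError("at least two trait summary files are required")
        if not (0.0 < self.p_threshold < 1.0):
            raise PipelineError("--p-threshold must lie in (0, 1)")
        if self.clump_window_bp < 0:
            raise PipelineError("--clump-kb must be >= 0")
        if self.n_policy not in ("min", "mean"):
            raise PipelineError("--n-policy must be 'min' or 'mean'")
        if self.pvalue_method not in ("f", "bartlett"):
            raise PipelineError("--pvalue-method must be 'f' or 'bartlett'")


def _n_default_for(config: RunConfig, trait: str):
    nd = config.n_default
    if nd is None or isinstance(nd, (int, float)):
        return nd
    return nd.get(trait)


def _load_panel(config: RunConfig):
    tables, qc = {}, {}
    for trait, path in config.sumstats.items():
        tables[trait], qc[trait] = sumstats.read_sumstats(
            path, column_map=config.column_map,
            n_default=_n_default_for(config, trait),
        )
    panel, hqc = sumstats.harmonize(tables)
    for trait in qc:
        qc[trait].update(hqc.get(trait, {}))
    qc["n_common_variants"] = hqc["n_common_variants"]
    return panel, qc


def _trait_corr(config: RunConfig, panel):
    if config.trait_corr_file:
        S = traitcorr.read_trait_corr(config.trait_corr_file, traits=panel.traits)
    else:
        S = traitcorr.estimate_trait_corr(panel)
    if config.metacca_plus:
        S = traitcorr.condition_psd(
            S, eigen_floor=config.eigen_floor, shrink_step=config.shrink_step
        )
    return S


def _decompose_leads(panel, S, leads, config: RunConfig):
    results = []
    for lead in leads:
        i = panel.variant_index(lead.key.id)
        results.append(
            decompose.decompose_variant(
                panel, i, S,
                threshold=config.p_threshold,
                n_policy=config.n_policy,
                pvalue_method=config.pvalue_method,
            )
        )
    return results


def _write_manifest(out_dir, payload):
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(payload, fh, indent=2, default=str)


def run(config: RunConfig) -> dict:
    """Execute the full workflow; returns leads, decompositions and paths."""
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    timings: dict[str, float] = {}
    manifest = {
        "tool": "phenotrace",
        "version": __version__,
        "mode": "run",
        "status": "incomplete",
        "config": asdict(config),
    }
    try:
        t0 = time.perf_counter()
        panel, qc = _load_panel(config)
        timings["read_harmonize_s"] = time.perf_counter() - t0
        log.info("panel: %d variants x %d traits", panel.n_variants, panel.n_traits)
        sumstats.write_qc_report(qc, os.path.join(config.out_dir, "qc_report.tsv"))

        t0 = time.perf_counter()
        S = _trait_corr(config, panel)
        if config.corr_exclude_significant and not config.trait_corr_file:
            first_pass = scan_panel(
                panel, S, threshold=config.p_threshold,
                chunk_size=config.chunk_size, workers=config.threads,
                n_policy=config.n_policy, pvalue_method=config.pvalue_method,
            )
            drop = {a.variant.id for a in first_pass}
            if drop:
                keep = ~panel.variants["id"].isin(drop).values
                reduced = sumstats.SummaryStatPanel(
                    variants=panel.variants[keep].reset_index(drop=True),
                    traits=panel.traits,
                    beta=panel.beta[keep], se=panel.se[keep], n=panel.n[keep],
                )
                S = traitcorr.estimate_trait_corr(reduced)
                if config.metacca_plus:
                    S = traitcorr.condition_psd(
                        S, eigen_floor=config.eigen_floor,
                        shrink_step=config.shrink_step,
                    )
        traitcorr.write_trait_corr(
            S, os.path.join(config.out_dir, "trait_correlations.tsv")
        )
        timings["trait_corr_s"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        stats_cache: list = []
        significant = scan_panel(
            panel, S, threshold=config.p_threshold,
            chunk_size=config.chunk_size, workers=config.threads,
            n_policy=config.n_policy, pvalue_method=config.pvalue_method,
            stats_out=stats_cache,
        )
        stats_cache[0].to_csv(
            os.path.join(config.out_dir, "scan_stats.tsv"),
            sep="\t", index=False, float_format="%.10g",
        )
        timings["scan_s"] = time.perf_counter() - t0
        log.info("%d genome-wide significant variants", len(significant))

        leads = clump(significant, window_bp=config.clump_window_bp)
        if config.custom_snps:
            leads = add_custom(
                panel, S, config.custom_snps, leads,
                n_policy=config.n_policy, pvalue_method=config.pvalue_method,
            )
        log.info("%d lead variants after clumping", len(leads))

        t0 = time.perf_counter()
        results = _decompose_leads(panel, S, leads, config)
        timings["decompose_s"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        written = reporting.render_outputs(
            results, leads, panel, config.out_dir,
            threshold=config.p_threshold, formats=config.plot_formats,
        )
        timings["report_s"] = time.perf_counter() - t0

        manifest.update(
            status="complete",
            traits=panel.traits,
            n_variants=panel.n_variants,
            n_significant=len(significant),
            n_leads=len(leads),
            shrinkage_applied=S.shrinkage_applied,
            timings=timings,
            outputs=written,
        )
        _write_manifest(config.out_dir, manifest)
        return {"panel": panel, "S_YY": S, "leads": leads,
                "results": results, "manifest": manifest}
    except Exception as exc:
        manifest.update(status="failed", error=str(exc), timings=timings)
        _write_manifest(config.out_dir, manifest)
        raise


def decompose_rerun(
    run_dir: str,
    custom_snps: list[str] | None = None,
    out_dir: str | None = None,
    p_threshold: float | None = None,
) -> dict:
    """Re-decompose leads of a finished run without rescanning.

    Loads the previous run's manifest, cached per-variant scan statistics
    and trait correlations; re-reads the input summary files to rebuild the
    panel (needed for subset scoring) and then decomposes the clumped leads
    plus any additional custom variants.
    """
    manifest_path = os.path.join(run_dir, "manifest.json")
    if not os.path.exists(manifest_path):
        raise PipelineError(f"no manifest.json in {run_dir}")
    with open(manifest_path) as fh:
        prior = json.load(fh)
    if prior.get("status") != "complete":
        raise PipelineError("previous run did not complete; rerun it first")

    cfg_dict = dict(prior["config"])
    cfg_dict["custom_snps"] = list(custom_snps or [])
    cfg_dict["out_dir"] = out_dir or run_dir
    if p_threshold is not None:
        cfg_dict["p_threshold"] = p_threshold
    cfg_dict["plot_formats"] = tuple(cfg_dict.get("plot_formats") or ("png",))
    config = RunConfig(**cfg_dict)
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)

    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    panel, _ = _load_panel(config)
    S = traitcorr.read_trait_corr(
        os.path.join(run_dir, "trait_correlations.tsv"), traits=panel.traits
    )
    stats = pd.read_csv(os.path.join(run_dir, "scan_stats.tsv"), sep="\t",
                        dtype={"chrom": str})
    timings["load_s"] = time.perf_counter() - t0

    nlp_threshold = -math.log10(config.p_threshold)
    significant = []
    for row in stats.itertuples(index=False):
        if row.neg_log10_p > nlp_threshold:
            i = panel.variant_index(row.id)
            significant.append(
                assoc.SubsetAssociation(
                    variant=panel.variant_key(i),
                    traits=tuple(panel.traits),
                    r1=float(row.r1), r_squared=float(row.r_squared),
                    neg_log10_p=float(row.neg_log10_p), bic=float(row.bic),
                    n_used=int(row.n_used),
                )
            )
    leads = clump(significant, window_bp=config.clump_window_bp)
    if config.custom_snps:
        leads = add_custom(
            panel, S, config.custom_snps, leads,
            n_policy=config.n_policy, pvalue_method=config.pvalue_method,
        )

    t0 = time.perf_counter()
    results = _decompose_leads(panel, S, leads, config)
    timings["decompose_s"] = time.perf_counter() - t0
    written = reporting.render_outputs(
        results, leads, panel, config.out_dir,
        threshold=config.p_threshold, formats=config.plot_formats,
    )
    manifest = {
        "tool": "phenotrace",
        "version": __version__,
        "mode": "decompose",
        "status": "complete",
        "config": asdict(config),
        "source_run": run_dir,
        "n_leads": len(leads),
        "timings": timings,
        "outputs": written,
    }
    _write_manifest(config.out_dir, manifest)
    return {"panel": panel, "S_YY": S, "leads": leads,
            "results": results, "manifest": manifest}
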