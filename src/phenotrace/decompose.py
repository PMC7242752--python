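"""Trace decomposition of a multivariate association into trait sets.

Starting from the full K-trait model, one trait is removed at a time:

* highest trace — at each step every (k-1)-subset of the current subset is
  scored and the one with the highest canonical correlation is kept, i.e.
  the most replaceable trait is dropped first;
* lowest trace — the subset with the lowest canonical correlation is kept,
  i.e. the most irreplaceable trait is dropped first;
* inverted trace — the cumulative sets of traits dropped on the lowest
  trace, in drop order (sizes 1..K-1), which puts the prospective driver
  sets into the search space of the optimal subset.

From these, three trait sets summarise the association:

* drivers — the traits dropped on the lowest trace up to and including the
  first step at which the multivariate P-value is no longer genome-wide
  significant; without them the association would not have been reported;
* optimal set — the minimum-BIC subset among all subsets appearing on the
  three traces (plus the full model);
* central traits — the union of drivers and the optimal set.

The greedy procedure scores about K^2 + K subsets per variant instead of
the 2^K - 1 required by exhaustive search; subsets already scored are
cached so shared candidates are never recomputed.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

from . import assoc
from .sumstats import SummaryStatPanel, VariantKey

log = logging.getLogger(__name__)

#: two candidate subsets within this r1 distance are considered tied
TIE_TOL = 1e-12


@dataclass(frozen=True)
class TraceStep:
    trace: str  # "highest" | "lowest" | "inverted"
    step_index: int
    subset: tuple[str, ...]
    dropped_trait: str | None
    assoc: assoc.SubsetAssociation


@dataclass
class DecompositionResult:
    variant: VariantKey
    highest_trace: list[TraceStep]
    lowest_trace: list[TraceStep]
    inverted_trace: list[TraceStep]
    drivers: tuple[str, ...]
    p_without_drivers: float | None  # -log10 scale; None when drivers = all traits
    optimal_set: tuple[str, ...]
    optimal_bic: float
    optimal_assoc: assoc.SubsetAssociation
    central: tuple[str, ...]
    drop_rank: dict[str, int]  # 1 = first dropped on the lowest trace

    @property
    def full_model(self) -> assoc.SubsetAssociation:
        return self.highest_trace[0].assoc


class SubsetScorer:
    """Memoised scoring of trait subsets for one variant.

    ``evaluations`` counts distinct subsets actually computed, which is the
    quantity behind the ~K^2 versus 2^K - 1 efficiency argument.
    """

    def __init__(self, panel: SummaryStatPanel, variant_index: int, S_YY,
                 n_policy: str = "min", pvalue_method: str = "f"):
        self.panel = panel
        self.variant_index = variant_index
        self.S_YY = S_YY
        self.n_policy = n_policy
        self.pvalue_method = pvalue_method
        self.evaluations = 0
        self._order = {t: j for j, t in enumerate(panel.traits)}
        self._cache: dict[frozenset, assoc.SubsetAssociation] = {}

    def canonical(self, traits) -> tuple[str, ...]:
        """Subset in panel trait order (deterministic representation)."""
        return tuple(sorted(traits, key=self._order.__getitem__))

    def score(self, traits) -> assoc.SubsetAssociation:
        key = frozenset(traits)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        res = assoc.subset_association(
            self.panel, self.variant_index, self.canonical(traits), self.S_YY,
            n_policy=self.n_policy, pvalue_method=self.pvalue_method,
        )
        self._cache[key] = res
        self.evaluations += 1
        return res


def _pick(candidates, mode: str):
    """Select the kept subset among (dropped_trait, association) candidates.

    ``mode="max"`` keeps the highest-r1 subset, ``mode="min"`` the lowest.
    Candidates tied within TIE_TOL are resolved by dropping the
    lexicographically smallest trait name, for reproducibility.
    """
    r1s = [a.r1 for _, a in candidates]
    best = max(r1s) if mode == "max" else min(r1s)
    tied = [
        (t, a) for t, a in candidates
        if (best - a.r1 if mode == "max" else a.r1 - best) <= TIE_TOL
    ]
    return min(tied, key=lambda ta: ta[0])


def _greedy_trace(scorer: SubsetScorer, mode: str, name: str) -> list[TraceStep]:
    full = scorer.score(scorer.panel.traits)
    steps = [TraceStep(name, 0, scorer.canonical(scorer.panel.traits), None, full)]
    current = list(scorer.canonical(scorer.panel.traits))
    while len(current) > 1:
        candidates = []
        for t in current:
            sub = tuple(x for x in current if x != t)
            candidates.append((t, scorer.score(sub)))
        dropped, kept = _pick(candidates, mode)
        current = [x for x in current if x != dropped]
        steps.append(TraceStep(name, len(steps), tuple(current), dropped, kept))
    return steps


def build_traces(
    panel: SummaryStatPanel,
    variant_index: int,
    S_YY,
    scorer: SubsetScorer | None = None,
    n_policy: str = "min",
    pvalue_method: str = "f",
) -> tuple[list[TraceStep], list[TraceStep], list[TraceStep]]:
    """Highest, lowest and inverted traces for one variant."""
    if panel.n_traits < 2:
        raise assoc.AssociationError("decomposition requires K >= 2 traits")
    if scorer is None:
        scorer = SubsetScorer(panel, variant_index, S_YY,
                              n_policy=n_policy, pvalue_method=pvalue_method)
    highest = _greedy_trace(scorer, "max", "highest")
    lowest = _greedy_trace(scorer, "min", "lowest")
    dropped = [s.dropped_trait for s in lowest[1:]]
    inverted = []
    for t in range(1, len(dropped) + 1):
        sub = scorer.canonical(dropped[:t])
        inverted.append(
            TraceStep("inverted", t - 1, sub, dropped[t - 1], scorer.score(sub))
        )
    return highest, lowest, inverted


def find_drivers(
    lowest_trace: list[TraceStep],
    threshold: float = 5e-8,
) -> tuple[tuple[str, ...], float | None]:
    """Driver traits from the lowest trace.

    Walking down the lowest trace, the drivers are the traits dropped up to
    and including the first step whose subset P-value is no longer below
    the genome-wide threshold; the returned P (on -log10 scale) is that
    step's.  If significance persists through the final single-trait
    subset, every trait is a driver and the P is None.  A full model that
    is itself not significant (custom variants) yields an empty driver set.
    """
    nlp_threshold = -math.log10(threshold)
    full = lowest_trace[0].assoc
    if full.neg_log10_p <= nlp_threshold:
        log.warning(
            "variant %s: full model is not genome-wide significant "
            "(P = 1e-%.2f); no driver traits defined",
            full.variant.id, full.neg_log10_p,
        )
        return (), None
    dropped: list[str] = []
    for step in lowest_trace[1:]:
        dropped.append(step.dropped_trait)
        if step.assoc.neg_log10_p <= nlp_threshold:
            return tuple(dropped), step.assoc.neg_log10_p
    return lowest_trace[0].subset, None


def find_optimal(
    highest_trace: list[TraceStep],
    inverted_trace: list[TraceStep],
    full_model: assoc.SubsetAssociation | None = None,
) -> tuple[tuple[str, ...], float, assoc.SubsetAssociation]:
    """Minimum-BIC subset over the candidate pool of all trace subsets.

    The pool is every subset on the highest trace (sizes K..1), every
    subset on the inverted trace (sizes 1..K-1) and the full model; ties
    are broken towards the smaller subset, then lexicographically.
    """
    pool: dict[frozenset, assoc.SubsetAssociation] = {}
    for step in highest_trace:
        pool.setdefault(frozenset(step.subset), step.assoc)
    for step in inverted_trace:
        pool.setdefault(frozenset(step.subset), step.assoc)
    if full_model is not None:
        pool.setdefault(frozenset(full_model.traits), full_model)
    best = min(
        pool.values(),
        key=lambda a: (a.bic, len(a.traits), tuple(sorted(a.traits))),
    )
    return best.traits, best.bic, best


def central_traits(drivers, optimal_set) -> tuple[str, ...]:
    """Union of driver traits and the optimal BIC subset."""
    return tuple(sorted(set(drivers) | set(optimal_set)))


def decompose_variant(
    panel: SummaryStatPanel,
    variant_index: int,
    S_YY,
    threshold: float = 5e-8,
    n_policy: str = "min",
    pvalue_method: str = "f",
) -> DecompositionResult:
    """Full decomposition of one variant into driver/optimal/central sets."""
    scorer = SubsetScorer(panel, variant_index, S_YY,
                          n_policy=n_policy, pvalue_method=pvalue_method)
    highest, lowest, inverted = build_traces(panel, variant_index, S_YY,
                                             scorer=scorer)
    drivers, p_without = find_drivers(lowest, threshold=threshold)
    optimal_set, optimal_bic, optimal_assoc = find_optimal(
        highest, inverted, full_model=highest[0].assoc
    )
    drop_rank = {s.dropped_trait: s.step_index for s in lowest[1:]}
    survivor = lowest[-1].subset[0]
    drop_rank[survivor] = panel.n_traits
    # central ordered like the panel for stable reporting
    central = tuple(
        t for t in panel.traits if t in set(drivers) | set(optimal_set)
    )
    return DecompositionResult(
        variant=panel.variant_key(variant_index),
        highest_trace=highest,
        lowest_trace=lowest,
        inverted_trace=inverted,
        drivers=drivers,
        p_without_drivers=p_without,
        optimal_set=optimal_set,
        optimal_bic=optimal_bic,
        optimal_assoc=optimal_assoc,
        central=central,
        drop_rank=drop_rank,
    )


def exhaustive_minimum_bic(
    scorer: SubsetScorer, max_traits: int = 12
) -> tuple[tuple[str, ...], float]:
    """Brute-force minimum BIC over all 2^K - 1 subsets (test oracle).

    Guarded to small K; the greedy traces exist precisely to avoid this
    enumeration at scale.
    """
    traits = scorer.canonical(scorer.panel.traits)
    if len(traits) > max_traits:
        raise assoc.AssociationError(
            f"exhaustive search limited to K <= {max_traits}"
        )
    best = None
    for k in range(1, len(traits) + 1):
        for sub in combinations(traits, k):
            a = scorer.score(sub)
            key = (a.bic, len(a.traits), tuple(sorted(a.traits)))
            if best is None or key < best[0]:
                best = (key, a)
    return best[1].traits, best[1].bic
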