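"""Co-module filtering cascade.

Three stages, applied in order to the output of a threshold-grid run:

1. redundancy elimination — pairs of co-modules whose per-species gene-score
   correlations multiply to more than 0.8 describe the same content; the one
   found at the higher (stricter) threshold sum is kept;
2. minimum-size filter — co-modules with fewer than 10 features for at
   least one species are dropped;
3. fully-overlapping reduction — among co-modules whose species-1 gene sets
   are nested, only the biggest (by the min-of-both-species size) is kept.

Each stage returns a subset of its input; co-modules are never modified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .ppa import CoModule

logger = logging.getLogger(__name__)

__all__ = [
    "PairSimilarity",
    "pair_similarity",
    "eliminate_redundant",
    "filter_min_probes",
    "comodule_size",
    "reduce_fully_overlapping",
    "postprocess_cascade",
]


@dataclass(frozen=True)
class PairSimilarity:
    """Correlations between two co-modules' full-length gene-score vectors,
    one per species, and their product.  ``defined`` is False when either
    vector has zero variance."""

    c_h: float
    c_m: float
    product: float
    defined: bool


def _pearson(x: np.ndarray, y: np.ndarray) -> float | None:
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        return None
    return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))


def pair_similarity(a: CoModule, b: CoModule) -> PairSimilarity:
    """Pearson correlation of the two co-modules' score vectors over the
    whole feature universe (zeros for non-members), per species."""
    if a.feature_scores_1.ids != b.feature_scores_1.ids or a.feature_scores_2.ids != b.feature_scores_2.ids:
        raise ValueError("co-modules come from different feature universes")
    c_h = _pearson(a.feature_scores_1.scores, b.feature_scores_1.scores)
    c_m = _pearson(a.feature_scores_2.scores, b.feature_scores_2.scores)
    if c_h is None or c_m is None:
        logger.warning("pair_similarity: zero-variance score vector; product treated as 0")
        return PairSimilarity(np.nan if c_h is None else c_h,
                              np.nan if c_m is None else c_m, 0.0, False)
    return PairSimilarity(c_h, c_m, c_h * c_m, True)


def eliminate_redundant(comodules: list[CoModule], product_cut: float = 0.8) -> list[CoModule]:
    """Greedy redundancy elimination.

    Candidates are visited by descending sum of the two feature thresholds
    (ties: more members, then input order) and accepted unless their
    similarity product with an already-accepted co-module exceeds
    ``product_cut``.  The accepted set is returned in input order.
    """
    def n_members(cm: CoModule) -> int:
        return len(cm.feature_scores_1.membership) + len(cm.feature_scores_2.membership)

    order = sorted(
        range(len(comodules)),
        key=lambda i: (-(comodules[i].thresholds[0] + comodules[i].thresholds[1]),
                       -n_members(comodules[i]), i),
    )
    accepted: list[int] = []
    for i in order:
        cm = comodules[i]
        if all(pair_similarity(cm, comodules[j]).product <= product_cut for j in accepted):
            accepted.append(i)
    return [comodules[i] for i in sorted(accepted)]


def filter_min_probes(comodules: list[CoModule], min_count: int = 10) -> list[CoModule]:
    """Keep co-modules with at least ``min_count`` features in both species."""
    return [
        cm
        for cm in comodules
        if len(cm.feature_scores_1.membership) >= min_count
        and len(cm.feature_scores_2.membership) >= min_count
    ]


def comodule_size(cm: CoModule, genes_1=None, genes_2=None) -> int:
    """Size = min of the two species' gene counts.  Gene-level sets may be
    passed explicitly (after probe collapse); otherwise feature memberships
    are counted."""
    n1 = len(genes_1) if genes_1 is not None else len(cm.feature_scores_1.membership)
    n2 = len(genes_2) if genes_2 is not None else len(cm.feature_scores_2.membership)
    return min(n1, n2)


def reduce_fully_overlapping(
    comodules: list[CoModule], gene_sets_1=None, gene_sets_2=None
) -> list[CoModule]:
    """Collapse groups of co-modules with nested species-1 gene sets.

    Two co-modules overlap fully when one's species-1 gene set contains the
    other's.  Groups are the connected components of this relation; within
    each, the co-module of maximal size survives (ties: larger species-1
    set, then input order).  Gene-level sets (after probe collapse) may be
    passed explicitly; otherwise feature memberships are used.
    """
    n = len(comodules)
    sets1 = (
        [frozenset(s) for s in gene_sets_1]
        if gene_sets_1 is not None
        else [cm.feature_scores_1.membership for cm in comodules]
    )
    sets2 = (
        [frozenset(s) for s in gene_sets_2]
        if gene_sets_2 is not None
        else [cm.feature_scores_2.membership for cm in comodules]
    )
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if sets1[i] <= sets1[j] or sets1[j] <= sets1[i]:
                parent[find(i)] = find(j)
    best: dict[int, int] = {}
    for i in range(n):
        r = find(i)
        if r not in best:
            best[r] = i
        else:
            b = best[r]
            key_i = (min(len(sets1[i]), len(sets2[i])), len(sets1[i]), -i)
            key_b = (min(len(sets1[b]), len(sets2[b])), len(sets1[b]), -b)
            if key_i > key_b:
                best[r] = i
    keep = sorted(best.values())
    return [comodules[i] for i in keep]


def postprocess_cascade(
    comodules: list[CoModule],
    product_cut: float = 0.8,
    min_count: int = 10,
) -> tuple[list[CoModule], dict[str, int]]:
    """Run the full three-stage cascade; also return per-stage survivor
    counts for provenance."""
    counts = {"input": len(comodules)}
    stage1 = eliminate_redundant(comodules, product_cut)
    counts["after_redundancy"] = len(stage1)
    stage2 = filter_min_probes(stage1, min_count)
    counts["after_min_probes"] = len(stage2)
    stage3 = reduce_fully_overlapping(stage2)
    counts["after_overlap_reduction"] = len(stage3)
    return stage3, counts
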