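"""Expression-conservation rate gamma and its nulls.

A gene family is a connected component of the bipartite ortholog-pair graph
(genes of the two species as vertices, pairs as edges).  For a co-module
with gene sets on both species' sides,

    gamma = n_og / min(nfam_h, nfam_m)

where n_og counts families represented in the co-module on BOTH sides
(orthologous groups), and nfam_h / nfam_m count the families represented on
each side that have at least one ortholog measured on the other species'
array at all.  gamma is 1 when every family that could be conserved is, 0
when none is, and undefined (not 0) when min(nfam_h, nfam_m) = 0.

The chance level is estimated by reshuffling the ortholog list while
preserving the one-to-one / many-to-many split, and the noise ceiling by
running the discovery on two replicate halves of a single species.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
from scipy import stats

from .data import OrthologyMap
from .ppa import CoModule

logger = logging.getLogger(__name__)

__all__ = [
    "FamilyPartition",
    "GammaResult",
    "build_families",
    "gamma",
    "shuffle_orthologs",
    "null_gamma",
    "replicate_gamma",
    "compare_gamma",
]


@dataclass
class FamilyPartition:
    """Disjoint gene families (connected components of the ortholog graph),
    each split into its species-1 and species-2 members."""

    families: list[tuple[frozenset[str], frozenset[str]]]  # (species-1, species-2)

    def __post_init__(self):
        self._fam_of_1: dict[str, int] = {}
        self._fam_of_2: dict[str, int] = {}
        for k, (s1, s2) in enumerate(self.families):
            for g in s1:
                self._fam_of_1[g] = k
            for g in s2:
                self._fam_of_2[g] = k

    def family_of(self, gene: str, side: int) -> int | None:
        return (self._fam_of_1 if side == 1 else self._fam_of_2).get(gene)

    def __len__(self):
        return len(self.families)


@dataclass
class GammaResult:
    """Family accounting for one co-module.

    ``gamma`` is None when min(nfam_h, nfam_m) = 0 (undefined, excluded
    from medians and tests).
    """

    n_og: int
    nfam_h: int
    nfam_m: int
    gamma: float | None


def build_families(orth: OrthologyMap) -> FamilyPartition:
    """Connected components of the bipartite ortholog-pair graph, ordered by
    smallest member id for determinism."""
    g = nx.Graph()
    for a, b in orth.pairs:
        g.add_edge(("1", a), ("2", b))
    fams = []
    for comp in nx.connected_components(g):
        s1 = frozenset(x for side, x in comp if side == "1")
        s2 = frozenset(x for side, x in comp if side == "2")
        fams.append((s1, s2))
    fams.sort(key=lambda f: min(f[0] | f[1]))
    return FamilyPartition(fams)


def gamma(
    cm_genes_1,
    cm_genes_2,
    fam: FamilyPartition,
    array_genes_1,
    array_genes_2,
) -> GammaResult:
    """Expression-conservation rate of one co-module.

    ``array_genes_1`` / ``array_genes_2`` are the genes measured on each
    species' array: a family counts toward a side's nfam only if one of its
    orthologs on the *other* species is measured at all (not necessarily in
    the co-module).
    """
    array_genes_1 = set(array_genes_1)
    array_genes_2 = set(array_genes_2)
    fams_1 = {fam.family_of(g, 1) for g in cm_genes_1} - {None}
    fams_2 = {fam.family_of(g, 2) for g in cm_genes_2} - {None}
    nfam_h = sum(1 for k in fams_1 if fam.families[k][1] & array_genes_2)
    nfam_m = sum(1 for k in fams_2 if fam.families[k][0] & array_genes_1)
    n_og = len(fams_1 & fams_2)
    denom = min(nfam_h, nfam_m)
    return GammaResult(n_og, nfam_h, nfam_m, n_og / denom if denom > 0 else None)


def shuffle_orthologs(orth: OrthologyMap, rng: np.random.Generator) -> OrthologyMap:
    """Randomly re-pair the ortholog list, preserving the number of
    one-to-one and many-to-many pairs.

    One-to-one pairs have their species-2 partners permuted among
    themselves; many-to-many pairs have the distinct species-2 genes they
    involve relabelled by a random permutation (which preserves the pair
    multiset structure, hence the class counts).
    """
    one, many = orth.classify()
    new_pairs: set[tuple[str, str]] = set()
    one_sorted = sorted(one)
    partners = [b for _, b in one_sorted]
    perm = rng.permutation(len(partners))
    for (a, _), k in zip(one_sorted, perm):
        new_pairs.add((a, partners[k]))
    many_sorted = sorted(many)
    genes2 = sorted({b for _, b in many_sorted})
    relabel = {g: genes2[k] for g, k in zip(genes2, rng.permutation(len(genes2)))}
    for a, b in many_sorted:
        new_pairs.add((a, relabel[b]))
    return OrthologyMap(new_pairs)


def null_gamma(
    cm_genes_1,
    cm_genes_2,
    orth: OrthologyMap,
    array_genes_1,
    array_genes_2,
    n_reps: int = 10,
    rng: np.random.Generator | None = None,
    shuffled: list | None = None,
) -> float | None:
    """Mean gamma over ``n_reps`` ortholog reshufflings (the chance level).

    Pre-shuffled orthologies (or their already-built FamilyPartitions, which
    amortizes the component search across the co-modules of one run) may be
    passed so the same draws are shared across co-modules; otherwise they
    are drawn from ``rng``.  Undefined replicate gammas are excluded
    (logged); None if all are.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if shuffled is None:
        if rng is None:
            raise ValueError("either rng or pre-shuffled orthologies required")
        shuffled = [shuffle_orthologs(orth, rng) for _ in range(n_reps)]
    values = []
    for sh in shuffled[:n_reps]:
        fam = sh if isinstance(sh, FamilyPartition) else build_families(sh)
        res = gamma(cm_genes_1, cm_genes_2, fam, array_genes_1, array_genes_2)
        if res.gamma is not None:
            values.append(res.gamma)
    if not values:
        return None
    if len(values) < n_reps:
        logger.info("null_gamma: %d undefined replicate(s) excluded", n_reps - len(values))
    return float(np.mean(values))


def replicate_gamma(cm: CoModule) -> GammaResult:
    """Gamma for a co-module from a replicate-split run of one species.

    Here n_og is the number of probe sets present in both sides'
    memberships and the family counts are simply each side's membership
    size, so gamma is the overlap fraction of the smaller side.
    """
    m1 = cm.feature_scores_1.membership
    m2 = cm.feature_scores_2.membership
    n_og = len(m1 & m2)
    denom = min(len(m1), len(m2))
    return GammaResult(n_og, len(m1), len(m2), n_og / denom if denom > 0 else None)


# ---------------------------------------------------------------------------
# rank test
# ---------------------------------------------------------------------------

def _midranks(pooled: np.ndarray) -> np.ndarray:
    return stats.rankdata(pooled)


def _exact_rank_sum_p(x: np.ndarray, y: np.ndarray, alternative: str) -> float:
    """Exhaustive-enumeration rank-sum p-value with midranks for ties.

    Enumerates every assignment of the pooled values into a group of
    ``len(x)``; feasible only for small pooled sizes.
    """
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    n1 = len(x)
    obs = ranks[:n1].sum()
    total = 0
    count = 0
    mean = ranks.sum() * n1 / len(ranks)
    for idx in combinations(range(len(ranks)), n1):
        r = ranks[list(idx)].sum()
        total += 1
        if alternative == "greater":
            count += r >= obs - 1e-12
        elif alternative == "less":
            count += r <= obs + 1e-12
        else:
            count += abs(r - mean) >= abs(obs - mean) - 1e-12
    return count / total


def rank_sum_test(x, y, alternative: str = "greater") -> tuple[float, float]:
    """Wilcoxon rank-sum / Mann-Whitney test returning (U statistic, p).

    Small samples (both sides < 8 and a feasible enumeration) use exhaustive
    enumeration over arrangements with midranks; otherwise the tie-corrected
    normal approximation without continuity correction (so identical samples
    give p = 0.5 one-sided / 1.0 two-sided).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = len(x), len(y)
    ranks = _midranks(np.concatenate([x, y]))
    u_stat = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    small = min(n1, n2) < 8 and math.comb(n1 + n2, n1) <= 500_000
    if small:
        return float(u_stat), float(_exact_rank_sum_p(x, y, alternative))
    mu = n1 * n2 / 2.0
    # tie-corrected variance of U
    _, tie_counts = np.unique(np.concatenate([x, y]), return_counts=True)
    n = n1 + n2
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var == 0:
        return float(u_stat), 1.0 if alternative == "two-sided" else 0.5
    z = (u_stat - mu) / math.sqrt(var)
    if alternative == "greater":
        p = stats.norm.sf(z)
    elif alternative == "less":
        p = stats.norm.cdf(z)
    else:
        p = 2 * stats.norm.sf(abs(z))
    return float(u_stat), float(min(1.0, p))


def compare_gamma(real, null) -> tuple[float, float]:
    """One-sided Mann-Whitney U test of real gammas exceeding null gammas.

    Undefined values (None/NaN) are removed first; returns (U, p) for the
    alternative "real > null".
    """
    real = np.array([v for v in real if v is not None and not np.isnan(v)], dtype=float)
    null = np.array([v for v in null if v is not None and not np.isnan(v)], dtype=float)
    if real.size == 0 or null.size == 0:
        raise ValueError("empty gamma list after removing undefined values")
    return rank_sum_test(real, null, alternative="greater")
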