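"""The ping-pong algorithm: alternating thresholded projections between two
expression matrices that share one dimension.

Both matrices must expose the same ordered set of shared-dimension
identifiers as their columns (HOGs in the organ-shared configuration, or
one-to-one ortholog pairs in the gene-shared configuration after
transposition).  Starting from a seed set of shared elements, the algorithm
alternates four projection/threshold steps until the three membership sets
(features of each matrix, shared elements) are stable; the fixed points are
co-modules of coherently over-expressed features and shared elements.

Conventions (the signature-algorithm family's): feature scores are computed
from a column z-scored copy of each matrix (each shared-dimension profile
standardized across features), shared scores from a row z-scored copy (each
feature profile standardized across the shared dimension); standard
deviations are population (divide by n) throughout; thresholding keeps only
the upper tail, so only over-expression is detected; surviving scores are
rescaled by their maximum into (0, 1].
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from itertools import product

import numpy as np

from .data import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ScoreVector",
    "Seed",
    "CoModule",
    "normalize_for_projection",
    "threshold_scores",
    "make_random_seeds",
    "ppa_iterate",
    "run_ppa_grid",
    "write_comodules_json",
    "read_comodules_json",
    "write_comodules_tsv",
]

DEFAULT_FEATURE_GRID = tuple(np.arange(2.5, 6.0 + 1e-9, 0.5))
DEFAULT_SHARED_GRID = tuple(np.arange(1.0, 4.5 + 1e-9, 0.5))


@dataclass(frozen=True, eq=False)
class ScoreVector:
    """Membership scores over an ordered identifier universe.

    ``scores`` is dense over ``ids``; zero means non-membership.  When the
    membership is nonempty the maximum score is exactly 1.
    """

    ids: tuple[str, ...]
    scores: np.ndarray

    @property
    def membership(self) -> frozenset[str]:
        return frozenset(i for i, s in zip(self.ids, self.scores) if s > 0)

    def member_ids(self) -> list[str]:
        return [i for i, s in zip(self.ids, self.scores) if s > 0]

    def is_empty(self) -> bool:
        return not np.any(self.scores > 0)


@dataclass(frozen=True)
class Seed:
    """A starting set of shared-dimension identifiers."""

    hog_ids: frozenset[str]

    def __post_init__(self):
        if not self.hog_ids:
            raise ValueError("seed must be nonempty")


@dataclass(eq=False)
class CoModule:
    """A fixed point of the ping-pong iteration.

    One score vector over the shared dimension and one over each matrix's
    feature dimension, together with the thresholds that produced it.
    """

    shared_scores: ScoreVector
    feature_scores_1: ScoreVector
    feature_scores_2: ScoreVector
    thresholds: tuple[float, float, float]  # (t_feature_1, t_feature_2, t_shared)
    iterations: int
    converged: bool
    n_seeds: int = 1  # provenance: seeds that reached this fixed point

    @property
    def membership_key(self):
        return (
            self.feature_scores_1.membership,
            self.feature_scores_2.membership,
            self.shared_scores.membership,
        )


# ---------------------------------------------------------------------------
# normalization and thresholding
# ---------------------------------------------------------------------------

def _zscore(a: np.ndarray, axis: int) -> np.ndarray:
    mu = a.mean(axis=axis, keepdims=True)
    sd = a.std(axis=axis, keepdims=True)  # population convention
    out = np.zeros_like(a, dtype=float)
    np.divide(a - mu, sd, out=out, where=sd > 0)
    return out


def normalize_for_projection(
    expr: ExpressionMatrix,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Return (row-z-scored, column-z-scored) copies of a matrix.

    The column-normalized copy is used when computing feature scores from
    shared scores, the row-normalized copy when computing shared scores from
    feature scores.  Constant rows or columns become all-zero (logged)
    rather than raising.
    """
    if expr.n_features < 2 or expr.n_samples < 2:
        raise ValueError("normalization requires at least 2 rows and 2 columns")
    v = expr.values
    n_const_rows = int(np.sum(v.std(axis=1) == 0))
    n_const_cols = int(np.sum(v.std(axis=0) == 0))
    if n_const_rows or n_const_cols:
        logger.warning(
            "normalize_for_projection: %d constant row(s), %d constant column(s) set to zero",
            n_const_rows,
            n_const_cols,
        )
    row = ExpressionMatrix(
        expr.species, list(expr.feature_ids), list(expr.sample_ids), _zscore(v, axis=1)
    )
    col = ExpressionMatrix(
        expr.species, list(expr.feature_ids), list(expr.sample_ids), _zscore(v, axis=0)
    )
    return row, col


def _threshold_columns(X: np.ndarray, t: float) -> np.ndarray:
    """Apply the mean + t*sd upper-tail threshold to every column of X.

    Per column: elements strictly above mean + t*sd (population sd over the
    whole column) survive; survivors are divided by the maximum surviving
    value.  Columns whose support is empty, or whose maximum survivor is not
    positive (degenerate all-negative projections), come back all-zero.
    Membership additionally requires a positive value so that scores stay in
    (0, 1].
    """
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    cut = mu + t * sd
    mask = (X > cut) & (X > 0)
    masked = np.where(mask, X, -np.inf)
    mx = masked.max(axis=0)
    ok = mx > 0
    out = np.zeros_like(X)
    if np.any(ok):
        safe_mx = np.where(ok, mx, 1.0)
        np.divide(X, safe_mx[None, :], out=out, where=mask & ok[None, :])
    return out


def threshold_scores(x, t: float, ids=None) -> ScoreVector:
    """Keep the elements of ``x`` more than ``t`` population standard
    deviations above the mean of ``x``, rescaled to (0, 1] by the maximum
    survivor; everything else scores zero."""
    if t < 0:
        raise ValueError("threshold t must be >= 0")
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 1:
        raise ValueError("x must be a nonempty 1-D vector")
    if ids is None:
        ids = tuple(str(i) for i in range(x.size))
    scores = _threshold_columns(x[:, None], t)[:, 0]
    return ScoreVector(tuple(ids), scores)


# ---------------------------------------------------------------------------
# seeding
# ---------------------------------------------------------------------------

def make_random_seeds(shared_ids, n_seeds: int, rng: np.random.Generator) -> list[Seed]:
    """Draw random seeds: for each, a size k uniform on 1..|shared_ids| and
    then a uniform k-subset of the shared identifiers."""
    shared_ids = list(shared_ids)
    if not shared_ids:
        raise ValueError("shared_ids must be nonempty")
    if n_seeds <= 0:
        raise ValueError("n_seeds must be positive")
    seeds = []
    n = len(shared_ids)
    for _ in range(n_seeds):
        k = int(rng.integers(1, n + 1))
        picked = rng.choice(n, size=k, replace=False)
        seeds.append(Seed(frozenset(shared_ids[i] for i in picked)))
    return seeds


# ---------------------------------------------------------------------------
# iteration engine
# ---------------------------------------------------------------------------

def _check_shared_alignment(E1: ExpressionMatrix, E2: ExpressionMatrix) -> list[str]:
    if E1.sample_ids != E2.sample_ids:
        raise ValueError("matrices do not share an aligned sample dimension")
    return list(E1.sample_ids)


class _Projector:
    """Precomputed normalized copies of a matrix pair for repeated runs."""

    def __init__(self, E1: ExpressionMatrix, E2: ExpressionMatrix):
        self.shared_ids = tuple(_check_shared_alignment(E1, E2))
        self.feature_ids_1 = tuple(E1.feature_ids)
        self.feature_ids_2 = tuple(E2.feature_ids)
        r1, c1 = normalize_for_projection(E1)
        r2, c2 = normalize_for_projection(E2)
        self.R1, self.C1 = r1.values, c1.values
        self.R2, self.C2 = r2.values, c2.values


def _iterate_batch(
    proj: _Projector,
    S0: np.ndarray,
    t_f1: float,
    t_f2: float,
    t_s: float,
    max_iter: int,
    tol: float,
):
    """Run the four-step cycle on a batch of seed score columns.

    ``S0``: (n_shared, n_seeds) initial shared scores.  Returns a list, one
    entry per column: either None (died or did not converge) or a tuple
    (f1, f2, s, n_cycles) of final score vectors.
    """
    n_shared, m = S0.shape
    results: list = [None] * m
    active = np.arange(m)
    S = S0.copy()
    prev_f1 = np.zeros((proj.R1.shape[0], m))
    prev_f2 = np.zeros((proj.R2.shape[0], m))
    prev_s = S0.copy()
    first = True
    for cycle in range(1, max_iter + 1):
        F1 = _threshold_columns(proj.C1 @ S, t_f1)
        S_mid = _threshold_columns(proj.R1.T @ F1, t_s)
        F2 = _threshold_columns(proj.C2 @ S_mid, t_f2)
        S_new = _threshold_columns(proj.R2.T @ F2, t_s)

        alive = (F1 > 0).any(axis=0) & (S_mid > 0).any(axis=0) & (F2 > 0).any(axis=0) & (
            S_new > 0
        ).any(axis=0)
        if not first:
            same_members = (
                ((F1 > 0) == (prev_f1 > 0)).all(axis=0)
                & ((F2 > 0) == (prev_f2 > 0)).all(axis=0)
                & ((S_new > 0) == (prev_s > 0)).all(axis=0)
            )
            small_change = (
                (np.abs(F1 - prev_f1).max(axis=0) < tol)
                & (np.abs(F2 - prev_f2).max(axis=0) < tol)
                & (np.abs(S_new - prev_s).max(axis=0) < tol)
            )
            done = alive & (same_members | small_change)
        else:
            done = np.zeros(F1.shape[1], dtype=bool)
        for j in np.flatnonzero(done):
            results[active[j]] = (F1[:, j].copy(), F2[:, j].copy(), S_new[:, j].copy(), cycle)
        keep = alive & ~done
        if not np.any(keep):
            return results
        active = active[keep]
        S = S_new[:, keep]
        prev_f1 = F1[:, keep]
        prev_f2 = F2[:, keep]
        prev_s = S_new[:, keep]
        first = False
    return results  # remaining columns hit max_iter -> None


def _seed_matrix(seeds, shared_ids) -> np.ndarray:
    index = {h: i for i, h in enumerate(shared_ids)}
    S0 = np.zeros((len(shared_ids), len(seeds)))
    for j, seed in enumerate(seeds):
        for h in seed.hog_ids:
            if h not in index:
                raise ValueError(f"seed id {h!r} not in shared dimension")
            S0[index[h], j] = 1.0
    return S0


def ppa_iterate(
    E1: ExpressionMatrix,
    E2: ExpressionMatrix,
    seed: Seed,
    thresholds: tuple[float, float, float],
    max_iter: int = 100,
    tol: float = 1e-3,
) -> CoModule | None:
    """Run the four-step cycle from one seed to a fixed point.

    Cycle: (1) features of matrix 1 from the shared scores (column-z-scored
    projection); (2) shared scores from those features (row-z-scored
    projection); (3) features of matrix 2; (4) shared scores again.  Stops
    when the three membership sets repeat across consecutive cycles or all
    score changes fall below ``tol``; returns None if any score vector
    empties or ``max_iter`` is reached.
    """
    proj = _Projector(E1, E2)
    return _finalize_one(proj, seed, thresholds, max_iter, tol)


def _finalize_one(proj, seed, thresholds, max_iter, tol):
    t_f1, t_f2, t_s = thresholds
    S0 = _seed_matrix([seed], proj.shared_ids)
    res = _iterate_batch(proj, S0, t_f1, t_f2, t_s, max_iter, tol)[0]
    if res is None:
        return None
    f1, f2, s, n_cycles = res
    return CoModule(
        shared_scores=ScoreVector(proj.shared_ids, s),
        feature_scores_1=ScoreVector(proj.feature_ids_1, f1),
        feature_scores_2=ScoreVector(proj.feature_ids_2, f2),
        thresholds=(t_f1, t_f2, t_s),
        iterations=n_cycles,
        converged=True,
    )


def run_ppa_grid(
    E1: ExpressionMatrix,
    E2: ExpressionMatrix,
    seeds: list[Seed],
    feature_threshold_grid=DEFAULT_FEATURE_GRID,
    shared_threshold_grid=DEFAULT_SHARED_GRID,
    max_iter: int = 100,
    tol: float = 1e-3,
) -> list[CoModule]:
    """Run the iteration for every (seed, threshold combination) and collapse
    identical fixed points.

    The same feature threshold is applied to both matrices for each grid
    value, so the combinations are the product of the feature grid with the
    shared grid.  Fixed points with identical membership triples (features
    of each matrix, shared set) are collapsed to one co-module carrying a
    count of the seeds that reached it; non-converged or emptied seeds are
    dropped (count logged).
    """
    if not seeds:
        return []
    if len(feature_threshold_grid) == 0 or len(shared_threshold_grid) == 0:
        raise ValueError("threshold grids must be nonempty")
    proj = _Projector(E1, E2)
    S0 = _seed_matrix(seeds, proj.shared_ids)
    distinct: dict = {}
    order: list = []
    n_dropped = 0
    for t_f, t_s in product(feature_threshold_grid, shared_threshold_grid):
        batch = _iterate_batch(proj, S0, t_f, t_f, t_s, max_iter, tol)
        for res in batch:
            if res is None:
                n_dropped += 1
                continue
            f1, f2, s, n_cycles = res
            key = (
                frozenset(np.flatnonzero(f1 > 0).tolist()),
                frozenset(np.flatnonzero(f2 > 0).tolist()),
                frozenset(np.flatnonzero(s > 0).tolist()),
            )
            if key in distinct:
                distinct[key].n_seeds += 1
            else:
                cm = CoModule(
                    shared_scores=ScoreVector(proj.shared_ids, s),
                    feature_scores_1=ScoreVector(proj.feature_ids_1, f1),
                    feature_scores_2=ScoreVector(proj.feature_ids_2, f2),
                    thresholds=(float(t_f), float(t_f), float(t_s)),
                    iterations=n_cycles,
                    converged=True,
                )
                distinct[key] = cm
                order.append(cm)
    if n_dropped:
        logger.info("run_ppa_grid: %d seed/threshold runs did not converge", n_dropped)
    return order


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _sv_to_obj(sv: ScoreVector) -> dict:
    members = sv.member_ids()
    idx = {i: k for k, i in enumerate(sv.ids)}
    return {
        "ids": members,
        "scores": [round(float(sv.scores[idx[i]]), 4) for i in members],
    }


def _sv_from_obj(obj: dict, universe: list[str]) -> ScoreVector:
    scores = np.zeros(len(universe))
    pos = {i: k for k, i in enumerate(universe)}
    for i, s in zip(obj["ids"], obj["scores"]):
        scores[pos[i]] = s
    return ScoreVector(tuple(universe), scores)


def write_comodules_json(comodules: list[CoModule], path) -> None:
    """One JSON document for a whole run: universes once, then per
    co-module the member ids, member scores (4 decimals), thresholds,
    iteration count and seed provenance."""
    if comodules:
        universes = {
            "shared": list(comodules[0].shared_scores.ids),
            "features_1": list(comodules[0].feature_scores_1.ids),
            "features_2": list(comodules[0].feature_scores_2.ids),
        }
    else:
        universes = {"shared": [], "features_1": [], "features_2": []}
    doc = {
        "universes": universes,
        "comodules": [
            {
                "id": f"CM{k+1:03d}",
                "shared": _sv_to_obj(cm.shared_scores),
                "features_1": _sv_to_obj(cm.feature_scores_1),
                "features_2": _sv_to_obj(cm.feature_scores_2),
                "thresholds": list(cm.thresholds),
                "iterations": cm.iterations,
                "converged": cm.converged,
                "n_seeds": cm.n_seeds,
            }
            for k, cm in enumerate(comodules)
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_comodules_json(path) -> list[CoModule]:
    with open(path) as fh:
        doc = json.load(fh)
    u = doc["universes"]
    out = []
    for obj in doc["comodules"]:
        out.append(
            CoModule(
                shared_scores=_sv_from_obj(obj["shared"], u["shared"]),
                feature_scores_1=_sv_from_obj(obj["features_1"], u["features_1"]),
                feature_scores_2=_sv_from_obj(obj["features_2"], u["features_2"]),
                thresholds=tuple(obj["thresholds"]),
                iterations=obj["iterations"],
                converged=obj["converged"],
                n_seeds=obj["n_seeds"],
            )
        )
    return out


def write_comodules_tsv(comodules: list[CoModule], path) -> None:
    """Flat table: co_module_id, dimension, element_id, score."""
    with open(path, "w") as fh:
        fh.write("co_module_id\tdimension\telement_id\tscore\n")
        for k, cm in enumerate(comodules):
            cmid = f"CM{k+1:03d}"
            for dim, sv in (
                ("shared", cm.shared_scores),
                ("features_1", cm.feature_scores_1),
                ("features_2", cm.feature_scores_2),
            ):
                for i in sv.member_ids():
                    s = sv.scores[sv.ids.index(i)]
                    fh.write(f"{cmid}\t{dim}\t{i}\t{s:.4f}\n")
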