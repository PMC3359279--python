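"""End-to-end orchestration of the two discovery experiments and the
replicate control.

Modes
-----
organ-shared
    Merge each species' organ samples into homologous organ groups (HOGs),
    run the ping-pong grid with HOGs as the shared dimension, post-process,
    collapse probes to genes, and score expression conservation (gamma)
    against the shuffled-orthology null.
gene-shared
    Restrict both matrices to one-to-one orthologous genes (one probe set
    per gene, chosen at random under the run seed), transpose so the
    ortholog pairs form the shared dimension, and run the same engine; the
    co-modules then pair homologous organ sets across species.
replicate-control
    Split one species' duplicate arrays into two organ-aligned matrices and
    run the engine on them; gamma computed between the two replicate sides
    bounds what the noise level allows.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import conservation, postprocess
from .data import (
    ExpressionMatrix,
    HOGMap,
    OrthologyMap,
    ProbeGeneMap,
    collapse_probes_to_genes,
    merge_into_hogs,
    read_expression_matrix,
    read_hog_map,
    read_orthology,
    read_probe_gene_map,
    split_replicates,
)
from .ppa import (
    DEFAULT_FEATURE_GRID,
    DEFAULT_SHARED_GRID,
    make_random_seeds,
    run_ppa_grid,
    write_comodules_json,
    write_comodules_tsv,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "run_organ_shared", "run_gene_shared", "run_replicate_control"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run (defaults follow the study design:
    10,000 seeds, feature thresholds 2.5-6, shared thresholds 1-4.5,
    redundancy cut 0.8, minimum 10 features per species, 10 null
    reshufflings)."""

    mode: str = "organ-shared"
    expr1: str | None = None
    expr2: str | None = None
    hog_map: str | None = None
    orthology: str | None = None
    probe_map: str | None = None
    n_seeds: int = 10_000
    feature_threshold_grid: tuple = DEFAULT_FEATURE_GRID
    shared_threshold_grid: tuple = DEFAULT_SHARED_GRID
    product_cut: float = 0.8
    min_probes: int = 10
    null_reps: int = 10
    max_iter: int = 100
    tol: float = 1e-3
    seed: int = 0
    out_dir: str = "copong_out"
    species1: str = "species1"
    species2: str = "species2"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        for key in ("feature_threshold_grid", "shared_threshold_grid"):
            if key in raw:
                raw[key] = tuple(float(x) for x in raw[key])
        return cls(**raw)


def _align_shared(E1: ExpressionMatrix, E2: ExpressionMatrix) -> ExpressionMatrix:
    """Reorder E2's columns to E1's shared-id order."""
    if set(E1.sample_ids) != set(E2.sample_ids):
        raise ValueError("shared dimensions differ between the two matrices")
    if E1.sample_ids == E2.sample_ids:
        return E2
    idx = {s: j for j, s in enumerate(E2.sample_ids)}
    cols = [idx[s] for s in E1.sample_ids]
    return ExpressionMatrix(
        E2.species, list(E2.feature_ids), list(E1.sample_ids), E2.values[:, cols],
        replicate_of=E2.replicate_of,
    )


def _transpose(expr: ExpressionMatrix) -> ExpressionMatrix:
    return ExpressionMatrix(
        expr.species, list(expr.sample_ids), list(expr.feature_ids), expr.values.T
    )


def run_organ_shared(
    E1: ExpressionMatrix,
    E2: ExpressionMatrix,
    hogs: HOGMap,
    orth: OrthologyMap,
    probes: ProbeGeneMap,
    config: RunConfig,
    rng: np.random.Generator,
):
    """HOG-shared discovery + postprocess + conservation scoring.

    Returns (filtered co-modules, gamma rows, stage counts)."""
    M1 = merge_into_hogs(E1, hogs)
    M2 = _align_shared(M1, merge_into_hogs(E2, hogs))
    seeds = make_random_seeds(M1.sample_ids, config.n_seeds, rng)
    raw = run_ppa_grid(
        M1, M2, seeds,
        config.feature_threshold_grid, config.shared_threshold_grid,
        config.max_iter, config.tol,
    )
    kept, counts = postprocess.postprocess_cascade(raw, config.product_cut, config.min_probes)
    fam = conservation.build_families(orth)
    array_1 = collapse_probes_to_genes(set(M1.feature_ids), probes)
    array_2 = collapse_probes_to_genes(set(M2.feature_ids), probes)
    shuffles = [
        conservation.build_families(conservation.shuffle_orthologs(orth, rng))
        for _ in range(config.null_reps)
    ]
    gamma_rows = []
    for k, cm in enumerate(kept):
        g1 = collapse_probes_to_genes(cm.feature_scores_1.membership, probes)
        g2 = collapse_probes_to_genes(cm.feature_scores_2.membership, probes)
        res = conservation.gamma(g1, g2, fam, array_1, array_2)
        null = conservation.null_gamma(
            g1, g2, orth, array_1, array_2, n_reps=config.null_reps, shuffled=shuffles
        )
        gamma_rows.append(
            {
                "co_module_id": f"CM{k+1:03d}",
                "n_og": res.n_og,
                "nfam_h": res.nfam_h,
                "nfam_m": res.nfam_m,
                "gamma": res.gamma,
                "null_mean_gamma": null,
            }
        )
    return kept, gamma_rows, counts, raw


def run_gene_shared(
    E1: ExpressionMatrix,
    E2: ExpressionMatrix,
    hogs: HOGMap,
    orth: OrthologyMap,
    probes: ProbeGeneMap,
    config: RunConfig,
    rng: np.random.Generator,
):
    """Ortholog-pair-shared discovery.

    Both matrices are HOG-merged, restricted to one-to-one ortholog pairs
    with unambiguous probes on both arrays (one probe set per gene picked at
    random), and transposed so pairs are the shared columns.  Returns
    (co-modules, pair ids, stage counts).
    """
    M1 = merge_into_hogs(E1, hogs)
    M2 = merge_into_hogs(E2, hogs)
    unamb = probes.unambiguous()
    probes_by_gene_1: dict[str, list[str]] = {}
    probes_by_gene_2: dict[str, list[str]] = {}
    feats_1, feats_2 = set(M1.feature_ids), set(M2.feature_ids)
    for p, g in unamb.items():
        if p in feats_1:
            probes_by_gene_1.setdefault(g, []).append(p)
        elif p in feats_2:
            probes_by_gene_2.setdefault(g, []).append(p)
    one, _ = orth.classify()
    usable = sorted(
        (a, b) for a, b in one if a in probes_by_gene_1 and b in probes_by_gene_2
    )
    if not usable:
        raise ValueError("no one-to-one ortholog pair is measured on both arrays")
    pair_ids = [f"{a}|{b}" for a, b in usable]
    rows_1, rows_2 = [], []
    for a, b in usable:
        ps1 = sorted(probes_by_gene_1[a])
        ps2 = sorted(probes_by_gene_2[b])
        rows_1.append(ps1[int(rng.integers(len(ps1)))])
        rows_2.append(ps2[int(rng.integers(len(ps2)))])
    G1 = _transpose_pairs(M1, rows_1, pair_ids)
    G2 = _transpose_pairs(M2, rows_2, pair_ids)
    seeds = make_random_seeds(pair_ids, config.n_seeds, rng)
    raw = run_ppa_grid(
        G1, G2, seeds,
        config.feature_threshold_grid, config.shared_threshold_grid,
        config.max_iter, config.tol,
    )
    kept, counts = postprocess.postprocess_cascade(
        raw, config.product_cut, min_count=1
    )
    return kept, pair_ids, counts, raw


def _transpose_pairs(M: ExpressionMatrix, probe_rows: list[str], pair_ids: list[str]) -> ExpressionMatrix:
    sub = M.subset_features(probe_rows)
    return ExpressionMatrix(M.species, list(M.sample_ids), pair_ids, sub.values.T)


def run_replicate_control(
    expr: ExpressionMatrix, config: RunConfig, rng: np.random.Generator
):
    """Split a duplicate-array matrix and run the engine on the two halves;
    gamma is the probe-set overlap between the two replicate sides.

    Returns (co-modules, gamma rows, stage counts)."""
    Ea, Eb = split_replicates(expr, rng)
    seeds = make_random_seeds(Ea.sample_ids, config.n_seeds, rng)
    raw = run_ppa_grid(
        Ea, Eb, seeds,
        config.feature_threshold_grid, config.shared_threshold_grid,
        config.max_iter, config.tol,
    )
    kept, counts = postprocess.postprocess_cascade(raw, config.product_cut, config.min_probes)
    gamma_rows = []
    for k, cm in enumerate(kept):
        res = conservation.replicate_gamma(cm)
        gamma_rows.append(
            {
                "co_module_id": f"CM{k+1:03d}",
                "n_og": res.n_og,
                "nfam_h": res.nfam_h,
                "nfam_m": res.nfam_m,
                "gamma": res.gamma,
                "null_mean_gamma": None,
            }
        )
    return kept, gamma_rows, counts, raw


def _write_gamma_tsv(rows, path) -> None:
    with open(path, "w") as fh:
        fh.write("co_module_id\tn_og\tnfam_h\tnfam_m\tgamma\tnull_mean_gamma\n")
        for r in rows:
            g = "NA" if r["gamma"] is None else f"{r['gamma']:.6f}"
            n = "NA" if r["null_mean_gamma"] is None else f"{r['null_mean_gamma']:.6f}"
            fh.write(f"{r['co_module_id']}\t{r['n_og']}\t{r['nfam_h']}\t{r['nfam_m']}\t{g}\t{n}\n")


def run_pipeline(config: RunConfig) -> dict:
    """File-level entry point: read the configured inputs, dispatch on mode,
    and write co-module JSON/TSV, the gamma table and a run log into the
    output directory.  Outputs are fully determined by (inputs, config,
    seed); input files are never modified."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    if config.mode not in {"organ-shared", "gene-shared", "replicate-control"}:
        raise ValueError(f"unknown mode: {config.mode}")

    if config.mode == "replicate-control":
        if config.expr1 is None or config.hog_map is None:
            raise ValueError("replicate-control mode needs expr1 and hog_map (organ labels)")
        E1 = read_expression_matrix(config.expr1, config.species1)
        hogs = read_hog_map(config.hog_map)
        E1.replicate_of = {s: hogs.entries[(config.species1, s)] for s in E1.sample_ids}
        kept, gamma_rows, counts, raw = run_replicate_control(E1, config, rng)
    else:
        needed = [config.expr1, config.expr2, config.hog_map, config.orthology, config.probe_map]
        if any(x is None for x in needed):
            raise ValueError(f"mode {config.mode} needs expr1, expr2, hog_map, orthology, probe_map")
        E1 = read_expression_matrix(config.expr1, config.species1)
        E2 = read_expression_matrix(config.expr2, config.species2)
        hogs = read_hog_map(config.hog_map)
        orth = read_orthology(config.orthology)
        probes = read_probe_gene_map(config.probe_map)
        if config.mode == "organ-shared":
            kept, gamma_rows, counts, raw = run_organ_shared(E1, E2, hogs, orth, probes, config, rng)
        else:
            kept, _, counts, raw = run_gene_shared(E1, E2, hogs, orth, probes, config, rng)
            gamma_rows = []

    write_comodules_json(kept, out / "comodules.json")
    write_comodules_tsv(kept, out / "comodules.tsv")
    _write_gamma_tsv(gamma_rows, out / "gamma.tsv")
    log = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in dataclasses.asdict(config).items()},
        "stage_counts": counts,
        "n_comodules": len(kept),
    }
    with open(out / "run.log", "w") as fh:
        json.dump(log, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return {
        "comodules": kept,
        "grid_comodules": raw,
        "gamma": gamma_rows,
        "stage_counts": counts,
        "out_dir": str(out),
    }
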