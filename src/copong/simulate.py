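"""Synthetic paired-species expression data with planted co-modules.

The generator emulates the structure of a two-species organ expression
study: a shared set of homologous organ groups (HOGs) with technical
replicate samples, an ortholog-pair list mixing one-to-one and many-to-many
families, genes measured by one or more probe sets, and log-scale
expression that is Gaussian baseline noise plus an additive over-expression
effect for planted (module) genes in planted HOGs.  A configurable fraction
``conservation_rho`` of each planted module's species-1 genes have their
orthologs planted on the species-2 side; the remainder of the species-2
side is filled from unrelated families, so the conservation rate of the
planted truth equals rho by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import ExpressionMatrix, HOGMap, OrthologyMap, ProbeGeneMap, collapse_probes_to_genes
from .ppa import CoModule

__all__ = [
    "SimConfig",
    "PlantedModule",
    "SyntheticTruth",
    "simulate_pair",
    "simulate_replicate_pair",
    "recovery_score",
]


@dataclass
class SimConfig:
    """Study-design knobs for the generator.

    Defaults describe a small two-species organ atlas: 12 HOGs with two
    replicate arrays each, 200 gene families of which 86.6% are one-to-one
    orthologs, genes carried by 1-3 probe sets, and 3 planted co-modules of
    3-4 organs and 10-14 genes per species, over-expressed by 5 noise
    standard deviations, with 80% of planted genes conserved across the
    species boundary.  Technical replicate noise is half the biological
    baseline noise.  Module gene sets are kept sparse relative to the gene
    universe (about 5%) because the upper-tail thresholding detects genes
    standing out against the per-organ score distribution.
    """

    n_hogs: int = 12
    samples_per_hog_per_species: int = 2
    n_families: int = 200
    fraction_one_to_one: float = 0.866
    max_family_size: int = 3
    probes_per_gene_distribution: dict[int, float] = field(
        default_factory=lambda: {1: 0.7, 2: 0.25, 3: 0.05}
    )
    n_planted: int = 3
    organs_per_module: tuple[int, int] = (3, 4)
    genes_per_module: tuple[int, int] = (10, 14)
    conservation_rho: float = 0.8
    effect_delta: float = 5.0
    noise_sd: float = 1.0
    tech_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_hogs", "samples_per_hog_per_species", "n_families", "n_planted"):
            if getattr(self, name) < (0 if name == "n_planted" else 1):
                raise ValueError(f"{name} must be positive")
        for name in ("fraction_one_to_one", "conservation_rho"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.effect_delta < 0:
            raise ValueError("effect_delta must be >= 0")
        if abs(sum(self.probes_per_gene_distribution.values()) - 1.0) > 1e-9:
            raise ValueError("probes_per_gene_distribution must sum to 1")
        if self.n_planted * self.organs_per_module[1] > self.n_hogs:
            raise ValueError("planted modules need more HOGs than available")


@dataclass
class PlantedModule:
    hogs: frozenset[str]
    genes_1: frozenset[str]
    genes_2: frozenset[str]
    conserved_families: frozenset[int]


@dataclass
class SyntheticTruth:
    modules: list[PlantedModule]
    hog_ids: list[str]


def _draw_range(rng, lo_hi: tuple[int, int]) -> int:
    lo, hi = lo_hi
    return int(rng.integers(lo, hi + 1))


def _build_orthology(cfg: SimConfig, rng):
    """Families, gene lists per species, and the pair list."""
    n_one = round(cfg.fraction_one_to_one * cfg.n_families)
    families = []  # (genes_1, genes_2)
    pairs = set()
    for k in range(cfg.n_families):
        if k < n_one:
            g1, g2 = [f"h{k:04d}"], [f"m{k:04d}"]
        else:
            while True:
                a = int(rng.integers(1, cfg.max_family_size + 1))
                b = int(rng.integers(1, cfg.max_family_size + 1))
                if a > 1 or b > 1:
                    break
            g1 = [f"h{k:04d}_{i}" for i in range(a)]
            g2 = [f"m{k:04d}_{i}" for i in range(b)]
        for x in g1:
            for y in g2:
                pairs.add((x, y))
        families.append((g1, g2))
    return families, OrthologyMap(pairs)


def _assign_probes(genes: list[str], prefix: str, cfg: SimConfig, rng):
    counts = np.array(sorted(cfg.probes_per_gene_distribution))
    probs = np.array([cfg.probes_per_gene_distribution[c] for c in counts], dtype=float)
    entries: dict[str, set[str]] = {}
    probes_of: dict[str, list[str]] = {}
    for g in genes:
        n = int(rng.choice(counts, p=probs))
        ps = [f"{prefix}{g}_p{i}" for i in range(n)]
        probes_of[g] = ps
        for p in ps:
            entries[p] = {g}
    return entries, probes_of


def _plant_modules(cfg: SimConfig, families, rng):
    """Choose disjoint HOG sets and disjoint families for each module."""
    hog_ids = [f"HOG{h:02d}" for h in range(cfg.n_hogs)]
    free_hogs = list(hog_ids)
    free_fams = list(range(len(families)))
    modules = []
    for _ in range(cfg.n_planted):
        n_org = _draw_range(rng, cfg.organs_per_module)
        n_gen = _draw_range(rng, cfg.genes_per_module)
        if n_org > len(free_hogs):
            raise ValueError("not enough free HOGs to plant module")
        picked_h = rng.choice(len(free_hogs), size=n_org, replace=False)
        hogs = frozenset(free_hogs[i] for i in picked_h)
        free_hogs = [h for h in free_hogs if h not in hogs]

        n_cons = round(cfg.conservation_rho * n_gen)
        n_fill = n_gen - n_cons
        if n_gen + n_fill > len(free_fams):
            raise ValueError("not enough free gene families to plant module")
        picked = rng.choice(len(free_fams), size=n_gen + n_fill, replace=False)
        fam_ids = [free_fams[i] for i in picked]
        core, fill = fam_ids[:n_gen], fam_ids[n_gen:]
        free_fams = [f for f in free_fams if f not in set(fam_ids)]

        genes_1 = frozenset(families[k][0][0] for k in core)
        conserved = core[:n_cons]
        genes_2 = frozenset(families[k][1][0] for k in conserved) | frozenset(
            families[k][1][0] for k in fill
        )
        modules.append(PlantedModule(hogs, genes_1, genes_2, frozenset(conserved)))
    return hog_ids, modules


def _expression_for_species(
    cfg: SimConfig,
    species: str,
    probes_of: dict[str, list[str]],
    genes: list[str],
    hog_ids: list[str],
    planted: list[tuple[frozenset[str], frozenset[str]]],  # (hogs, genes) per module
    rng,
):
    """Biological signal per probe x HOG plus per-replicate technical noise.

    Returns the replicate-sample matrix, the (species, sample)->HOG map
    entries, and the per-replicate matrices (used for replicate splits).
    """
    probe_ids = [p for g in genes for p in probes_of[g]]
    probe_gene = np.array([g for g in genes for _ in probes_of[g]])
    n_p, n_h = len(probe_ids), len(hog_ids)
    bio = rng.normal(0.0, cfg.noise_sd, size=(n_p, n_h))
    hog_index = {h: j for j, h in enumerate(hog_ids)}
    for hogs, mod_genes in planted:
        rows = np.isin(probe_gene, list(mod_genes))
        cols = [hog_index[h] for h in hogs]
        bio[np.ix_(rows, cols)] += cfg.effect_delta * cfg.noise_sd
    reps = []
    for _ in range(cfg.samples_per_hog_per_species):
        reps.append(bio + rng.normal(0.0, cfg.tech_sd, size=bio.shape))
    sample_ids, cols, entries, replicate_of = [], [], {}, {}
    for j, h in enumerate(hog_ids):
        for r in range(cfg.samples_per_hog_per_species):
            sid = f"{species}_{h}_r{r+1}"
            sample_ids.append(sid)
            cols.append(reps[r][:, j])
            entries[(species, sid)] = h
            replicate_of[sid] = h
    expr = ExpressionMatrix(
        species=species,
        feature_ids=probe_ids,
        sample_ids=sample_ids,
        values=np.column_stack(cols),
        replicate_of=replicate_of,
    )
    return expr, entries, probe_ids, reps


def simulate_pair(config: SimConfig):
    """Generate one paired-species data set.

    Returns (E1, E2, hogs, orth, probes, truth): replicate-sample
    expression matrices for the two species, the HOG map covering all their
    samples, the ortholog pair list, the probe->gene map (both species'
    probes in one map), and the planted truth.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    families, orth = _build_orthology(config, rng)
    hog_ids, modules = _plant_modules(config, families, rng)

    genes_1 = [g for f in families for g in f[0]]
    genes_2 = [g for f in families for g in f[1]]
    entries_1, probes_of_1 = _assign_probes(genes_1, "", config, rng)
    entries_2, probes_of_2 = _assign_probes(genes_2, "", config, rng)

    E1, map_1, _, _ = _expression_for_species(
        config, "species1", probes_of_1, genes_1, hog_ids,
        [(m.hogs, m.genes_1) for m in modules], rng,
    )
    E2, map_2, _, _ = _expression_for_species(
        config, "species2", probes_of_2, genes_2, hog_ids,
        [(m.hogs, m.genes_2) for m in modules], rng,
    )
    hogs = HOGMap({**map_1, **map_2})
    probes = ProbeGeneMap({**entries_1, **entries_2})
    truth = SyntheticTruth(modules, hog_ids)
    return E1, E2, hogs, orth, probes, truth


def simulate_replicate_pair(config: SimConfig):
    """Generate a single species' data as two replicate matrices.

    Both matrices hold the same biological signal (planted structure
    included) with independent technical noise, columns aligned by organ,
    for estimating the replicate noise ceiling on gamma.
    """
    config.validate()
    if config.samples_per_hog_per_species != 2:
        raise ValueError("replicate pair generation requires exactly 2 replicates per organ")
    rng = np.random.default_rng(config.seed)
    families, _ = _build_orthology(config, rng)
    hog_ids, modules = _plant_modules(config, families, rng)
    genes_1 = [g for f in families for g in f[0]]
    _, probes_of = _assign_probes(genes_1, "", config, rng)
    _, _, probe_ids, reps = _expression_for_species(
        config, "species1", probes_of, genes_1, hog_ids,
        [(m.hogs, m.genes_1) for m in modules], rng,
    )
    def one(vals, tag):
        return ExpressionMatrix(
            species="species1",
            feature_ids=list(probe_ids),
            sample_ids=list(hog_ids),
            values=vals,
        )
    truth = SyntheticTruth(modules, hog_ids)
    return one(reps[0], "a"), one(reps[1], "b"), truth


def _jaccard(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def recovery_score(
    truth: SyntheticTruth,
    found: list[CoModule],
    probes: ProbeGeneMap | None = None,
) -> list[dict]:
    """Best-match Jaccard of each planted module against the found co-modules.

    Feature memberships are collapsed to gene level when a probe map is
    given.  Each planted module is matched to the found co-module with the
    highest mean Jaccard over the three dimensions (HOGs, species-1 genes,
    species-2 genes); unmatched modules score 0 everywhere.
    """
    prepared = []
    for cm in found:
        f1 = cm.feature_scores_1.membership
        f2 = cm.feature_scores_2.membership
        if probes is not None:
            f1 = frozenset(collapse_probes_to_genes(f1, probes))
            f2 = frozenset(collapse_probes_to_genes(f2, probes))
        prepared.append((cm.shared_scores.membership, f1, f2))
    out = []
    for mod in truth.modules:
        best = {"jaccard_hogs": 0.0, "jaccard_genes_1": 0.0, "jaccard_genes_2": 0.0,
                "mean_jaccard": 0.0, "matched": None}
        for k, (sh, f1, f2) in enumerate(prepared):
            jh = _jaccard(mod.hogs, sh)
            j1 = _jaccard(mod.genes_1, f1)
            j2 = _jaccard(mod.genes_2, f2)
            mean = (jh + j1 + j2) / 3.0
            if mean > best["mean_jaccard"]:
                best = {"jaccard_hogs": jh, "jaccard_genes_1": j1,
                        "jaccard_genes_2": j2, "mean_jaccard": mean, "matched": k}
        out.append(best)
    return out
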