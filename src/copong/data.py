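"""Core data containers and table I/O.

Expression matrices are features x samples (probe sets or genes in rows,
organs or homologous organ groups in columns), on a log-like normalized
scale.  Normalization of raw arrays is out of scope: values are consumed
as produced upstream.  All tables are plain TSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "HOGMap",
    "OrthologyMap",
    "ProbeGeneMap",
    "GeneAttributes",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_hog_map",
    "read_orthology",
    "write_orthology",
    "read_probe_gene_map",
    "read_gene_attributes",
    "merge_into_hogs",
    "collapse_probes_to_genes",
    "split_replicates",
]


def _check_unique(ids, what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise ValueError(f"duplicate {what} id: {x!r}")
        seen.add(x)


@dataclass
class ExpressionMatrix:
    """A features x samples log-scale expression matrix for one species.

    Parameters
    ----------
    species : str
        Species label, e.g. ``"human"`` or ``"mouse"``.
    feature_ids : list of str
        Row identifiers (probe sets or genes), unique, in matrix order.
    sample_ids : list of str
        Column identifiers (organs or HOGs), unique, in matrix order.
    values : ndarray of shape (n_features, n_samples)
        Finite float expression values.
    replicate_of : dict, optional
        Maps a sample id to its organ label when columns are technical
        replicates of organs.
    """

    species: str
    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    replicate_of: dict[str, str] | None = None

    def __post_init__(self) -> None:
        _check_unique(self.feature_ids, "feature")
        _check_unique(self.sample_ids, "sample")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must all be finite")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_features(self, keep: list[str]) -> "ExpressionMatrix":
        """Return a copy restricted to ``keep`` rows, in the given order."""
        idx = {f: i for i, f in enumerate(self.feature_ids)}
        rows = [idx[f] for f in keep]
        return replace(self, feature_ids=list(keep), values=self.values[rows, :])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)


@dataclass
class HOGMap:
    """Mapping of organ samples to homologous organ groups (HOGs).

    ``entries[(species, sample_id)] = hog_id``.  A HOG groups anatomically
    homologous organ samples across the two species so they can serve as the
    shared dimension of the co-module analysis.
    """

    entries: dict[tuple[str, str], str]

    def hogs(self) -> list[str]:
        out: list[str] = []
        for h in self.entries.values():
            if h not in out:
                out.append(h)
        return out

    def for_species(self, species: str) -> dict[str, str]:
        return {s: h for (sp, s), h in self.entries.items() if sp == species}


@dataclass
class OrthologyMap:
    """Set of ortholog pairs (gene of species 1, gene of species 2).

    A pair is *one-to-one* when both of its genes occur in exactly one pair;
    all other pairs are classified many-to-many.
    """

    pairs: set[tuple[str, str]]

    def __post_init__(self) -> None:
        self.pairs = set(self.pairs)

    def genes1(self) -> set[str]:
        return {a for a, _ in self.pairs}

    def genes2(self) -> set[str]:
        return {b for _, b in self.pairs}

    def classify(self) -> tuple[set[tuple[str, str]], set[tuple[str, str]]]:
        """Partition pairs into (one_to_one, many_to_many)."""
        deg1: dict[str, int] = {}
        deg2: dict[str, int] = {}
        for a, b in self.pairs:
            deg1[a] = deg1.get(a, 0) + 1
            deg2[b] = deg2.get(b, 0) + 1
        one = {(a, b) for a, b in self.pairs if deg1[a] == 1 and deg2[b] == 1}
        return one, self.pairs - one

    def summary(self) -> dict[str, float]:
        """Counts of pair classes and the one-to-one percentage."""
        one, many = self.classify()
        n = len(self.pairs)
        return {
            "n_pairs": n,
            "n_one_to_one": len(one),
            "n_many_to_many": len(many),
            "pct_one_to_one": 100.0 * len(one) / n if n else float("nan"),
        }


@dataclass
class ProbeGeneMap:
    """Probe set -> gene id(s).  Probes hitting more than one gene are
    ambiguous and excluded from gene-level outputs."""

    entries: dict[str, set[str]]

    def unambiguous(self) -> dict[str, str]:
        return {p: next(iter(g)) for p, g in self.entries.items() if len(g) == 1}


@dataclass
class GeneAttributes:
    """Per-gene dN (nonsynonymous) and dS (synonymous) substitution rates.

    The dN/dS ratio is defined only where dS > 0; genes with undefined
    ratios are excluded from rank tests.
    """

    table: pd.DataFrame  # index: gene id; columns: dN, dS

    def ratios(self) -> pd.Series:
        ok = self.table["dS"] > 0
        r = self.table.loc[ok, "dN"] / self.table.loc[ok, "dS"]
        return r.dropna()


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_expression_matrix(path, species: str) -> ExpressionMatrix:
    """Read a TSV expression matrix (header = sample ids, first column =
    feature ids, numeric body; no missing values allowed)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"empty expression matrix file: {path}")
    _check_unique(df.index.astype(str), "feature")
    _check_unique(df.columns.astype(str), "sample")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError:
        for j, col in enumerate(df.columns):
            for i, v in enumerate(df[col]):
                try:
                    float(v)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"non-numeric value {v!r} at row {df.index[i]!r}, "
                        f"column {col!r}"
                    ) from None
        raise
    return ExpressionMatrix(
        species=species,
        feature_ids=[str(x) for x in df.index],
        sample_ids=[str(x) for x in df.columns],
        values=values,
    )


def write_expression_matrix(expr: ExpressionMatrix, path) -> None:
    expr.to_frame().to_csv(path, sep="\t", index_label="feature_id")


def read_hog_map(path) -> HOGMap:
    """3-column TSV: species, sample_id, hog_id (no header required)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["species", "sample_id", "hog_id"], dtype=str)
    entries = {(r.species, r.sample_id): r.hog_id for r in df.itertuples()}
    return HOGMap(entries)


def write_hog_map(hogs: HOGMap, path) -> None:
    with open(path, "w") as fh:
        for (sp, s), h in hogs.entries.items():
            fh.write(f"{sp}\t{s}\t{h}\n")


def read_orthology(path) -> OrthologyMap:
    """2-column TSV of ortholog pairs."""
    df = pd.read_csv(path, sep="\t", header=None, names=["g1", "g2"], dtype=str)
    return OrthologyMap(set(zip(df.g1, df.g2)))


def write_orthology(orth: OrthologyMap, path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(orth.pairs):
            fh.write(f"{a}\t{b}\n")


def read_probe_gene_map(path) -> ProbeGeneMap:
    """2-column TSV (probe, gene); multi-gene probes appear on several rows."""
    df = pd.read_csv(path, sep="\t", header=None, names=["probe", "gene"], dtype=str)
    entries: dict[str, set[str]] = {}
    for r in df.itertuples():
        entries.setdefault(r.probe, set()).add(r.gene)
    return ProbeGeneMap(entries)


def write_probe_gene_map(pmap: ProbeGeneMap, path) -> None:
    with open(path, "w") as fh:
        for p in sorted(pmap.entries):
            for g in sorted(pmap.entries[p]):
                fh.write(f"{p}\t{g}\n")


def read_gene_attributes(path) -> GeneAttributes:
    """3-column TSV: gene, dN, dS."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "dN", "dS"])
    df = df.set_index("gene")
    return GeneAttributes(df.astype(float))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def merge_into_hogs(expr: ExpressionMatrix, hogs: HOGMap) -> ExpressionMatrix:
    """Average organ sample columns into one column per HOG.

    Each output cell is the arithmetic mean of the feature's values over the
    samples mapped to that HOG.  HOG column order follows first appearance in
    the map restricted to this matrix's samples; feature order is preserved.
    """
    smap = hogs.for_species(expr.species)
    for s in expr.sample_ids:
        if s not in smap:
            raise ValueError(f"sample {s!r} missing from HOG map for species {expr.species!r}")
    hog_order: list[str] = []
    groups: dict[str, list[int]] = {}
    for j, s in enumerate(expr.sample_ids):
        h = smap[s]
        if h not in groups:
            groups[h] = []
            hog_order.append(h)
        groups[h].append(j)
    for h, cols in groups.items():
        if len(cols) < 2:
            logger.warning("HOG %r represented by only %d sample(s)", h, len(cols))
    out = np.column_stack([expr.values[:, groups[h]].mean(axis=1) for h in hog_order])
    return ExpressionMatrix(
        species=expr.species,
        feature_ids=list(expr.feature_ids),
        sample_ids=hog_order,
        values=out,
    )


def collapse_probes_to_genes(feature_set, pmap: ProbeGeneMap) -> set[str]:
    """Map a set of probe ids to gene ids.

    Only probes mapping unambiguously to a single gene contribute; ambiguous
    probes are dropped, unknown probes are ignored (count logged).
    """
    unamb = pmap.unambiguous()
    unknown = sum(1 for p in feature_set if p not in pmap.entries)
    if unknown:
        logger.info("collapse_probes_to_genes: %d unknown probe(s) ignored", unknown)
    return {unamb[p] for p in feature_set if p in unamb}


def split_replicates(
    expr: ExpressionMatrix, rng: np.random.Generator
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Randomly distribute the two replicates of each organ into two matrices.

    Requires ``replicate_of`` and exactly two replicate columns per organ.
    Output columns are labelled with organ names, paired across the two
    matrices, in order of first appearance of each organ.
    """
    if expr.replicate_of is None:
        raise ValueError("split_replicates requires replicate_of to be set")
    organs: list[str] = []
    by_organ: dict[str, list[int]] = {}
    for j, s in enumerate(expr.sample_ids):
        organ = expr.replicate_of.get(s)
        if organ is None:
            raise ValueError(f"sample {s!r} has no organ in replicate_of")
        if organ not in by_organ:
            by_organ[organ] = []
            organs.append(organ)
        by_organ[organ].append(j)
    for organ, cols in by_organ.items():
        if len(cols) != 2:
            raise ValueError(f"organ {organ!r} has {len(cols)} replicates, expected 2")
    cols_a, cols_b = [], []
    for organ in organs:
        j1, j2 = by_organ[organ]
        if rng.random() < 0.5:
            cols_a.append(j1)
            cols_b.append(j2)
        else:
            cols_a.append(j2)
            cols_b.append(j1)

    def build(cols):
        return ExpressionMatrix(
            species=expr.species,
            feature_ids=list(expr.feature_ids),
            sample_ids=list(organs),
            values=expr.values[:, cols],
        )

    a, b = build(cols_a), build(cols_b)
    # keep track of which original replicate column each organ slot holds
    a.replicate_of = {organ: expr.sample_ids[j] for organ, j in zip(organs, cols_a)}
    b.replicate_of = {organ: expr.sample_ids[j] for organ, j in zip(organs, cols_b)}
    return a, b
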