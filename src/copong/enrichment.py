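"""Gene-set overlap and attribute-shift statistics.

Hypergeometric overlap of a co-module's genes with an external gene list,
flat one-sided Fisher term enrichment (one 2x2 table per term, no
ontology-graph decorrelation), a two-sided Wilcoxon rank-sum shift test on
dN/dS, and Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import GeneAttributes
from .conservation import rank_sum_test

__all__ = [
    "EnrichmentResult",
    "hypergeometric_overlap",
    "bonferroni",
    "term_enrichment",
    "dnds_shift_test",
]


@dataclass
class EnrichmentResult:
    query_id: str
    reference_id: str
    overlap: int
    query_size: int
    reference_size: int
    universe_size: int
    p_raw: float
    p_corrected: float


def hypergeometric_overlap(
    query, reference, universe, query_id: str = "query", reference_id: str = "reference"
) -> EnrichmentResult:
    """Upper-tail (inclusive) hypergeometric p for the overlap of two gene
    sets within a universe: P(X >= |query & reference|)."""
    query, reference, universe = set(query), set(reference), set(universe)
    if not query <= universe:
        raise ValueError("query is not a subset of the universe")
    if not reference <= universe:
        raise ValueError("reference is not a subset of the universe")
    k = len(query & reference)
    p = float(stats.hypergeom.sf(k - 1, len(universe), len(reference), len(query)))
    p = min(1.0, max(0.0, p))
    return EnrichmentResult(
        query_id, reference_id, k, len(query), len(reference), len(universe), p, p
    )


def bonferroni(p_values) -> list[float]:
    """Multiply each p by the number of tests, capped at 1."""
    p_values = list(p_values)
    m = len(p_values)
    out = []
    for p in p_values:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"p-value {p} outside [0, 1]")
        out.append(min(1.0, m * p))
    return out


def term_enrichment(gene_set, annotations: dict, universe, n_tests: int | None = None) -> list[EnrichmentResult]:
    """One-sided Fisher exact over-representation test per annotation term.

    ``annotations`` maps term -> gene set; every annotated gene must be in
    the universe.  Bonferroni is over ``n_tests`` (default: the number of
    terms).  Results are sorted by raw p.
    """
    gene_set, universe = set(gene_set), set(universe)
    m = n_tests if n_tests is not None else len(annotations)
    results = []
    for term, genes in annotations.items():
        genes = set(genes)
        if not genes <= universe:
            raise ValueError(f"annotation term {term!r} has genes outside the universe")
        k = len(gene_set & genes)
        table = [
            [k, len(gene_set) - k],
            [len(genes) - k, len(universe) - len(gene_set) - len(genes) + k],
        ]
        _, p = stats.fisher_exact(table, alternative="greater")
        p = float(min(1.0, max(0.0, p)))
        results.append(
            EnrichmentResult(
                "query", term, k, len(gene_set), len(genes), len(universe),
                p, min(1.0, m * p),
            )
        )
    results.sort(key=lambda r: (r.p_raw, r.reference_id))
    return results


def dnds_shift_test(
    cm_genes, attrs: GeneAttributes, n_tests: int = 98
) -> tuple[float, float, float, str]:
    """Two-sided Wilcoxon rank-sum of a co-module's dN/dS ratios against the
    ratios of all genes in the table (co-module included).

    Returns (median co-module ratio, raw p, Bonferroni-corrected p over
    ``n_tests``, direction "lower"/"higher" by median comparison).
    """
    ratios = attrs.ratios()
    cm_ratios = ratios[ratios.index.isin(set(cm_genes))]
    if cm_ratios.empty:
        raise ValueError("no co-module gene has a defined dN/dS ratio")
    _, p = rank_sum_test(cm_ratios.to_numpy(), ratios.to_numpy(), alternative="two-sided")
    med_cm = float(np.median(cm_ratios))
    med_all = float(np.median(ratios))
    direction = "lower" if med_cm < med_all else "higher"
    return med_cm, float(p), min(1.0, n_tests * p), direction
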