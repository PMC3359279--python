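# Methods

## Data model

Expression matrices are features × samples, on a log-like normalized scale
(e.g. the output of an array normalization pipeline); no normalization is
performed here and no missing values are allowed. Samples are either organ
arrays (possibly technical replicates) or homologous organ groups (HOGs)
after merging. HOG merging takes the arithmetic mean of a feature's values
over the samples mapped to a HOG; a HOG backed by fewer than two arrays is
allowed but warned about. Probes mapping to more than one gene are treated
as ambiguous and contribute nothing at gene level; unknown probes are
dropped with a logged count rather than raising, since silent exclusion is
how such tables are conventionally consumed. HOGs present in only one
species are not supported: the shared dimension must be common to both
matrices. Replicate splitting supports exactly two replicates per organ —
the design the replicate control needs — and assigns each pair to the two
output matrices uniformly at random under the caller's generator.

## The ping-pong iteration

Each matrix is held in two z-scored copies: column-normalized `E^C` (every
shared-dimension profile standardized across features) and row-normalized
`E^R` (every feature profile standardized across the shared dimension).
Feature scores are projections of the shared score vector through `E^C`;
shared scores are projections of feature scores through `E^R`ᵀ. This is
the signature-algorithm family's orientation: a gene's score measures how
far it stands out *within* the selected organs' expression distributions,
and an organ's score how coherently the selected genes are elevated in it.
The reverse assignment (feature scores through row-normalized data) was
considered and rejected: row centering absorbs most of an over-expression
effect that spans several of few organ columns (an additive 5σ effect over
3 of 12 HOGs is dampened to a z-score of about 1.6), which puts genuine
modules below any workable threshold.

Thresholding keeps entries strictly above `mean + t·sd` of the whole score
vector, with the population (divide-by-n) standard deviation everywhere —
one stated convention keeps every worked example exactly reproducible.
Survivors are rescaled by their maximum into (0, 1]; membership
additionally requires a positive value, so in the degenerate case of an
all-negative projection the score vector is empty rather than containing
scores outside (0, 1]. Only over-expression is sought; signed or
down-regulated modules are out of scope.

Convergence is declared when the three membership sets (features of each
species, shared set) are identical in two consecutive cycles, or when the
L∞ change of all score vectors falls below `tol = 1e-3`; seeds that empty
any vector or fail to converge within `max_iter = 100` cycles are dropped
with a logged count. Seeds are drawn by picking a size uniformly from
1..|shared| and then a uniform subset of that size; in the gene-shared
configuration (matrices transposed so one-to-one ortholog pairs form the
shared columns) seeds are likewise subsets of the shared dimension. The
threshold grid defaults to 2.5–6 (features) × 1–4.5 (shared) in steps of
0.5, with the same feature threshold applied to both species in any one
combination; distinct co-modules within a run are fixed points with exactly
equal membership triples, each carrying the count of seeds that reached it.
`run_ppa_grid` iterates all seeds of one threshold combination as a single
batched matrix recurrence (per-column thresholding, per-column convergence
tracking); `ppa_iterate` is the width-1 case of the same code path, so the
two are identical by construction.

## Post-processing cascade

Redundancy: for each pair of co-modules, Pearson correlations `c_h`, `c_m`
between the per-species gene-score vectors, taken over the full feature
universe with zeros for non-members (defined for every pair and sensitive
to both membership and score shape). Pairs with `c_h·c_m > 0.8` are
redundant; elimination is greedy in descending order of the two feature
thresholds' sum (ties: more members, then input order), accepting a
candidate only if its product with every already-accepted co-module stays
at or below the cut. Undefined correlations (zero variance) count as
product 0 with a warning. Then co-modules with fewer than 10 features in
either species are removed, and groups of co-modules whose species-1 gene
sets are nested (connected components of the "is-subset-or-superset"
relation — transitive closure, since the narrower pairwise-sequential
reading is underdetermined) are reduced to their largest member, size being
the smaller of the two species' gene counts.

A consequence worth knowing: with a multi-threshold grid, the redundancy
rule deliberately prefers a module's strictest-threshold variant, which
contains only its highest-scoring core. On small planted modules (tens of
genes) the surviving representative can therefore have a gene-level Jaccard
of 0.5–0.85 against the full planted set even when the grid contains an
exact fixed point. Recovery benchmarks are accordingly scored on the grid
output (before the cascade), while the cascade is verified through its own
invariants: no surviving pair similar above 0.8, none nested, all at least
10 features per species.

## Conservation rate γ

Gene families are connected components of the bipartite ortholog-pair
graph, ordered by smallest member id for determinism. For a co-module with
gene-level sets on both sides, `γ = n_og / min(nfam_h, nfam_m)`, where
`n_og` counts families represented in the co-module on both sides and
`nfam_h` (resp. `nfam_m`) counts the families of side 1 (resp. 2) having
at least one ortholog measured anywhere on the other species' array. When
`min(nfam_h, nfam_m) = 0`, γ is undefined — not 0 — and excluded from
medians and tests, since 0/0 is not evidence of non-conservation.

The null reshuffles the ortholog list preserving the one-to-one /
many-to-many split: one-to-one pairs have their species-2 partners permuted
among themselves; many-to-many pairs have the distinct species-2 genes they
involve relabelled by a random permutation, which preserves the pair
multiset exactly (the finer permutation scheme is otherwise unspecified, so
the class-count-preserving relabeling was chosen). Ten reshufflings per
run, shared across the co-modules of a run for consistency; the per-module
null is the mean γ over defined reshuffled values. The replicate control
runs the same discovery on two replicate halves of one species; there γ is
simply the probe-set overlap fraction of the smaller side, and it bounds
what the noise level permits.

Real and null γ lists are compared with a one-sided Mann–Whitney U test
(alternative: real exceeds null). Small samples (both sides < 8, feasible
enumeration) use exhaustive enumeration over pooled arrangements with
midranks; larger samples use the tie-corrected normal approximation
*without* continuity correction, so identical samples give exactly p = 0.5.

## Enrichment statistics

Overlap of a co-module with an external gene list uses the inclusive
upper-tail hypergeometric probability; term enrichment is a flat one-sided
Fisher exact test per term (equivalent to the hypergeometric tail on the
same 2×2 table — asserted as a property), with no ontology-graph
decorrelation. The dN/dS shift test is a two-sided Wilcoxon rank-sum of a
co-module's defined ratios (dS > 0) against all genes in the table,
co-module included, as literally specified; the direction label compares
medians. Bonferroni correction multiplies raw p-values by the configured
number of tests and caps at 1; whether tests are counted per co-module,
per external list, or both is a study-design choice, so the count is an
explicit argument (default 98 for the dN/dS screen, the number of
co-modules a full discovery run typically feeds into it).

## Synthetic data generator

The generator emulates a paired-species organ atlas: `n_hogs` HOGs with
`samples_per_hog_per_species` replicate arrays per species, `n_families`
gene families of which a configurable fraction are one-to-one (the default
0.866 matches the typical one-to-one share of a mammalian ortholog list),
many-to-many families of up to `max_family_size` genes per side joined by
complete bipartite pairs, and genes carried by 1–3 probe sets (default mix
70/25/5%). Baseline expression is i.i.d. Gaussian per probe × HOG
(`noise_sd = 1`), replicates add independent technical noise
(`tech_sd = 0.5` by default), and each planted module adds
`effect_delta·noise_sd` (default 5) to its member genes' probes in its
member HOGs. Gaussian baselines rather than resampled intensities: the
engine works on z-scored projections, so only relative structure matters
and Gaussian keeps the examples analytic.

Planted modules get disjoint HOG sets and disjoint families (an error if
the configuration cannot fit). A fraction `conservation_rho` of a module's
side-1 genes have their orthologs planted on side 2; the remainder of side
2 is filled from families not planted anywhere, so the γ of the planted
truth equals ρ by construction. Default module geometry is 3–4 HOGs and
10–14 genes per species against a ≈200-gene universe: module columns then
contain ≈5% elevated probes, which keeps the planted z-scores (≈3.3)
comfortably above the lowest grid threshold while leaving the background
untouched. What the generator does *not* emulate: probe-level artifacts
(GC bias, saturation), correlated baseline structure between organs,
unbalanced replicate designs, and partial organ coverage between species —
so passing benchmarks demonstrate correctness of the machinery on additive
Gaussian signal, not robustness to every artifact of real arrays.

## Problem sizes used in benchmarks

Recovery and separation benchmarks run at desk scale: ≈200 gene families
per species, 12 HOGs, 200 random seeds over the default 8×8 threshold grid
(recovery); 40 single-HOG co-modules of 8–12 families at ρ = 0.5 against
10 reshufflings (null separation); 60 seeds per replicate-control run.
The acceptance script uses 30–50 seeded repetitions per quantity; the test
suite uses 100 where a rate out of 100 runs is asserted.

## Known limitations

Only two data sets (one pair of species) per run; no signed modules; flat
enrichment without ontology structure; the redundancy cascade's
stringency-over-completeness preference described above; and γ's
sensitivity to array coverage — families absent from one array are
uncountable and silently reduce both numerator and denominator.
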