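"""Discover cross-species co-modules in a synthetic paired-organ atlas.

Generates two species' expression matrices with three planted co-modules,
merges organ replicates into homologous organ groups (HOGs), runs the
ping-pong threshold grid from 200 random seeds, applies the filtering
cascade, and scores how well the planted modules were recovered.
"""

import numpy as np

import copong as cp

cfg = cp.SimConfig(seed=7)
E1, E2, hogs, orth, probes, truth = cp.simulate_pair(cfg)
M1 = cp.merge_into_hogs(E1, hogs)
M2 = cp.merge_into_hogs(E2, hogs)
print(f"species 1: {M1.n_features} probes x {M1.n_samples} HOGs; "
      f"species 2: {M2.n_features} probes x {M2.n_samples} HOGs")

seeds = cp.make_random_seeds(M1.sample_ids, 200, np.random.default_rng(1))
grid = cp.run_ppa_grid(M1, M2, seeds)
kept, counts = cp.postprocess_cascade(grid)
print(f"distinct fixed points over the threshold grid: {len(grid)}")
print(f"cascade survivor counts: {counts}")

rec = cp.recovery_score(truth, grid, probes)
for k, r in enumerate(rec):
    print(f"planted module {k}: Jaccard HOGs={r['jaccard_hogs']:.2f} "
          f"genes1={r['jaccard_genes_1']:.2f} genes2={r['jaccard_genes_2']:.2f}")
# A Jaccard of 1.0 in every dimension means the grid found a fixed point
# whose organ set and both gene sets coincide exactly with the planted truth.
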