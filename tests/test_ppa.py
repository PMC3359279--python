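"""Normalization, thresholding, seeding and the ping-pong fixed-point
iteration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from copong.data import ExpressionMatrix, merge_into_hogs
from copong.ppa import (
    CoModule,
    Seed,
    make_random_seeds,
    normalize_for_projection,
    ppa_iterate,
    read_comodules_json,
    run_ppa_grid,
    threshold_scores,
    write_comodules_json,
)
from copong.simulate import recovery_score


class TestNormalization:
    def test_hand_computed_row_zscores(self):
        m = ExpressionMatrix("h", ["g1", "g2"], ["a", "b", "c"],
                             np.array([[1.0, 2.0, 3.0], [0.0, 0.0, 1.0]]))
        row, _ = normalize_for_projection(m)
        np.testing.assert_allclose(
            row.values[0], [-1.2247448, 0.0, 1.2247448], atol=1e-6
        )

    def test_constant_row_becomes_zero(self):
        m = ExpressionMatrix("h", ["g1", "g2"], ["a", "b", "c"],
                             np.array([[5.0, 5.0, 5.0], [0.0, 1.0, 2.0]]))
        row, _ = normalize_for_projection(m)
        assert np.all(row.values[0] == 0)

    def test_moments_of_random_matrix(self, rng):
        m = ExpressionMatrix("h", [f"g{i}" for i in range(20)],
                             [f"s{j}" for j in range(6)], rng.normal(size=(20, 6)))
        row, col = normalize_for_projection(m)
        np.testing.assert_allclose(row.values.mean(axis=1), 0, atol=1e-12)
        np.testing.assert_allclose(row.values.std(axis=1), 1, atol=1e-12)
        np.testing.assert_allclose(col.values.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(col.values.std(axis=0), 1, atol=1e-12)

    def test_too_small_matrix_rejected(self):
        m = ExpressionMatrix("h", ["g1"], ["a", "b"], np.array([[1.0, 2.0]]))
        with pytest.raises(ValueError):
            normalize_for_projection(m)


class TestThresholding:
    def test_constant_vector_empty(self):
        assert threshold_scores([1, 1, 1, 1], 1.0).is_empty()

    def test_single_outlier_hand_case(self):
        # mean 2.5, population sd ~4.330 -> cutoff ~6.83: only the 10 survives
        sv = threshold_scores([0, 0, 0, 10], 1.0)
        assert sv.membership == {"3"}
        assert sv.scores[3] == 1.0

    def test_max_score_is_one_when_nonempty(self, rng):
        for _ in range(20):
            sv = threshold_scores(rng.normal(size=30), 1.0)
            if not sv.is_empty():
                assert sv.scores.max() == pytest.approx(1.0)
                assert sv.scores.min() >= 0.0

    def test_support_matches_bruteforce_and_large_t_empty(self, rng):
        for _ in range(50):
            x = rng.normal(size=25)
            t = float(rng.uniform(0, 3))
            sv = threshold_scores(x, t)
            cut = x.mean() + t * x.std()
            expect = {str(i) for i in range(25) if x[i] > cut and x[i] > 0}
            assert sv.membership == expect
        assert threshold_scores(x, 100.0).is_empty()

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        x=st.lists(st.floats(-50, 50, allow_nan=False), min_size=1, max_size=30),
        t1=st.floats(0, 5),
        t2=st.floats(0, 5),
    )
    def test_support_antimonotone_in_t(self, x, t1, t2):
        lo, hi = sorted((t1, t2))
        assert threshold_scores(x, hi).membership <= threshold_scores(x, lo).membership

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            threshold_scores([1, 2], -0.5)


class TestSeeding:
    def test_singleton_universe(self, rng):
        seeds = make_random_seeds(["H1"], 5, rng)
        assert len(seeds) == 5
        assert all(s.hog_ids == frozenset({"H1"}) for s in seeds)

    def test_invalid_counts(self, rng):
        with pytest.raises(ValueError):
            make_random_seeds(["H1"], 0, rng)
        with pytest.raises(ValueError):
            make_random_seeds([], 3, rng)

    def test_reproducible(self):
        ids = [f"H{i}" for i in range(10)]
        a = make_random_seeds(ids, 50, np.random.default_rng(3))
        b = make_random_seeds(ids, 50, np.random.default_rng(3))
        assert [s.hog_ids for s in a] == [s.hog_ids for s in b]

    def test_size_distribution_uniform(self):
        ids = [f"H{i}" for i in range(27)]
        seeds = make_random_seeds(ids, 10_000, np.random.default_rng(0))
        sizes = np.array([len(s.hog_ids) for s in seeds])
        observed = np.bincount(sizes, minlength=28)[1:]
        chi2 = stats.chisquare(observed)
        assert chi2.pvalue > 0.01


def _merged_pair(planted_dataset):
    _, (E1, E2, hogs, orth, probes, truth) = planted_dataset
    return merge_into_hogs(E1, hogs), merge_into_hogs(E2, hogs), probes, truth


class TestIteration:
    def test_all_zero_matrices_give_none(self):
        z = np.zeros((5, 4))
        E1 = ExpressionMatrix("a", [f"g{i}" for i in range(5)], list("wxyz"), z)
        E2 = ExpressionMatrix("b", [f"h{i}" for i in range(5)], list("wxyz"), z)
        cm = ppa_iterate(E1, E2, Seed(frozenset({"w"})), (3.0, 3.0, 2.0))
        assert cm is None

    def test_planted_seed_recovers_planted_module(self, planted_dataset):
        M1, M2, probes, truth = _merged_pair(planted_dataset)
        mod = truth.modules[0]
        cm = ppa_iterate(M1, M2, Seed(mod.hogs), (2.5, 2.5, 1.0))
        assert cm is not None and cm.converged
        assert cm.shared_scores.membership == mod.hogs
        from copong.data import collapse_probes_to_genes

        assert collapse_probes_to_genes(cm.feature_scores_1.membership, probes) == set(mod.genes_1)
        assert collapse_probes_to_genes(cm.feature_scores_2.membership, probes) == set(mod.genes_2)

    def test_deterministic(self, planted_dataset):
        M1, M2, _, truth = _merged_pair(planted_dataset)
        seed = Seed(truth.modules[1].hogs)
        a = ppa_iterate(M1, M2, seed, (3.0, 3.0, 1.5))
        b = ppa_iterate(M1, M2, seed, (3.0, 3.0, 1.5))
        np.testing.assert_array_equal(a.shared_scores.scores, b.shared_scores.scores)
        np.testing.assert_array_equal(a.feature_scores_1.scores, b.feature_scores_1.scores)

    def test_output_is_fixed_point(self, planted_dataset):
        """Re-running the four steps once on a returned co-module reproduces
        its membership sets."""
        M1, M2, _, truth = _merged_pair(planted_dataset)
        cm = ppa_iterate(M1, M2, Seed(truth.modules[0].hogs), (2.5, 2.5, 1.0))
        t_f1, t_f2, t_s = cm.thresholds
        row1, col1 = normalize_for_projection(M1)
        row2, col2 = normalize_for_projection(M2)
        f1 = threshold_scores(col1.values @ cm.shared_scores.scores, t_f1,
                              ids=M1.feature_ids)
        s_mid = threshold_scores(row1.values.T @ f1.scores, t_s, ids=M1.sample_ids)
        f2 = threshold_scores(col2.values @ s_mid.scores, t_f2, ids=M2.feature_ids)
        s_new = threshold_scores(row2.values.T @ f2.scores, t_s, ids=M2.sample_ids)
        assert f1.membership == cm.feature_scores_1.membership
        assert f2.membership == cm.feature_scores_2.membership
        assert s_new.membership == cm.shared_scores.membership

    def test_shared_dimension_mismatch_errors(self, small_expr):
        other = ExpressionMatrix("m", ["x"], ["q1", "q2"], np.zeros((1, 2)))
        with pytest.raises(ValueError):
            ppa_iterate(small_expr, other, Seed(frozenset({"s1"})), (3, 3, 2))


class TestGrid:
    def test_zero_seeds_empty(self, planted_dataset):
        M1, M2, _, _ = _merged_pair(planted_dataset)
        assert run_ppa_grid(M1, M2, []) == []

    def test_single_combo_planted_module(self, planted_dataset):
        M1, M2, probes, truth = _merged_pair(planted_dataset)
        seeds = make_random_seeds(M1.sample_ids, 100, np.random.default_rng(0))
        cms = run_ppa_grid(M1, M2, seeds, feature_threshold_grid=[3.0],
                           shared_threshold_grid=[2.0])
        # a single threshold combination on strongly planted data collapses
        # to few distinct fixed points, each reached by many seeds
        assert len(cms) >= 1
        assert sum(cm.n_seeds for cm in cms) <= 100
        assert all(cm.n_seeds >= 1 for cm in cms)

    def test_grid_reproducible_and_recovers_modules(self, planted_dataset):
        M1, M2, probes, truth = _merged_pair(planted_dataset)
        seeds = make_random_seeds(M1.sample_ids, 200, np.random.default_rng(1))
        cms1 = run_ppa_grid(M1, M2, seeds)
        cms2 = run_ppa_grid(M1, M2, seeds)
        assert [c.membership_key for c in cms1] == [c.membership_key for c in cms2]
        rec = recovery_score(truth, cms1, probes)
        for r in rec:
            assert min(r["jaccard_hogs"], r["jaccard_genes_1"], r["jaccard_genes_2"]) >= 0.9

    def test_membership_triples_distinct(self, planted_dataset):
        M1, M2, _, _ = _merged_pair(planted_dataset)
        seeds = make_random_seeds(M1.sample_ids, 100, np.random.default_rng(2))
        cms = run_ppa_grid(M1, M2, seeds)
        keys = [cm.membership_key for cm in cms]
        assert len(keys) == len(set(keys))

    def test_gene_shared_transposed_run_recovers_organ_module(self, rng):
        """With matrices transposed so genes form the shared dimension, the
        same engine recovers a planted organ set on both feature sides."""
        n_genes, n_org = 120, 24
        mod_genes = list(range(12))
        mod_orgs = [0, 1]
        base1 = rng.normal(size=(n_org, n_genes))
        base2 = rng.normal(size=(n_org, n_genes))
        for b in (base1, base2):
            b[np.ix_(mod_orgs, mod_genes)] += 6.0
        gene_ids = [f"og{i}" for i in range(n_genes)]
        E1 = ExpressionMatrix("h", [f"ho{i}" for i in range(n_org)], gene_ids, base1)
        E2 = ExpressionMatrix("m", [f"mo{i}" for i in range(n_org)], gene_ids, base2)
        seed = Seed(frozenset(gene_ids[i] for i in mod_genes))
        cm = ppa_iterate(E1, E2, seed, (2.5, 2.5, 1.5))
        assert cm is not None
        assert cm.feature_scores_1.membership == {f"ho{i}" for i in mod_orgs}
        assert cm.feature_scores_2.membership == {f"mo{i}" for i in mod_orgs}


class TestSerialization:
    def test_json_round_trip(self, planted_dataset, tmp_path):
        M1, M2, _, truth = _merged_pair(planted_dataset)
        seeds = make_random_seeds(M1.sample_ids, 50, np.random.default_rng(4))
        cms = run_ppa_grid(M1, M2, seeds, feature_threshold_grid=[2.5, 3.0],
                           shared_threshold_grid=[1.0, 2.0])
        path = tmp_path / "cms.json"
        write_comodules_json(cms, path)
        back = read_comodules_json(path)
        assert len(back) == len(cms)
        for a, b in zip(cms, back):
            assert a.membership_key == b.membership_key
            assert a.thresholds == b.thresholds
            assert a.n_seeds == b.n_seeds
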