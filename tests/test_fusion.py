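"""Similarity screening, normalization, fusion, and training-matrix revision."""

import numpy as np
import pytest

from dtifuse import (DTIDataset, minmax_normalize, performance_weights,
                     revise_training_matrix, similarity_screen, vote_fuse,
                     weighted_fuse)

from conftest import gaussian_similarity, random_dataset


def screen_oracle(S_d, Y, theta):
    """Exhaustive double loop over drug pairs and targets."""
    n, m = Y.shape
    Y1 = Y.copy()
    added = set()
    for a in range(n):
        for b in range(n):
            if a == b or S_d[a, b] < theta:
                continue
            for t in range(m):
                if Y[a, t] == 1 and Y[b, t] == 0:
                    Y1[b, t] = 1
                    added.add((b, t))
    return Y1, added


class TestSimilarityScreen:
    def test_threshold_above_all_similarities_is_identity(self, tiny_dataset):
        y1, added = similarity_screen(tiny_dataset, theta_sim=0.99)
        np.testing.assert_array_equal(y1.values, tiny_dataset.Y)
        assert added == []

    def test_similar_drug_inherits_target(self, tiny_dataset):
        """d1 interacts with t1, d2 is similar to d1 (0.8 >= theta) and has
        no known interaction with t1 -> (d2, t1) is added."""
        y1, added = similarity_screen(tiny_dataset, theta_sim=0.7)
        assert y1.values[1, 0] == 1
        assert (1, 0) in {(p.drug_index, p.target_index) for p in added}
        # D3 is similar to nobody at 0.7, so its row is untouched
        np.testing.assert_array_equal(y1.values[2], tiny_dataset.Y[2])

    @pytest.mark.parametrize("seed,theta", [(0, 0.5), (1, 0.7), (2, 0.3),
                                            (3, 0.9), (4, 0.6)])
    def test_matches_double_loop_oracle(self, seed, theta):
        ds = random_dataset(seed, 10, 8, density=0.25)
        y1, added = similarity_screen(ds, theta_sim=theta)
        expected_Y1, expected_added = screen_oracle(ds.S_d, ds.Y, theta)
        np.testing.assert_array_equal(y1.values, expected_Y1)
        assert {(p.drug_index, p.target_index) for p in added} == expected_added

    def test_never_deletes_positives(self):
        for seed in range(5):
            ds = random_dataset(seed, 8, 6, density=0.3)
            y1, _ = similarity_screen(ds, theta_sim=0.4)
            assert np.all(y1.values >= ds.Y)

    def test_no_transitive_closure(self):
        """A chain a~b~c with only a interacting must not reach c when
        sim(a, c) is below the threshold."""
        S_d = np.array([[1.0, 0.8, 0.1],
                        [0.8, 1.0, 0.8],
                        [0.1, 0.8, 1.0]])
        Y = np.array([[1], [0], [0]])
        ds = DTIDataset(["a", "b", "c"], ["t"], Y, S_d, np.array([[1.0]]))
        y1, _ = similarity_screen(ds, theta_sim=0.7)
        assert y1.values[1, 0] == 1
        assert y1.values[2, 0] == 0

    def test_top_k_mode_selects_most_similar_pairs(self, tiny_dataset):
        y1_k, _ = similarity_screen(tiny_dataset, theta_sim=None, top_k=1)
        y1_t, _ = similarity_screen(tiny_dataset, theta_sim=0.8)
        np.testing.assert_array_equal(y1_k.values, y1_t.values)

    def test_exactly_one_mode_required(self, tiny_dataset):
        with pytest.raises(ValueError, match="exactly one"):
            similarity_screen(tiny_dataset, theta_sim=0.5, top_k=3)


class TestNormalize:
    def test_binary_matrix_unchanged(self):
        M = np.array([[0.0, 1.0], [1.0, 0.0]])
        np.testing.assert_array_equal(minmax_normalize(M), M)

    def test_constant_matrix_maps_to_zero(self):
        np.testing.assert_array_equal(minmax_normalize(np.full((3, 3), 4.2)),
                                      np.zeros((3, 3)))

    def test_affine_map_arithmetic(self):
        M = np.array([[2.0, 6.0], [4.0, 3.0]])
        np.testing.assert_allclose(minmax_normalize(M), (M - 2.0) / 4.0)


class TestWeightedFuse:
    def test_single_source_identity_on_normalized(self):
        M = np.array([[0.5, 2.0], [1.0, 0.0]])
        np.testing.assert_allclose(weighted_fuse([M], [1.0]).values,
                                   minmax_normalize(M))

    def test_equal_weights_equal_average(self):
        rng = np.random.default_rng(0)
        mats = [rng.random((4, 3)) for _ in range(3)]
        fused = weighted_fuse(mats, np.full(3, 1 / 3)).values
        ave = np.mean([minmax_normalize(m) for m in mats], axis=0)
        np.testing.assert_allclose(fused, ave)

    def test_elementwise_oracle(self):
        A = np.array([[0.0, 1.0], [0.5, 0.25]])
        B = np.array([[1.0, 0.0], [0.5, 0.75]])
        C = np.array([[0.0, 0.5], [1.0, 0.0]])
        fused = weighted_fuse([A, B, C], [0.5, 0.3, 0.2]).values
        np.testing.assert_allclose(fused, 0.5 * A + 0.3 * B + 0.2 * C)

    def test_weights_must_sum_to_one(self):
        M = np.zeros((2, 2))
        with pytest.raises(ValueError, match="sum to 1"):
            weighted_fuse([M, M], [0.5, 0.4])
        with pytest.raises(ValueError, match="expected 2"):
            weighted_fuse([M, M], [1.0])

    def test_output_in_convex_hull_of_sources(self):
        rng = np.random.default_rng(1)
        mats = [rng.random((5, 4)) * rng.integers(1, 10) for _ in range(3)]
        w = rng.dirichlet(np.ones(3))
        fused = weighted_fuse(mats, w).values
        normalized = np.stack([minmax_normalize(m) for m in mats])
        assert np.all(fused <= normalized.max(axis=0) + 1e-12)
        assert np.all(fused >= normalized.min(axis=0) - 1e-12)


class TestVoteFuse:
    def test_identical_binary_sources_pass_through(self):
        M = np.array([[1.0, 0.0], [0.0, 1.0]])
        fused = vote_fuse([M, M, M], binarize_fraction=0.5).values
        np.testing.assert_array_equal(fused, M)

    def test_majority_rule_cells(self):
        """Per-cell votes (1,1,0) -> 1 and (1,0,0) -> 0."""
        A = np.array([[1.0, 1.0], [0.0, 0.0]])
        B = np.array([[1.0, 0.0], [1.0, 0.0]])
        C = np.array([[0.0, 1.0], [0.0, 1.0]])
        fused = vote_fuse([A, B, C], binarize_fraction=0.5).values
        np.testing.assert_array_equal(fused, [[1.0, 1.0], [0.0, 0.0]])

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_per_cell_majority_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mats = [rng.random((6, 5)) for _ in range(3)]
        frac = 0.2
        k = int(np.ceil(frac * 30))
        binarized = []
        for m in mats:
            cut = np.sort(m.ravel())[::-1][k - 1]
            b = (m >= cut).astype(int)
            # ties above the cutoff cannot occur with continuous draws
            assert b.sum() == k
            binarized.append(b)
        expected = (np.sum(binarized, axis=0) >= 2).astype(float)
        np.testing.assert_array_equal(vote_fuse(mats, frac).values, expected)

    def test_even_source_count_rejected(self):
        M = np.zeros((2, 2))
        with pytest.raises(ValueError, match="odd"):
            vote_fuse([M, M], 0.5)


class TestPerformanceWeights:
    def test_identical_sources_equal_weights(self):
        ds = random_dataset(0, 8, 6, density=0.3)
        fn = lambda d: d.Y + 0.1  # noqa: E731 - same scores for every source
        w = performance_weights(ds, {"a": fn, "b": fn, "c": fn}, seed=0)
        np.testing.assert_allclose(w, np.full(3, 1 / 3))

    def test_weights_sum_to_one(self):
        ds = random_dataset(1, 8, 6, density=0.3)
        rng = np.random.default_rng(0)
        fns = {name: (lambda d, s=seed: np.random.default_rng(s).random(d.Y.shape))
               for seed, name in enumerate("abc")}
        w = performance_weights(ds, fns, seed=1)
        assert w.sum() == pytest.approx(1.0)
        assert (w >= 0).all()

    def test_oracle_source_gets_largest_weight(self, benchmark_one):
        """A source that scores with the ground truth must out-weigh random
        sources: its inner-CV AUPR is maximal by construction."""
        ds, truth = benchmark_one
        oracle = lambda d: truth.true_Y.astype(float)  # noqa: E731
        rand1 = lambda d: np.random.default_rng(1).random(d.Y.shape)  # noqa: E731
        rand2 = lambda d: np.random.default_rng(2).random(d.Y.shape)  # noqa: E731
        w = performance_weights(ds, {"oracle": oracle, "r1": rand1, "r2": rand2},
                                seed=0)
        assert w[0] == w.max()
        assert w[0] > 0.5


class TestReviseTrainingMatrix:
    def test_zero_fraction_is_identity(self):
        ds = random_dataset(2, 6, 5)
        scores = np.random.default_rng(0).random(ds.Y.shape)
        revised, added = revise_training_matrix(ds.Y, scores, 0.0)
        np.testing.assert_array_equal(revised, ds.Y)
        assert added == []

    def test_added_sets_nest_as_fraction_grows(self):
        ds = random_dataset(5, 8, 6, density=0.2)
        scores = np.random.default_rng(1).random(ds.Y.shape)
        prev = set()
        for frac in (0.02, 0.05, 0.1, 0.3):
            _, added = revise_training_matrix(ds.Y, scores, frac)
            cur = {(p.drug_index, p.target_index) for p in added}
            assert prev <= cur
            prev = cur

    def test_positives_never_removed(self):
        ds = random_dataset(3, 6, 5, density=0.3)
        scores = np.random.default_rng(2).random(ds.Y.shape)
        revised, _ = revise_training_matrix(ds.Y, scores, 0.2)
        assert np.all(revised >= ds.Y)

    def test_sort_oracle_on_5x4_fixture(self):
        rng = np.random.default_rng(3)
        Y = np.zeros((5, 4), dtype=int)
        Y[0, 0] = Y[2, 3] = 1
        scores = rng.random((5, 4))
        revised, added = revise_training_matrix(Y, scores, 0.1)
        unl = [(i, j) for i in range(5) for j in range(4) if Y[i, j] == 0]
        k = int(np.ceil(0.1 * len(unl)))  # 2 of 18
        expected = sorted(unl, key=lambda p: (-scores[p], p))[:k]
        assert [(p.drug_index, p.target_index) for p in added] == expected
        assert revised.sum() == Y.sum() + k

    def test_fraction_out_of_range(self):
        with pytest.raises(ValueError):
            revise_training_matrix(np.zeros((2, 2), int), np.zeros((2, 2)), 1.5)
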