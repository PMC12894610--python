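"""z-scoring, complete linkage, NMI and the permutation comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import normalized_mutual_info_score

from affectdim import (
    SyntheticConfig,
    ValidationError,
    complete_linkage_cluster,
    contingency,
    generate,
    majority_cluster_labels,
    nmi,
    nmi_curve,
    nmi_difference_permutation_test,
    nmi_from_labels,
    zscore_columns,
)
from oracles import complete_linkage_bruteforce, nmi_bruteforce, partition_sets


def five_blobs(seed, n_per=10, spread=0.3):
    rng = np.random.default_rng(seed)
    centers = np.eye(5) * 4
    X = np.vstack([c + rng.normal(0, spread, (n_per, 5)) for c in centers])
    truth = np.repeat(np.arange(5), n_per)
    return X, truth


class TestZScore:
    def test_hand_computed_column(self):
        out = zscore_columns(np.array([[1.0], [2.0], [3.0]]))
        np.testing.assert_allclose(out.ravel(), [-1.0, 0.0, 1.0], atol=1e-12)

    def test_idempotent_on_standardized_data(self):
        rng = np.random.default_rng(0)
        z = zscore_columns(rng.normal(size=(40, 3)))
        np.testing.assert_allclose(zscore_columns(z), z, atol=1e-12)

    def test_constant_column_errors_naming_it(self):
        X = np.ones((5, 2))
        X[:, 0] = np.arange(5)
        with pytest.raises(ValidationError, match="1"):
            zscore_columns(X)


class TestCompleteLinkage:
    def test_two_well_separated_pairs(self):
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        res = complete_linkage_cluster(X, 2)
        assert partition_sets(res.assignments) == {frozenset({0, 1}), frozenset({2, 3})}

    def test_k_equals_n_gives_singletons(self):
        X = np.arange(6, dtype=float)[:, None]
        res = complete_linkage_cluster(X, 6)
        assert len(set(res.assignments)) == 6

    @pytest.mark.parametrize("k", [1, 0, 7])
    def test_k_out_of_range_rejected(self, k):
        with pytest.raises(ValidationError):
            complete_linkage_cluster(np.arange(6, dtype=float)[:, None], k)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_merge_oracle_small_n(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 8))
        k = int(rng.integers(2, n))
        X = rng.normal(size=(n, 3))
        ours = complete_linkage_cluster(X, k).assignments
        oracle = complete_linkage_bruteforce(X, k)
        assert partition_sets(ours) == partition_sets(oracle)


class TestContingency:
    def test_identical_partitions_are_diagonal(self):
        t = contingency([0, 1, 2, 0, 1, 2], [0, 1, 2, 0, 1, 2])
        np.testing.assert_array_equal(t.counts, 2 * np.eye(3, dtype=int))

    def test_single_cluster_single_column(self):
        t = contingency([0] * 6, [0, 0, 1, 1, 2, 2])
        assert t.counts.shape == (3, 1)
        assert t.counts.sum() == 6

    def test_matches_bruteforce_pair_counting(self):
        rng = np.random.default_rng(3)
        a = rng.integers(0, 4, 50)
        t = rng.integers(0, 3, 50)
        tab = contingency(a, t)
        for i, r in enumerate(tab.row_labels):
            for j, c in enumerate(tab.col_labels):
                assert tab.counts[i, j] == sum(
                    1 for x, y in zip(a, t) if x == c and y == r
                )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            contingency([0, 1], [0, 1, 2])


class TestNMI:
    def test_identical_partitions_give_one(self):
        assert nmi(np.array([[2, 0], [0, 2]])) == pytest.approx(1.0)

    def test_single_cluster_convention_gives_zero(self):
        assert nmi(np.array([[3], [4], [2]])) == 0.0

    def test_hand_computed_table(self):
        assert nmi(np.array([[3, 1], [1, 3]])) == pytest.approx(0.18872, abs=5e-6)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            nmi(np.array([[1, -1], [0, 2]]))

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=60, deadline=None)
    def test_transpose_and_relabel_invariance(self, seed):
        rng = np.random.default_rng(seed)
        t = rng.integers(0, 5, (rng.integers(2, 6), rng.integers(2, 6)))
        if t.sum() == 0:
            t[0, 0] = 1
        v = nmi(t)
        assert 0.0 <= v <= 1.0
        assert nmi(t.T) == pytest.approx(v, abs=1e-12)
        assert nmi(t[:, ::-1]) == pytest.approx(v, abs=1e-12)
        assert nmi(t[::-1, :]) == pytest.approx(v, abs=1e-12)

    def test_self_nmi_is_one_for_any_multicluster_partition(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            labels = rng.integers(0, 4, 30)
            if len(set(labels)) < 2:
                continue
            assert nmi_from_labels(labels, labels) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_sklearn_arithmetic_normalization(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.integers(0, 4, 60)
        b = rng.integers(0, 5, 60)
        ours = nmi_from_labels(a, b)
        ref = normalized_mutual_info_score(a, b, average_method="arithmetic")
        assert ours == pytest.approx(ref, abs=1e-10)


class TestNMICurve:
    def test_separable_blobs_peak_at_five(self):
        for seed in range(10):
            X, truth = five_blobs(seed)
            curve = nmi_curve(X, truth, range(2, 9))
            best_k = int(curve.loc[curve["nmi"].idxmax(), "k"])
            assert best_k == 5

    def test_permuted_truth_scores_below_aligned_truth(self):
        X, truth = five_blobs(0)
        rng = np.random.default_rng(1)
        aligned = nmi_curve(X, truth, [5])["nmi"].iloc[0]
        permuted = nmi_curve(X, rng.permutation(truth), range(2, 9))["nmi"]
        assert (permuted < aligned).all()

    def test_repeated_run_identical(self):
        X, truth = five_blobs(2)
        c1 = nmi_curve(X, truth, range(2, 8))
        c2 = nmi_curve(X, truth, range(2, 8))
        assert c1.equals(c2)

    def test_k_range_outside_items_rejected(self):
        X, truth = five_blobs(0, n_per=2)
        with pytest.raises(ValidationError):
            nmi_curve(X, truth, range(2, 11))


class TestPermutationTest:
    def test_identical_feature_sets_are_never_significant(self):
        X, truth = five_blobs(0)
        for seed in range(20):
            res = nmi_difference_permutation_test(
                X, X, truth, k=5, n_permutations=99, seed=seed
            )
            assert res.observed == 0.0
            assert res.p_value >= 0.3

    def test_strong_signal_attains_minimal_p(self):
        X, truth = five_blobs(3, n_per=16, spread=0.1)
        rng = np.random.default_rng(0)
        noise = rng.normal(size=X.shape)
        res = nmi_difference_permutation_test(
            X, noise, truth, k=5, n_permutations=999, seed=1
        )
        assert res.p_value == pytest.approx(1.0 / 1000.0)

    def test_mismatched_item_counts_rejected(self):
        X, truth = five_blobs(0)
        with pytest.raises(ValidationError):
            nmi_difference_permutation_test(X, X[:-1], truth, k=5, n_permutations=99)


class TestMajorityLabels:
    def test_diagonal_table_maps_identically(self):
        tab = contingency([0, 1, 2], ["disgust", "fear", "amusement"])
        labels = majority_cluster_labels(tab)
        assert labels.mapping == {0: "disgust", 1: "fear", 2: "amusement"}
        assert labels.tied_clusters == ()

    def test_tie_resolves_to_first_canonical_category_with_flag(self):
        assignments = [0, 0, 0, 0]
        truth = ["fear", "fear", "disgust", "disgust"]
        labels = majority_cluster_labels(contingency(assignments, truth))
        assert labels.mapping[0] == "disgust"  # first in canonical order
        assert labels.tied_clusters == (0,)

    @pytest.mark.parametrize("seed", range(10))
    def test_bijection_on_concentrated_synthetic_data(self, seed):
        table, _ = generate(SyntheticConfig(regime="discrete", kappa=100.0, seed=seed))
        z = zscore_columns(table.probabilities)
        res = complete_linkage_cluster(z, 5)
        labels = majority_cluster_labels(contingency(res.assignments, table.categories))
        assert sorted(labels.mapping.values()) == sorted(set(table.categories))
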