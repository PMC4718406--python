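import itertools
import math

import numpy as np
import pytest

from nucparticle.cluster_stats import (
    apply_cluster_order,
    kmeans_profiles,
    overlap_test,
    subsample_ttest,
)
from nucparticle.site_profile import ProfileMatrix


def matrix_from(values, ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"g{i}" for i in range(values.shape[0])]
    offsets = np.arange(values.shape[1]) * 10
    return ProfileMatrix(ids=ids, offsets=offsets, values=values)


class TestKMeans:
    def test_k1_centroid_is_column_mean(self):
        rng = np.random.default_rng(31)
        X = rng.uniform(0, 10, size=(20, 5))
        result = kmeans_profiles(matrix_from(X), k=1, seed=0)
        np.testing.assert_allclose(result.centroids[0], X.mean(axis=0))
        assert set(result.labels) == {1}

    def test_planted_partition_recovered_exactly(self):
        rng = np.random.default_rng(32)
        prototypes = rng.uniform(0, 1, size=(4, 8)) * 100  # well separated
        rows = np.repeat(prototypes, 10, axis=0) + rng.normal(0, 0.01, size=(40, 8))
        result = kmeans_profiles(matrix_from(rows), k=4, seed=0)
        planted = np.repeat(np.arange(4), 10)
        # same partition up to label permutation
        for lab in range(4):
            members = set(np.flatnonzero(planted == lab))
            got_labels = {int(result.labels[i]) for i in members}
            assert len(got_labels) == 1
            assert set(np.flatnonzero(result.labels == got_labels.pop())) == members

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(33)
        X = rng.uniform(0, 10, size=(30, 6))
        r1 = kmeans_profiles(matrix_from(X), k=3, seed=7)
        r2 = kmeans_profiles(matrix_from(X), k=3, seed=7)
        assert np.array_equal(r1.labels, r2.labels)
        assert r1.row_order == r2.row_order

    def test_row_order_sorted_by_cluster_then_distance(self):
        rng = np.random.default_rng(34)
        X = rng.uniform(0, 10, size=(25, 4))
        result = kmeans_profiles(matrix_from(X), k=3, seed=1)
        idx = {fid: i for i, fid in enumerate(result.ids)}
        labels = [int(result.labels[idx[f]]) for f in result.row_order]
        assert labels == sorted(labels)

    def test_k_exceeding_rows_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            kmeans_profiles(matrix_from(np.zeros((3, 2))), k=5, seed=0)


class TestApplyClusterOrder:
    def test_reorders_other_matrix_identically(self):
        rng = np.random.default_rng(35)
        X = rng.uniform(0, 10, size=(12, 4))
        mat = matrix_from(X)
        result = kmeans_profiles(mat, k=3, seed=2)
        ordered = apply_cluster_order(result, mat)
        assert ordered.ids == result.row_order
        # row content preserved under reordering
        for fid in mat.ids:
            np.testing.assert_array_equal(ordered.row(fid), mat.row(fid))

    def test_input_row_order_is_irrelevant(self):
        rng = np.random.default_rng(36)
        X = rng.uniform(0, 10, size=(10, 4))
        mat = matrix_from(X)
        result = kmeans_profiles(mat, k=2, seed=3)
        shuffled = matrix_from(X[::-1], ids=mat.ids[::-1])
        a = apply_cluster_order(result, mat)
        b = apply_cluster_order(result, shuffled)
        assert a.ids == b.ids
        np.testing.assert_array_equal(a.values, b.values)

    def test_missing_ids_reported(self):
        mat = matrix_from(np.zeros((4, 3)))
        result = kmeans_profiles(mat, k=2, seed=0)
        other = matrix_from(np.zeros((3, 3)), ids=["g0", "g1", "g2"])
        with pytest.raises(KeyError, match="g3"):
            apply_cluster_order(result, other)


def student_t_closed_form(a, b):
    """Textbook pooled-variance two-sample t for equal group sizes."""
    n1, n2 = len(a), len(b)
    va = np.var(a, ddof=1)
    vb = np.var(b, ddof=1)
    sp2 = ((n1 - 1) * va + (n2 - 1) * vb) / (n1 + n2 - 2)
    return (np.mean(a) - np.mean(b)) / math.sqrt(sp2 * (1 / n1 + 1 / n2))


class TestSubsampleTTest:
    def test_identical_conditions_give_t0_p1(self):
        rng = np.random.default_rng(41)
        v = rng.uniform(0, 10, size=500)
        tt = subsample_ttest(v, v.copy(), subset_size=10, n_subsets=10, seed=0)
        assert tt.t_stat == 0.0 and tt.p_two_tailed == 1.0

    def test_zero_variance_equal_means_flagged_degenerate(self):
        v = np.full(100, 3.0)
        tt = subsample_ttest(v, v.copy(), subset_size=10, n_subsets=10, seed=0)
        assert tt.degenerate and tt.p_two_tailed == 1.0

    def test_large_shift_is_highly_significant(self):
        rng = np.random.default_rng(42)
        a = rng.normal(10, 1, size=3000)
        b = a + 50.0
        tt = subsample_ttest(a, b, subset_size=100, n_subsets=29, seed=0)
        assert tt.p_two_tailed < 1e-6
        assert not tt.with_replacement

    def test_partition_is_disjoint_and_shared(self):
        # with exactly 29x100 features an exhaustive disjoint partition means
        # the average of subset means equals the overall mean exactly
        n = 2900
        a = np.arange(n, dtype=float)
        tt = subsample_ttest(a, a + 1.0, subset_size=100, n_subsets=29, seed=5)
        assert tt.means_a.mean() == pytest.approx(a.mean(), rel=1e-12)
        # shared partition: mean_b - mean_a == 1 for every subset
        np.testing.assert_allclose(tt.means_b - tt.means_a, 1.0)
        assert len(tt.means_a) == 29

    def test_t_matches_closed_form_on_fixed_means(self):
        rng = np.random.default_rng(43)
        n = 29 * 100
        a = rng.normal(5, 1, size=n)
        b = rng.normal(5.5, 1.2, size=n)
        tt = subsample_ttest(a, b, subset_size=100, n_subsets=29, seed=9)
        expected_t = student_t_closed_form(tt.means_a, tt.means_b)
        assert tt.t_stat == pytest.approx(expected_t, rel=1e-12)
        from scipy.stats import t as t_dist

        df = 2 * 29 - 2
        expected_p = 2 * t_dist.sf(abs(expected_t), df)
        assert tt.p_two_tailed == pytest.approx(expected_p, rel=1e-12)

    def test_overlapping_subsets_when_features_scarce(self):
        rng = np.random.default_rng(44)
        a = rng.normal(0, 1, size=50)
        tt = subsample_ttest(a, a + 10, subset_size=10, n_subsets=29, seed=1)
        assert tt.with_replacement
        assert tt.p_two_tailed < 1e-6

    def test_paired_option_uses_dependent_test(self):
        from scipy.stats import ttest_rel

        rng = np.random.default_rng(45)
        n = 200
        a = rng.normal(5, 1, size=n)
        b = a + rng.normal(0.3, 0.1, size=n)
        tt = subsample_ttest(a, b, subset_size=20, n_subsets=10, seed=2, paired=True)
        t_exp, p_exp = ttest_rel(tt.means_a, tt.means_b)
        assert tt.t_stat == pytest.approx(float(t_exp))
        assert tt.p_two_tailed == pytest.approx(float(p_exp))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            subsample_ttest([1.0, 2.0], [1.0], subset_size=1, n_subsets=2)


def enumerate_overlap_pvalue(background, n_a, n_b, k_obs):
    """P(|A ∩ B| >= k) by exhaustive enumeration over all B of size n_b."""
    universe = range(background)
    set_a = set(range(n_a))
    hits = 0
    total = 0
    for b in itertools.combinations(universe, n_b):
        total += 1
        hits += len(set_a & set(b)) >= k_obs
    return hits / total


class TestOverlapTest:
    def test_matches_exhaustive_enumeration(self):
        background = 12
        genes = [f"g{i}" for i in range(background)]
        list_a = genes[:4]
        list_b = genes[2:7]  # overlap = 2
        result = overlap_test(list_a, list_b, background)
        assert result.n_overlap == 2
        expected = enumerate_overlap_pvalue(background, 4, 5, 2)
        assert result.p_hyper == pytest.approx(expected, rel=1e-12)

    def test_identical_small_lists_match_enumeration(self):
        genes = [f"g{i}" for i in range(10)]
        list_a = genes[:3]
        result = overlap_test(list_a, list_a, 10)
        expected = enumerate_overlap_pvalue(10, 3, 3, 3)
        assert result.p_hyper == pytest.approx(expected, rel=1e-12)

    def test_disjoint_lists_give_p1(self):
        result = overlap_test(["a", "b"], ["c", "d"], 100)
        assert result.n_overlap == 0
        assert result.p_hyper == 1.0

    def test_list_larger_than_background_rejected(self):
        with pytest.raises(ValueError, match="background"):
            overlap_test([f"g{i}" for i in range(5)], ["g0"], 4)
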