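import numpy as np
import pytest

from cartosom import (ExpressionMatrix, PipelineConfig, run_ensemble,
                      harmonize_cluster_counts, build_fuzzy_matrix, resolve,
                      pairwise_affinity, filter_by_confidence, f_measure)
from cartosom.ensemble import consensus_components, build_consensus_fuzzy
from cartosom.mstcluster import ClusterRun


def _run(labels):
    labels = np.asarray(labels)
    k = labels.max() + 1
    sizes = np.bincount(labels, minlength=k)
    return ClusterRun(item_to_cluster=labels, n_clusters=int(k),
                      singleton_flags=sizes == 1)


def _matrix(n, d=2, seed=0):
    rng = np.random.default_rng(seed)
    vals = rng.normal(size=(n, d))
    return ExpressionMatrix([f"i{j}" for j in range(n)],
                            [f"f{j}" for j in range(d)], vals)


FAST = PipelineConfig(iterations=150, beta=3)


class TestHarmonize:
    def test_equal_counts_unchanged(self):
        runs = [_run([0, 0, 1, 1, 2, 2])] * 3
        harmonized, mu = harmonize_cluster_counts(runs, _matrix(6))
        assert mu == 3
        for lab in harmonized:
            np.testing.assert_array_equal(lab, runs[0].item_to_cluster)

    def test_counts_three_and_five_meet_at_four(self):
        # blocks of 4 items so splits/merges are well defined
        r3 = _run([0] * 8 + [1] * 4 + [2] * 4)
        r5 = _run([0, 0, 0, 0, 1, 1, 1, 1, 2, 2, 2, 2, 3, 3, 4, 4])
        mat = _matrix(16, seed=3)
        harmonized, mu = harmonize_cluster_counts([r3, r5], mat, seed=1)
        assert mu == 4
        assert all(lab.max() + 1 == 4 for lab in harmonized)

    def test_single_run_keeps_own_count(self):
        runs = [_run([0, 1, 1, 2, 2, 2])]
        _, mu = harmonize_cluster_counts(runs, _matrix(6))
        assert mu == 3

    def test_needs_at_least_one_run(self):
        with pytest.raises(ValueError):
            harmonize_cluster_counts([], _matrix(3))


class TestFuzzyMatrix:
    def test_two_identical_runs_single_column_hits(self):
        labels = np.array([0, 0, 1, 1, 2])
        F = build_fuzzy_matrix([labels, labels], mu=3)
        assert F.shape == (5, 3)
        assert ((F > 0).sum(axis=1) == 1).all()
        assert set(F[F > 0]) == {2.0}

    def test_item_split_between_clusters(self):
        a = np.array([0, 0, 1, 1])
        b = np.array([0, 1, 1, 0])  # items 1 and 3 flip
        F = build_fuzzy_matrix([a, b], mu=2)
        np.testing.assert_array_equal(F[1], [1.0, 1.0])
        np.testing.assert_array_equal(F[3], [1.0, 1.0])

    def test_rows_sum_to_run_count(self):
        rng = np.random.default_rng(0)
        runs = [rng.integers(0, 3, size=20) for _ in range(5)]
        F = build_fuzzy_matrix(runs, mu=3)
        np.testing.assert_array_equal(F.sum(axis=1), np.full(20, 5.0))

    def test_column_matching_is_label_permutation_invariant(self):
        a = np.array([0, 0, 1, 1, 2, 2])
        b = np.array([2, 2, 0, 0, 1, 1])  # same partition, renamed
        F = build_fuzzy_matrix([a, b], mu=3)
        assert set(F[F > 0]) == {2.0}


class TestResolve:
    def test_unanimous_row(self):
        labels, conf = resolve(np.array([[5.0, 0.0, 0.0]]), n_runs=5)
        assert labels[0] == 0 and conf[0] == 100.0

    def test_majority_row(self):
        # second row keeps column 0 occupied so no compaction renames occur
        labels, conf = resolve(np.array([[2.0, 3.0], [5.0, 0.0]]), n_runs=5)
        assert labels[0] == 1 and conf[0] == pytest.approx(60.0)

    def test_tie_goes_to_lower_column(self):
        labels, _ = resolve(np.array([[2.0, 2.0, 1.0]]), n_runs=5)
        assert labels[0] == 0

    def test_empty_columns_compacted(self):
        F = np.array([[3.0, 0.0, 0.0], [0.0, 0.0, 3.0]])
        labels, _ = resolve(F, n_runs=3)
        np.testing.assert_array_equal(labels, [0, 1])

    def test_idempotent(self):
        F = np.array([[2.0, 3.0], [4.0, 1.0], [0.0, 5.0]])
        l1, c1 = resolve(F, 5)
        # re-resolving the indicator matrix of the result reproduces it
        F2 = np.zeros_like(F)
        F2[np.arange(3), l1] = 5.0
        l2, c2 = resolve(F2, 5)
        np.testing.assert_array_equal(l1, l2)


class TestAffinity:
    def test_extremes_and_half(self):
        runs = [_run([0, 0, 1]), _run([0, 1, 1])]
        aff = pairwise_affinity(runs)
        assert aff[0, 1] == 0.5      # together in 1 of 2 runs
        assert aff[0, 2] == 0.0      # never together
        np.testing.assert_array_equal(np.diag(aff), 1.0)
        np.testing.assert_array_equal(aff, aff.T)

    def test_always_co_clustered_pair(self):
        runs = [_run([0, 0, 1])] * 4
        assert pairwise_affinity(runs)[0, 1] == 1.0

    def test_consensus_components_majority_rule(self):
        aff = np.array([
            [1.0, 0.6, 0.4],
            [0.6, 1.0, 0.4],
            [0.4, 0.4, 1.0],
        ])
        np.testing.assert_array_equal(consensus_components(aff, 0.5), [0, 0, 1])

    def test_consensus_fuzzy_rows_sum_to_E(self):
        runs = [_run([0, 0, 1, 1]), _run([0, 0, 0, 1]), _run([1, 1, 0, 0])]
        comp = consensus_components(pairwise_affinity(runs), 0.5)
        F = build_consensus_fuzzy(runs, comp)
        np.testing.assert_array_equal(F.sum(axis=1), np.full(4, 3.0))


class TestRunEnsemble:
    def test_single_iteration_matches_single_run_with_full_confidence(self):
        mat = _matrix(30, seed=5)
        res = run_ensemble(mat, FAST, n_ensemble=1, seed=4)
        np.testing.assert_array_equal(res.final_labels,
                                      res.runs[0].item_to_cluster)
        np.testing.assert_array_equal(res.confidence, np.full(30, 100.0))

    def test_deterministic_under_master_seed(self, gauss_small):
        mat, _ = gauss_small
        a = run_ensemble(mat, FAST, n_ensemble=3, seed=8)
        b = run_ensemble(mat, FAST, n_ensemble=3, seed=8)
        np.testing.assert_array_equal(a.final_labels, b.final_labels)
        np.testing.assert_array_equal(a.affinity, b.affinity)
        np.testing.assert_array_equal(a.F, b.F)

    def test_bookkeeping_invariants(self, gauss_small):
        mat, _ = gauss_small
        res = run_ensemble(mat, FAST, n_ensemble=3, seed=2)
        E = res.n_ensemble
        np.testing.assert_array_equal(res.F.sum(axis=1), np.full(mat.n_items, E))
        np.testing.assert_allclose(res.affinity, res.affinity.T)
        np.testing.assert_array_equal(np.diag(res.affinity), 1.0)
        np.testing.assert_allclose(
            res.confidence, 100.0 * res.F.max(axis=1) / E)

    def test_core_points_stable_across_runs(self, gauss_small):
        mat, truth = gauss_small
        res = run_ensemble(mat, FAST, n_ensemble=3, seed=1)
        frac_stable = np.mean(res.F.max(axis=1) / 3 >= 0.9)
        assert frac_stable >= 0.9

    def test_matching_consensus_path(self, gauss_small):
        mat, truth = gauss_small
        res = run_ensemble(mat, FAST, n_ensemble=3, seed=1, consensus="matching")
        assert res.F.shape[1] == res.mu
        assert f_measure(res.final_labels, truth) > 0.8

    def test_input_order_insensitive_quality(self, gauss_small):
        mat, truth = gauss_small
        perm = np.random.default_rng(0).permutation(mat.n_items)
        mat_p = ExpressionMatrix([mat.item_ids[i] for i in perm],
                                 mat.feature_ids, mat.values[perm])
        res = run_ensemble(mat_p, FAST, n_ensemble=3, seed=6)
        assert f_measure(res.final_labels, truth[perm]) > 0.95

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            run_ensemble(_matrix(10), FAST, n_ensemble=0)
        with pytest.raises(ValueError):
            run_ensemble(_matrix(10), FAST, n_ensemble=1, consensus="vote")


class TestFilterByConfidence:
    def _result(self):
        mat = _matrix(20, seed=9)
        return run_ensemble(mat, FAST, n_ensemble=2, seed=3)

    def test_zero_threshold_filters_nothing(self):
        res = self._result()
        out = filter_by_confidence(res, 0.0)
        assert (out.final_labels >= 0).all()

    def test_hundred_keeps_only_unanimous(self):
        res = self._result()
        out = filter_by_confidence(res, 100.0)
        kept = out.final_labels >= 0
        assert (res.confidence[kept] == 100.0).all()
        assert (res.confidence[~kept] < 100.0).all()

    def test_majority_threshold_arithmetic(self):
        # confidence 60 survives a 50 threshold; confidence 40 does not
        res = self._result()
        res.F = np.array([[2.0, 3.0], [2.0, 2.0]] + [[2.0, 0.0]] * 18)
        res.F[1, 0] = 2.0  # row [2,2] of E=5 -> conf 40 after resolve
        labels, conf = resolve(np.array([[2.0, 3.0], [2.0, 2.0]]), 5)
        assert conf[0] == pytest.approx(60.0) and conf[1] == pytest.approx(40.0)
        assert (conf >= 50.0).tolist() == [True, False]

    def test_affinity_retained_for_filtered_items(self):
        res = self._result()
        out = filter_by_confidence(res, 100.0)
        np.testing.assert_array_equal(out.affinity, res.affinity)

    def test_threshold_validated(self):
        res = self._result()
        with pytest.raises(ValueError):
            filter_by_confidence(res, -1.0)
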