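import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cartosom import (ExpressionMatrix, NormalizationPlan, DistanceSpec,
                      normalize, range_normalize_columns, compute_distance,
                      unit_variance_rows)
from cartosom.preprocess import prepare_features


def _mat(values, is_distance=False):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    return ExpressionMatrix([f"r{i}" for i in range(values.shape[0])],
                            [f"c{j}" for j in range(values.shape[1])],
                            values, is_distance)


class TestNormalize:
    def test_unit_variance_gives_unit_column_sd(self, rng):
        m = _mat(rng.normal(3.0, 5.0, size=(30, 4)))
        out = normalize(m, NormalizationPlan(unit_variance=True))
        np.testing.assert_allclose(out.values.std(axis=0), 1.0, atol=1e-12)

    def test_median_center_genes(self):
        out = normalize(_mat([[1.0, 2.0, 10.0]]),
                        NormalizationPlan(median_center_genes=True))
        np.testing.assert_array_equal(out.values, [[-1.0, 0.0, 8.0]])

    def test_sum_squares_on_scalar_matrix(self):
        out = normalize(_mat([[5.0]]), NormalizationPlan(sum_squares_normalize=True))
        np.testing.assert_allclose(out.values, [[1.0]])

    def test_sum_squares_square_matrix_reaches_unit_sums(self, rng):
        m = _mat(rng.normal(size=(5, 5)) + 2.0)
        out = normalize(m, NormalizationPlan(sum_squares_normalize=True))
        np.testing.assert_allclose((out.values ** 2).sum(axis=1), 1.0, atol=1e-5)
        np.testing.assert_allclose((out.values ** 2).sum(axis=0), 1.0, atol=1e-5)

    def test_sum_squares_rectangular_balanced_fixed_point(self, rng):
        # unit columns; rows all equal d/n (both cannot be 1 when n != d)
        m = _mat(rng.normal(size=(6, 4)) + 2.0)
        out = normalize(m, NormalizationPlan(sum_squares_normalize=True))
        np.testing.assert_allclose((out.values ** 2).sum(axis=0), 1.0, atol=1e-5)
        np.testing.assert_allclose((out.values ** 2).sum(axis=1), 4 / 6, atol=1e-5)

    def test_log2_rejects_non_positive_and_clips_on_request(self):
        m = _mat([[4.0, 0.0]])
        with pytest.raises(ValueError, match="log2"):
            normalize(m, NormalizationPlan(log2=True))
        out = normalize(m, NormalizationPlan(log2=True), log2_clip=True)
        np.testing.assert_allclose(out.values, [[2.0, 2.0]])

    def test_unit_variance_is_idempotent(self, rng):
        m = _mat(rng.normal(size=(20, 3)))
        plan = NormalizationPlan(unit_variance=True)
        once = normalize(m, plan)
        twice = normalize(once, plan)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-12)


class TestRangeNormalize:
    @pytest.mark.parametrize("col, expected", [
        ([1.0, 2.0, 3.0], [0.0, 50.0, 100.0]),
        ([7.0, 7.0, 7.0], [0.0, 0.0, 0.0]),
        ([-5.0, 5.0], [0.0, 100.0]),
    ])
    def test_column_examples(self, col, expected):
        out = range_normalize_columns(_mat(np.array(col)[:, None]))
        np.testing.assert_allclose(out.values[:, 0], expected)

    def test_idempotent(self, rng):
        m = _mat(rng.normal(size=(15, 3)))
        once = range_normalize_columns(m)
        twice = range_normalize_columns(once)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-12)


class TestUnitVarianceRows:
    def test_population_sd_convention(self):
        out = unit_variance_rows(_mat([[0.0, 2.0], [0.0, 4.0]]))
        # population sd of [0,2] is 1; of [0,4] is 2
        np.testing.assert_allclose(out.values, [[0.0, 2.0], [0.0, 2.0]])

    def test_constant_row_unchanged(self):
        out = unit_variance_rows(_mat([[3.0, 3.0, 3.0]]))
        np.testing.assert_array_equal(out.values, [[3.0, 3.0, 3.0]])


class TestComputeDistance:
    def test_euclidean_example(self):
        d = compute_distance(_mat([[0.0, 0.0], [3.0, 4.0]]), DistanceSpec())
        assert d.is_distance
        np.testing.assert_allclose(d.values, [[0.0, 5.0], [5.0, 0.0]])

    def test_pearson_self_distance_zero(self, rng):
        m = _mat(rng.normal(size=(5, 8)))
        d = compute_distance(m, DistanceSpec(metric="pearson"))
        np.testing.assert_allclose(np.diag(d.values), 0.0, atol=1e-12)

    def test_uncentered_proportional_vectors(self):
        # r = sum(x*y)/sqrt(sum x^2 * sum y^2) = 1 for proportional rows
        d = compute_distance(_mat([[1.0, 2.0], [2.0, 4.0]]),
                             DistanceSpec(metric="uncentered"))
        np.testing.assert_allclose(d.values[0, 1], 0.0, atol=1e-12)

    def test_pearson_zero_variance_row_gets_distance_one(self):
        d = compute_distance(_mat([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]]),
                             DistanceSpec(metric="pearson"))
        assert d.values[0, 1] == pytest.approx(1.0)

    def test_euclidean_matches_brute_force(self, rng):
        v = rng.normal(size=(20, 5))
        d = compute_distance(_mat(v), DistanceSpec()).values
        brute = np.empty((20, 20))
        for i in range(20):
            for j in range(20):
                brute[i, j] = np.sqrt(((v[i] - v[j]) ** 2).sum())
        np.testing.assert_allclose(d, brute, atol=1e-9)

    @pytest.mark.parametrize("metric", ["euclidean", "pearson", "uncentered"])
    def test_distance_matrix_invariants(self, metric, rng):
        m = _mat(rng.normal(size=(12, 6)))
        d = compute_distance(m, DistanceSpec(metric=metric)).values
        assert (d >= 0).all()
        np.testing.assert_allclose(d, d.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(d), 0.0, atol=1e-12)

    def test_requires_two_items(self):
        with pytest.raises(ValueError):
            compute_distance(_mat([[1.0, 2.0]]), DistanceSpec())


class TestPrepareFeatures:
    def test_distance_mode_yields_distance_profiles(self, rng):
        m = _mat(rng.normal(size=(6, 3)))
        out = prepare_features(m, DistanceSpec(mode="distance_matrix"))
        assert out.is_distance and out.values.shape == (6, 6)

    def test_feature_mode_passthrough(self, small_matrix):
        out = prepare_features(small_matrix, DistanceSpec())
        np.testing.assert_array_equal(out.values, small_matrix.values)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_range_normalize_bounds_property(seed):
    rng = np.random.default_rng(seed)
    m = _mat(rng.normal(scale=10.0, size=(8, 3)))
    out = range_normalize_columns(m).values
    assert out.min() >= -1e-9 and out.max() <= 100.0 + 1e-9
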