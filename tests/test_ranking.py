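"""Feature Sparsity Importance metric, aggregation and selection policies."""

import numpy as np
import pytest

import ecnn


def brute_force_importance(W1):
    """Literal loop implementation of the importance definition."""
    p, J = W1.shape
    means, variances = [], []
    for k in range(p):
        col = [abs(W1[k, j]) for j in range(J)]
        m = sum(col) / J
        means.append(m)
        variances.append(sum((c - m) ** 2 for c in col) / (J - 1))
    top = max(means)
    if top == 0:
        return np.zeros(p)
    return np.array([(m - v) / top for m, v in zip(means, variances)])


class TestWeightVariance:
    @pytest.mark.parametrize("column,expected", [
        ([0.5, 0.5], 0.0),
        ([1.0, 0.0], 0.5),
        ([1.0, 0.0, 1.0], 1 / 3),
    ])
    def test_sample_variance(self, column, expected):
        assert ecnn.weight_variance(np.array(column)) == pytest.approx(expected)

    def test_single_weight_rejected(self):
        with pytest.raises(ValueError):
            ecnn.weight_variance(np.array([0.5]))


class TestFeatureImportance:
    def test_fully_vs_disconnected_extremes(self):
        W1 = np.array([[1.0, 1.0, 1.0], [0.0, 0.0, 0.0]])
        assert np.allclose(ecnn.feature_importance(W1), [1.0, 0.0])

    def test_elementwise_sparsity_penalized(self):
        W1 = np.array([[1.0, 0.0], [1.0, 1.0]])
        assert np.allclose(ecnn.feature_importance(W1), [0.0, 1.0])

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            W1 = rng.uniform(-1, 1, size=(20, 5))
            assert np.allclose(ecnn.feature_importance(W1),
                               brute_force_importance(W1), atol=1e-12)

    def test_all_zero_matrix_gives_zeros(self):
        assert np.allclose(ecnn.feature_importance(np.zeros((4, 3))), 0.0)

    def test_not_scale_invariant(self):
        # means scale with c but variances with c^2, so the ranking is a
        # property of the bounded weights, not of rescaled copies
        rng = np.random.default_rng(1)
        W1 = rng.uniform(0, 1, size=(10, 4))
        r1 = ecnn.feature_importance(W1)
        r2 = ecnn.feature_importance(3.0 * W1)
        assert not np.allclose(r1, r2)

    def test_variance_strictly_decreases_importance(self):
        # fixed mean 0.5, growing spread
        cols = [np.full(4, 0.5),
                np.array([0.4, 0.6, 0.4, 0.6]),
                np.array([0.1, 0.9, 0.1, 0.9])]
        W1 = np.vstack(cols)
        r = ecnn.feature_importance(W1)
        assert r[0] > r[1] > r[2]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ecnn.feature_importance(np.zeros((0, 0)))


class TestAggregateImportance:
    def test_elementwise_mean(self):
        agg = ecnn.aggregate_importance([np.array([1.0, 0.0]),
                                         np.array([0.0, 1.0])])
        assert np.allclose(agg, [0.5, 0.5])

    def test_single_vector_identity(self):
        v = np.array([0.2, 0.9])
        assert np.allclose(ecnn.aggregate_importance([v]), v)

    def test_repeated_vector_identity(self):
        v = np.array([0.3, 0.1, 0.8])
        assert np.allclose(ecnn.aggregate_importance([v] * 5), v)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ecnn.aggregate_importance([np.zeros(2), np.zeros(3)])


class TestCategorizeFeatures:
    def test_three_way_taxonomy(self):
        W1 = np.array([[0.01, 0.03], [0.95, 0.99], [0.95, 0.02]])
        assert ecnn.categorize_features(W1) == ["disconnected", "full", "partial"]

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            ecnn.categorize_features(np.zeros((1, 2)), low=0.5, high=0.4)


class TestSelectTopk:
    def test_largest_k(self):
        r = np.array([0.9, 0.1, 0.5])
        sel = ecnn.select_topk(r, ["a", "b", "c"], 2)
        assert sel.names == ["a", "c"]

    def test_tie_broken_by_name(self):
        sel = ecnn.select_topk(np.array([0.5, 0.5, 0.1]), ["b", "a", "c"], 1)
        assert sel.names == ["a"]

    def test_k_equals_p_returns_descending(self):
        sel = ecnn.select_topk(np.array([0.1, 0.7, 0.4]), ["a", "b", "c"], 3)
        assert sel.names == ["b", "c", "a"]
        values = [v for _, v in sel.selected]
        assert values == sorted(values, reverse=True)

    def test_selection_is_idempotent(self):
        r = np.array([0.9, 0.2, 0.6, 0.4])
        names = ["a", "b", "c", "d"]
        sel = ecnn.select_topk(r, names, 3)
        again = ecnn.select_topk(np.array([v for _, v in sel.selected]),
                                 sel.names, 3)
        assert again.selected == sel.selected

    def test_k_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ecnn.select_topk(np.array([0.1]), ["a"], 2)


class TestSelectOutliers:
    def test_single_outlier_found(self):
        values = np.concatenate([
            np.random.default_rng(0).normal(0.08, 0.005, 100), [0.5]])
        names = [f"f{i}" for i in range(101)]
        mu, sigma = values.mean(), values.std()
        assert values[100] > mu + 3 * sigma  # construction sanity
        sel = ecnn.select_outliers(values, names, 3.0)
        assert sel.names == ["f100"]

    def test_degenerate_spread_selects_nothing(self):
        sel = ecnn.select_outliers(np.full(10, 0.3), [str(i) for i in range(10)])
        assert sel.selected == []


class TestSelectCumulative:
    def test_prefix_holding_quantile(self):
        sel = ecnn.select_cumulative(np.array([0.5, 0.3, 0.2]),
                                     ["a", "b", "c"], quantile=0.79)
        assert sel.names == ["a", "b"]

    def test_near_one_quantile_takes_all_nonzero(self):
        sel = ecnn.select_cumulative(np.array([0.5, 0.0, 0.2]),
                                     ["a", "b", "c"], quantile=0.999)
        assert sel.names == ["a", "c"]

    def test_single_nonzero_feature(self):
        for q in (0.05, 0.5, 0.95):
            sel = ecnn.select_cumulative(np.array([0.0, 0.4]), ["a", "b"], q)
            assert sel.names == ["b"]

    def test_negative_values_floored(self):
        sel = ecnn.select_cumulative(np.array([-0.2, 0.4]), ["a", "b"], 0.9)
        assert sel.names == ["b"]

    def test_all_zero_returns_empty(self):
        assert ecnn.select_cumulative(np.zeros(3), list("abc"), 0.9).selected == []


class TestImportanceReport:
    def test_aggregated_is_snapshot_mean(self, small_ensemble, small_cohort):
        report = ecnn.importance_report(small_ensemble, small_cohort.feature_names)
        assert np.allclose(report.aggregated, report.per_snapshot.mean(axis=0))
        assert len(report.categories) == small_cohort.n_features
        assert set(report.categories) <= {"disconnected", "partial", "full"}

    def test_policies_order_by_descending_importance(self, small_ensemble,
                                                     small_cohort):
        report = ecnn.importance_report(small_ensemble, small_cohort.feature_names)
        for policy in ("top_k", "sigma_outlier", "cumulative"):
            sel = ecnn.apply_policy(report, policy, k=5)
            values = [v for _, v in sel.selected]
            assert values == sorted(values, reverse=True)
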