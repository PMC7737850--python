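"""Confusion metrics, CV harness, baselines and simple statistics."""

import math

import numpy as np
import pytest

import ecnn
from ecnn.evaluation import DegenerateStatisticError, _eval_seed


class TestConfusionMetrics:
    def test_hand_confusion_table(self):
        m = ecnn.confusion_metrics([1, 1, 0, 0], [1, 0, 0, 0])
        assert (m.tp, m.fp, m.tn, m.fn) == (1, 0, 2, 1)
        assert m.accuracy == pytest.approx(0.75)
        assert m.tpr == pytest.approx(0.5)
        assert m.tnr == pytest.approx(1.0)
        assert m.ppv == pytest.approx(1.0)
        assert m.npv == pytest.approx(2 / 3)
        assert m.f1 == pytest.approx(2 / 3)

    def test_perfect_prediction(self):
        m = ecnn.confusion_metrics([1, 0, 1], [1, 0, 1])
        assert all(getattr(m, name) == 1.0
                   for name in ("accuracy", "tpr", "tnr", "ppv", "npv", "f1"))

    def test_always_positive_inactive_model(self):
        m = ecnn.confusion_metrics([1, 1, 0, 0], [1, 1, 1, 1])
        assert m.tpr == 1.0 and m.tnr == 0.0 and m.accuracy == 0.5

    def test_zero_denominator_gives_nan(self):
        m = ecnn.confusion_metrics([0, 0], [0, 0])
        assert math.isnan(m.tpr) and math.isnan(m.ppv)
        assert m.tnr == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ecnn.confusion_metrics([1, 0], [1])


class TestRunCv:
    def test_plan_size_and_aggregate(self, small_cohort, tiny_config):
        cv = ecnn.run_cv(small_cohort, tiny_config)
        assert len(cv.per_evaluation) == tiny_config.cv_k * tiny_config.cv_repeats
        accs = cv.metric_values("accuracy")
        assert cv.aggregate["accuracy"][0] == pytest.approx(np.nanmean(accs))

    def test_full_subset_identical_to_no_subset(self, small_cohort, tiny_config):
        a = ecnn.run_cv(small_cohort, tiny_config)
        b = ecnn.run_cv(small_cohort, tiny_config,
                        feature_subset=list(small_cohort.feature_names))
        assert [m.as_dict() for _, _, m in a.per_evaluation] == \
               [m.as_dict() for _, _, m in b.per_evaluation]

    def test_unknown_subset_rejected(self, small_cohort, tiny_config):
        with pytest.raises(KeyError):
            ecnn.run_cv(small_cohort, tiny_config, feature_subset=["nope"])

    def test_test_role_labels_do_not_affect_training(self, small_cohort,
                                                     tiny_config):
        # scrambling test-role labels must leave ranking untouched:
        # ranking trains on the train+validation roles only
        plan = ecnn.make_cv_folds(small_cohort.n_patients, tiny_config.cv_k,
                                  tiny_config.cv_repeats, seed=tiny_config.seed)
        test_idx = plan.assignments[0].test
        scrambled = ecnn.EventMatrix(
            values=small_cohort.values.copy(),
            feature_names=list(small_cohort.feature_names),
            labels=small_cohort.labels.copy(),
        )
        scrambled.labels[test_idx] = 1 - scrambled.labels[test_idx]
        rep_a, ens_a = ecnn.rank_features(small_cohort, tiny_config, plan)
        rep_b, ens_b = ecnn.rank_features(scrambled, tiny_config, plan)
        assert np.array_equal(rep_a.aggregated, rep_b.aggregated)
        assert all(np.array_equal(u, v)
                   for u, v in zip(ens_a.first_layers, ens_b.first_layers))

    def test_eval_seeds_stay_below_2_31(self):
        assert all(0 <= _eval_seed(s, i) < 2**31
                   for s in (0, 1, 2**20) for i in range(20))


class TestBackwardStepwise:
    STEP_CONFIG = dict(hidden_sizes=(8, 4), epochs=60, n_snapshots=2,
                       batch_size=32, seed=5, cv_k=3, cv_repeats=1)

    @staticmethod
    def _cohort(seed, n_informative=2):
        return ecnn.generate_cohort(ecnn.SimConfig(
            n_patients=600, n_features=10, n_informative=n_informative,
            sparsity=0.4, signal_strength=6.0, interaction_fraction=0.0,
            count_dispersion=1.5, seed=seed))

    def test_noise_features_eliminated_before_planted(self):
        # stepwise elimination is noisy at this scale; require the clean
        # outcome (only noise removed, planted retained) on a majority of seeds
        cfg = ecnn.TrainConfig(**self.STEP_CONFIG)
        successes = 0
        for seed in (21, 22, 23, 24, 25):
            cohort = self._cohort(seed)
            planted = [cohort.feature_names[i] for i in cohort.planted_features]
            noise = [n for n in cohort.feature_names if n not in planted][:2]
            survivors, trace = ecnn.backward_stepwise(
                cohort, planted + noise, cfg, tol=0.02)
            removed = [name for name, _ in trace[1:]]
            if removed and set(removed) <= set(noise) and \
                    all(p in survivors for p in planted):
                successes += 1
        assert successes >= 3

    def test_two_informative_features_both_retained(self):
        cfg = ecnn.TrainConfig(**self.STEP_CONFIG)
        cohort = self._cohort(21)
        planted = [cohort.feature_names[i] for i in cohort.planted_features]
        survivors, _ = ecnn.backward_stepwise(cohort, planted, cfg, tol=0.02)
        assert set(survivors) == set(planted)

    def test_tiny_initial_subset_rejected(self, tiny_config):
        cohort = self._cohort(21)
        with pytest.raises(ValueError):
            ecnn.backward_stepwise(cohort, [cohort.feature_names[0]], tiny_config)

    def test_trace_starts_with_baseline(self, tiny_config):
        cohort = self._cohort(21)
        planted = [cohort.feature_names[i] for i in cohort.planted_features]
        noise = [n for n in cohort.feature_names if n not in planted][:1]
        _, trace = ecnn.backward_stepwise(cohort, planted + noise,
                                          tiny_config, tol=0.0)
        assert trace[0][0] is None and 0.0 <= trace[0][1] <= 1.0


class TestRfBaseline:
    def test_planted_features_rank_high(self, small_cohort):
        imp = ecnn.rf_baseline_ranking(small_cohort, n_trees=100, seed=0)
        mask = np.zeros(small_cohort.n_features, bool)
        mask[small_cohort.planted_features] = True
        assert imp[mask].mean() > np.median(imp[~mask])

    def test_deterministic_given_seed(self, small_cohort):
        a = ecnn.rf_baseline_ranking(small_cohort, n_trees=50, seed=3)
        b = ecnn.rf_baseline_ranking(small_cohort, n_trees=50, seed=3)
        assert np.array_equal(a, b)

    def test_single_class_labels_rejected(self, small_cohort):
        degenerate = ecnn.EventMatrix(
            values=small_cohort.values,
            feature_names=list(small_cohort.feature_names),
            labels=np.zeros(small_cohort.n_patients, dtype=int),
        )
        with pytest.raises(ValueError):
            ecnn.rf_baseline_ranking(degenerate)


class TestRandomSubset:
    def test_full_draw_is_permutation(self):
        idx = ecnn.random_subset(6, 6, seed=0)
        assert sorted(idx.tolist()) == list(range(6))

    def test_seed_reproducible_and_empty_draw(self):
        assert np.array_equal(ecnn.random_subset(10, 4, 1),
                              ecnn.random_subset(10, 4, 1))
        assert ecnn.random_subset(5, 0, 0).size == 0

    def test_overdraw_rejected(self):
        with pytest.raises(ValueError):
            ecnn.random_subset(3, 4, 0)


class TestPearson:
    def test_perfect_correlations(self):
        r, _ = ecnn.pearson_feature_correlation([1, 2, 3], [1, 2, 3])
        assert r == pytest.approx(1.0)
        r, _ = ecnn.pearson_feature_correlation([1, 2, 3], [3, 2, 1])
        assert r == pytest.approx(-1.0)

    def test_binary_binary_is_phi(self):
        # contingency table tp=4, fp=1, fn=1, tn=4 -> phi = 0.6
        x = [1] * 5 + [0] * 5
        y = [1] * 4 + [0] + [1] + [0] * 4
        r, p = ecnn.pearson_feature_correlation(x, y)
        assert r == pytest.approx(0.6)
        assert 0 < p < 1

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateStatisticError):
            ecnn.pearson_feature_correlation([1, 1, 1], [0, 1, 0])


class TestPairedTtest:
    def test_matches_closed_form(self):
        a = np.array([0.7, 0.8, 0.9])
        b = np.array([0.6, 0.7, 0.85])
        t, p = ecnn.paired_ttest(a, b)
        d = a - b
        t_hand = d.mean() / (d.std(ddof=1) / np.sqrt(3))
        assert t == pytest.approx(t_hand, abs=1e-10)
        assert t == pytest.approx(5.0, abs=1e-10)
        assert 0 < p < 0.05

    def test_identical_vectors_degenerate(self):
        with pytest.raises(DegenerateStatisticError):
            ecnn.paired_ttest([0.5, 0.6], [0.5, 0.6])

    def test_constant_shift_degenerate(self):
        with pytest.raises(DegenerateStatisticError):
            ecnn.paired_ttest([0.7, 0.8, 0.9], [0.6, 0.7, 0.8])
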