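"""Evaluation-protocol tests: splits, alarms, prediction and
classification metrics, bootstrap and kappa."""

import numpy as np
import pytest

from chimerapred.evaluation import (AlarmPolicy, EpisodeTimeline,
                                    alarms_from_windows, bootstrap_ci,
                                    classification_metrics, cohens_kappa,
                                    prediction_metrics, split_episodes)


class TestSplits:
    def test_22_episodes_into_4_folds_sizes(self):
        folds = split_episodes(list(range(22)), n_folds=4, seed=0)
        sizes = sorted(np.bincount(folds, minlength=4), reverse=True)
        assert sizes == [6, 6, 5, 5]

    def test_same_seed_gives_identical_assignment(self):
        a = split_episodes(list(range(10)), 4, seizure_counts=[1, 2] * 5, seed=3)
        b = split_episodes(list(range(10)), 4, seizure_counts=[1, 2] * 5, seed=3)
        assert a == b

    def test_seizure_totals_balanced_within_one_of_optimum(self):
        """Greedy stratification matches the brute-force optimal spread on
        a 20-episode fixture with counts 1..5."""
        from itertools import product

        rng = np.random.default_rng(1)
        counts = rng.integers(1, 6, 20).tolist()
        folds = split_episodes(list(range(20)), 4, seizure_counts=counts, seed=0)
        totals = np.zeros(4)
        for ep, f in enumerate(folds):
            totals[f] += counts[ep]
        spread = totals.max() - totals.min()
        # brute-force optimum over balanced-size assignments is expensive;
        # a randomized search over many balanced assignments bounds it
        best = np.inf
        for _ in range(3000):
            perm = rng.permutation(20)
            t = np.zeros(4)
            for pos, ep in enumerate(perm):
                t[pos % 4] += counts[ep]
            best = min(best, t.max() - t.min())
        assert spread <= max(best, 1.0)

    def test_fewer_episodes_than_folds_rejected(self):
        with pytest.raises(ValueError):
            split_episodes([1, 2], 4)


def brute_force_alarms(p, t, policy):
    alarms, run, blocked = [], 0, -np.inf
    for prob, time in zip(p, t):
        run = run + 1 if prob > policy.probability_threshold else 0
        if run >= policy.consecutive_windows and time >= blocked:
            alarms.append(time)
            blocked = time + policy.refractory_minutes
            run = 0
    return alarms


class TestAlarms:
    def test_second_consecutive_window_fires(self):
        alarms = alarms_from_windows(np.array([0.9, 0.9]), np.array([0.0, 2.5]))
        assert alarms == [2.5]

    def test_isolated_positive_window_does_not_fire(self):
        alarms = alarms_from_windows(np.array([0.2, 0.9, 0.2, 0.9, 0.1]),
                                     np.arange(5) * 2.5)
        assert alarms == []

    def test_refractory_suppresses_follow_up_alarms(self):
        p = np.full(20, 0.9)
        t = np.arange(20) * 2.5  # minutes
        alarms = alarms_from_windows(p, t, AlarmPolicy(refractory_minutes=30.0))
        assert alarms[0] == 2.5
        assert all(b - a >= 30.0 for a, b in zip(alarms[:-1], alarms[1:]))

    def test_matches_bruteforce_scan_on_random_sequences(self):
        rng = np.random.default_rng(0)
        policy = AlarmPolicy()
        for _ in range(1000):
            n = int(rng.integers(5, 40))
            p = rng.uniform(0, 1, n)
            t = np.cumsum(rng.uniform(1, 3, n))
            assert alarms_from_windows(p, t, policy) == \
                brute_force_alarms(p, t, policy)


class TestPredictionMetrics:
    def test_single_alarm_40_minutes_before_onset(self):
        ep = EpisodeTimeline(duration=200.0, onset=150.0, ictal_end=152.0)
        report = prediction_metrics([[110.0]], [ep])
        assert report.horizon_sensitivity[30.0] == 0.0
        assert report.horizon_sensitivity[60.0] == 1.0
        assert report.horizon_sensitivity[90.0] == 1.0

    def test_no_alarms_gives_zero_everything(self):
        ep = EpisodeTimeline(duration=100.0, onset=95.0)
        report = prediction_metrics([[]], [ep])
        assert all(v == 0.0 for v in report.horizon_sensitivity.values())
        assert report.fp_per_hour == 0.0

    def test_scripted_fixture_matches_hand_computation(self):
        """10 episodes with scripted alarms: 6 hits at the 90-min horizon,
        4 at 30 min; 3 false alarms in 10 h of eligible baseline."""
        episodes, alarms = [], []
        for i in range(10):
            episodes.append(EpisodeTimeline(duration=150.0, onset=140.0,
                                            ictal_end=142.0))
            if i < 4:
                alarms.append([125.0])           # 15 min pre-onset
            elif i < 6:
                alarms.append([70.0])            # 70 min pre-onset
            elif i < 9:
                alarms.append([20.0])            # baseline false alarm
            else:
                alarms.append([])
        report = prediction_metrics(alarms, episodes)
        assert report.horizon_sensitivity[30.0] == pytest.approx(0.4)
        assert report.horizon_sensitivity[90.0] == pytest.approx(0.6)
        # eligible: 10 episodes x (50 min pre-horizon + 8 min post-ictal)
        eligible_hours = 10 * (50.0 + 8.0) / 60.0
        assert report.fp_per_hour == pytest.approx(3 / eligible_hours)

    def test_zero_eligible_time_rejected(self):
        ep = EpisodeTimeline(duration=90.0, onset=90.0, ictal_end=90.0)
        with pytest.raises(ValueError):
            prediction_metrics([[]], [ep])


class TestClassificationMetrics:
    def test_perfect_predictions(self):
        y = np.array([0, 1, 0, 1, 1])
        report = classification_metrics(y.astype(float), y)
        assert report.accuracy == 1.0 and report.sensitivity == 1.0
        assert report.specificity == 1.0 and report.auc_roc == 1.0

    def test_contingency_arithmetic(self):
        # TP=8, FN=2, FP=3, TN=17
        labels = np.array([1] * 10 + [0] * 20)
        scores = np.array([1.0] * 8 + [0.0] * 2 + [1.0] * 3 + [0.0] * 17)
        report = classification_metrics(scores, labels)
        assert report.sensitivity == pytest.approx(0.8)
        assert report.specificity == pytest.approx(0.85)
        assert report.accuracy == pytest.approx(25 / 30)

    def test_shuffled_labels_give_chance_auc(self):
        rng = np.random.default_rng(0)
        aucs = []
        for _ in range(100):
            scores = rng.uniform(0, 1, 200)
            labels = rng.integers(0, 2, 200)
            aucs.append(classification_metrics(scores, labels).auc_roc)
        assert abs(np.mean(aucs) - 0.5) < 0.05

    def test_single_class_reports_auc_absent(self):
        report = classification_metrics(np.array([0.2, 0.8]), np.array([1, 1]))
        assert report.auc_roc is None


class TestBootstrap:
    def test_constant_values_zero_width(self):
        lo, hi = bootstrap_ci(np.full(10, 0.7), seed=0)
        assert lo == hi == 0.7

    def test_interval_contains_point_estimate(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(0.8, 0.05, 30)
        lo, hi = bootstrap_ci(vals, seed=2)
        assert lo <= vals.mean() <= hi

    def test_width_matches_analytic_normal_reference(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(0.0, 1.0, 100)
        lo, hi = bootstrap_ci(vals, n_boot=2000, seed=4)
        analytic = 2 * 1.96 / np.sqrt(100)
        assert abs((hi - lo) - analytic) / analytic < 0.15

    def test_deterministic_given_seed(self):
        vals = np.random.default_rng(5).normal(size=20)
        assert bootstrap_ci(vals, seed=7) == bootstrap_ci(vals, seed=7)


class TestKappa:
    def test_identical_sequences_give_one(self):
        a = np.array([0, 1, 1, 0, 2])
        assert cohens_kappa(a, a) == pytest.approx(1.0)

    def test_independent_labels_near_zero(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 2, 10_000)
        b = rng.integers(0, 2, 10_000)
        assert abs(cohens_kappa(a, b)) < 0.05

    def test_hand_contingency(self):
        # a=b=1: 20, a=b=0: 15, a=1 b=0: 5, a=0 b=1: 10
        a = np.array([1] * 20 + [0] * 15 + [1] * 5 + [0] * 10)
        b = np.array([1] * 20 + [0] * 15 + [0] * 5 + [1] * 10)
        n = 50
        po = 35 / n
        pe = (25 / n) * (30 / n) + (25 / n) * (20 / n)
        assert cohens_kappa(a, b) == pytest.approx((po - pe) / (1 - pe))

    def test_degenerate_marginals_undefined(self):
        assert np.isnan(cohens_kappa(np.zeros(5), np.zeros(5)))
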