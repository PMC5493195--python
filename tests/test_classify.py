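import itertools
import math

import numpy as np
import pytest

from tremorstability import (
    ConfigurationError,
    ConfusionCounts,
    DataError,
    auc_mann_whitney,
    classify_fixed,
    compare_auc_bootstrap,
    cross_validate,
    diagnostic_metrics,
    duration_bootstrap,
    logistic_odds,
    optimal_threshold,
    roc,
)
from tremorstability.simulate import TremorModelParams, generate_recording


def auc_pairwise_oracle(scores, labels):
    """AUC by exhaustive pair enumeration (ties count one half)."""
    pos = [s for s, l in zip(scores, labels) if l == "ET"]
    neg = [s for s, l in zip(scores, labels) if l == "PD"]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestClassifyFixed:
    def test_strict_boundary_rule(self):
        preds = classify_fixed(np.array([0.7, 1.05, 1.06]), threshold=1.05)
        assert list(preds) == ["PD", "PD", "ET"]

    def test_all_correct_gives_unit_sensitivity(self):
        scores = np.array([1.2, 1.5, 2.0])
        labels = np.array(["ET", "ET", "ET"])
        _, counts = classify_fixed(scores, labels)
        assert counts.tp == 3 and counts.fn == 0

    def test_empty_table_rejected(self):
        with pytest.raises(DataError):
            classify_fixed(np.array([]))


class TestDiagnosticMetrics:
    def test_test_cohort_counts_both_directions(self):
        counts = ConfusionCounts(tp=19, fn=1, tn=14, fp=2)
        et = diagnostic_metrics(counts, direction="ET_vs_PD")
        assert et.lr_pos == pytest.approx(7.60, abs=0.005)
        assert et.lr_neg == pytest.approx(0.0571, abs=0.0005)
        assert et.accuracy == pytest.approx(33 / 36)
        pd_dir = diagnostic_metrics(counts, direction="PD_vs_ET")
        assert pd_dir.lr_pos == pytest.approx(17.50, abs=0.005)
        assert pd_dir.lr_neg == pytest.approx(0.1316, abs=0.0005)
        assert pd_dir.accuracy == pytest.approx(33 / 36)

    def test_chance_performance(self):
        rep = diagnostic_metrics(ConfusionCounts(1, 1, 1, 1))
        assert (rep.sensitivity, rep.specificity, rep.accuracy) == (0.5, 0.5, 0.5)
        assert rep.lr_pos == rep.lr_neg == 1.0

    def test_formula_invariants_over_count_scan(self):
        for tp, fn, tn, fp in itertools.product(range(0, 51, 7), repeat=4):
            if tp + fn == 0 or tn + fp == 0:
                continue
            rep = diagnostic_metrics(ConfusionCounts(tp, fn, tn, fp))
            assert rep.accuracy == pytest.approx((tp + tn) / (tp + fn + tn + fp))
            if rep.specificity < 1:
                assert rep.lr_pos == pytest.approx(
                    rep.sensitivity / (1 - rep.specificity)
                )
            else:
                assert math.isinf(rep.lr_pos)
            if rep.specificity > 0:
                assert rep.lr_neg == pytest.approx(
                    (1 - rep.sensitivity) / rep.specificity
                )
            else:
                assert math.isinf(rep.lr_neg)

    def test_perfect_specificity_sentinel(self):
        rep = diagnostic_metrics(ConfusionCounts(tp=5, fn=0, tn=5, fp=0))
        assert math.isinf(rep.lr_pos)


class TestRoc:
    def test_perfect_separation(self):
        scores = np.array([0.2, 0.4, 1.5, 2.0])
        labels = np.array(["PD", "PD", "ET", "ET"])
        assert roc(scores, labels).auc == 1.0

    def test_four_subject_example(self):
        scores = np.array([2.0, 3.0, 1.0, 2.5])
        labels = np.array(["ET", "ET", "PD", "PD"])
        assert roc(scores, labels).auc == pytest.approx(0.75)

    def test_auc_matches_pairwise_oracle_with_ties(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            n = rng.integers(4, 13)
            labels = np.array(["ET"] * (n // 2 + 1) + ["PD"] * (n - n // 2 - 1))
            if (labels == "PD").sum() == 0:
                continue
            scores = rng.integers(0, 5, size=n).astype(float)  # many ties
            assert auc_mann_whitney(scores, labels) == pytest.approx(
                auc_pairwise_oracle(scores, labels), abs=1e-12
            )

    def test_null_auc_near_half(self):
        rng = np.random.default_rng(2024)
        scores = rng.normal(0, 1, 200)
        labels = np.where(rng.random(200) < 0.5, "ET", "PD")
        assert roc(scores, labels).auc == pytest.approx(0.5, abs=0.08)

    def test_ci_clipped_and_ordered(self):
        scores = np.array([0.2, 0.4, 1.5, 2.0])
        labels = np.array(["PD", "PD", "ET", "ET"])
        result = roc(scores, labels)
        lo, hi = result.ci95
        assert 0.0 <= lo <= result.auc <= hi <= 1.0

    def test_delong_and_hanley_agree_in_order_of_magnitude(self):
        rng = np.random.default_rng(3)
        scores = np.concatenate([rng.normal(1, 1, 20), rng.normal(0, 1, 16)])
        labels = np.array(["ET"] * 20 + ["PD"] * 16)
        se_h = roc(scores, labels, ci_method="hanley").se
        se_d = roc(scores, labels, ci_method="delong").se
        assert 0.3 < se_h / se_d < 3.0

    def test_single_class_rejected(self):
        with pytest.raises(DataError):
            roc(np.array([1.0, 2.0]), np.array(["ET", "ET"]))


class TestOptimalThreshold:
    def test_separated_cohort_midpoint(self):
        scores = np.array([0.4, 0.9, 1.2, 2.0])
        labels = np.array(["PD", "PD", "ET", "ET"])
        choice = optimal_threshold(scores, labels)
        assert choice.observed == 0.9
        assert choice.midpoint == pytest.approx(1.05)
        assert choice.youden_j == pytest.approx(1.0)

    def test_exhaustive_candidate_enumeration(self):
        scores = np.array([0.5, 1.0, 1.5, 2.0, 2.5])
        labels = np.array(["PD", "ET", "PD", "ET", "ET"])
        best_j, best_c = -2.0, None
        for c in np.unique(scores):
            sens = np.mean(scores[labels == "ET"] > c)
            spec = np.mean(scores[labels == "PD"] <= c)
            j = sens - (1 - spec)
            if j >= best_j - 1e-12:
                best_j, best_c = j, c
        choice = optimal_threshold(scores, labels)
        assert choice.observed == best_c

    def test_threshold_reproduces_roc_operating_point(self, paper_features):
        scores = paper_features.tsi.to_numpy()
        labels = paper_features.label.to_numpy()
        choice = optimal_threshold(scores, labels)
        _, counts = classify_fixed(scores, labels, threshold=choice.observed)
        rep = diagnostic_metrics(counts)
        assert rep.sensitivity == pytest.approx(choice.sensitivity)
        assert rep.specificity == pytest.approx(choice.specificity)


class TestLogisticOdds:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(8)
        n = 2000
        x = rng.normal(0, 1, n)
        p = 1 / (1 + np.exp(-(0.3 + 2.0 * x)))
        labels = np.where(rng.random(n) < p, "ET", "PD")
        fit = logistic_odds(x, labels)
        assert fit.converged
        lo, hi = np.log(fit.exp_b_ci95[0]), np.log(fit.exp_b_ci95[1])
        assert lo < 2.0 < hi

    def test_uninformative_feature_covers_one(self):
        rng = np.random.default_rng(21)
        x = rng.normal(0, 1, 300)
        labels = np.where(rng.random(300) < 0.5, "ET", "PD")
        fit = logistic_odds(x, labels)
        assert fit.exp_b_ci95[0] < 1.0 < fit.exp_b_ci95[1]

    def test_constant_feature_rejected(self):
        with pytest.raises(DataError):
            logistic_odds(np.ones(20), np.array(["ET", "PD"] * 10))

    def test_perfect_separation_flagged(self):
        x = np.array([0.0, 0.1, 0.2, 1.0, 1.1, 1.2])
        labels = np.array(["PD", "PD", "PD", "ET", "ET", "ET"])
        fit = logistic_odds(x, labels)
        assert not fit.converged


class TestCrossValidate:
    def _cohort(self, n=60, seed=0, separated=True):
        rng = np.random.default_rng(seed)
        labels = np.array(["PD", "ET"] * (n // 2))
        if separated:
            scores = np.where(labels == "ET", 2.0, 0.5) + rng.normal(0, 0.1, n)
        else:
            scores = rng.normal(0, 1, n)
        return scores, labels

    def test_separable_feature_pools_to_perfect_accuracy(self):
        scores, labels = self._cohort(separated=True)
        result = cross_validate(scores, labels, folds=10, seed=1)
        assert result.pooled.accuracy == 1.0

    def test_shuffled_labels_near_chance(self):
        scores, labels = self._cohort(n=200, seed=5, separated=False)
        result = cross_validate(scores, labels, folds=10, seed=1)
        assert result.pooled.accuracy == pytest.approx(0.5, abs=0.1)

    def test_too_few_subjects_rejected(self):
        scores = np.arange(9, dtype=float)
        labels = np.array(["PD", "ET"] * 4 + ["PD"])
        with pytest.raises(DataError):
            cross_validate(scores, labels, folds=10)

    def test_always_positive_rule_yields_sens_one_spec_zero(self):
        scores, labels = self._cohort(n=40, separated=False)
        result = cross_validate(scores, labels, folds=10, seed=0, threshold=-np.inf)
        assert result.pooled.sensitivity == 1.0
        assert result.pooled.specificity == 0.0

    def test_reproducible_given_seed(self):
        scores, labels = self._cohort(n=80, seed=2, separated=False)
        a = cross_validate(scores, labels, folds=10, seed=33)
        b = cross_validate(scores, labels, folds=10, seed=33)
        assert a.pooled == b.pooled
        assert a.fold_thresholds == b.fold_thresholds


class TestCompareAucBootstrap:
    def test_identical_features_never_differ(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 40)
        labels = np.array(["ET", "PD"] * 20)
        result = compare_auc_bootstrap(a, a.copy(), labels, iterations=200, seed=1)
        assert result.fraction_a_better == 0.0
        assert result.fraction_tied == 1.0

    def test_separating_feature_beats_noise(self):
        rng = np.random.default_rng(3)
        labels = np.array(["ET"] * 50 + ["PD"] * 50)
        a = np.where(labels == "ET", 2.0, 0.0) + rng.normal(0, 0.2, 100)
        b = rng.normal(0, 1, 100)
        result = compare_auc_bootstrap(a, b, labels, iterations=500, seed=2)
        assert result.fraction_a_better > 0.99

    def test_zero_iterations_rejected(self):
        with pytest.raises(ConfigurationError):
            compare_auc_bootstrap(np.ones(4), np.ones(4), ["ET", "ET", "PD", "PD"], iterations=0)

    def test_unpaired_features_rejected(self):
        with pytest.raises(DataError):
            compare_auc_bootstrap(np.ones(4), np.ones(5), ["ET", "ET", "PD", "PD"])

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(9)
        labels = np.array(["ET", "PD"] * 15)
        a, b = rng.normal(0, 1, 30), rng.normal(0, 1, 30)
        r1 = compare_auc_bootstrap(a, b, labels, iterations=300, seed=7)
        r2 = compare_auc_bootstrap(a, b, labels, iterations=300, seed=7)
        assert r1 == r2


@pytest.fixture(scope="module")
def small_cohort():
    recs, labels = [], []
    for i, (jitter, label) in enumerate(
        [(0.3, "PD"), (0.4, "PD"), (2.2, "ET"), (2.5, "ET")]
    ):
        params = TremorModelParams(
            cycle_jitter_iqr=jitter, duration_s=40.0, seed=100 + i
        )
        recs.append(generate_recording(params)[0])
        labels.append(label)
    return recs, labels


class TestDurationBootstrap:
    def test_full_length_segment_is_forced_and_variance_free(self, small_cohort):
        recs, labels = small_cohort
        table = duration_bootstrap(recs, labels, durations=[37.0], iterations=10, seed=0)
        assert table.auc_sd.iloc[0] == 0.0

    def test_single_iteration_reports_zero_sd(self, small_cohort):
        recs, labels = small_cohort
        table = duration_bootstrap(recs, labels, durations=[10.0], iterations=1, seed=0)
        assert table.auc_sd.iloc[0] == 0.0
        assert 0.0 <= table.auc_mean.iloc[0] <= 1.0

    def test_duration_longer_than_recording_rejected(self, small_cohort):
        recs, labels = small_cohort
        with pytest.raises(Exception):
            duration_bootstrap(recs, labels, durations=[90.0], iterations=2, seed=0)
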