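"""Fold construction, AUC/CI statistics, and repeated-CV behaviour."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ehgterm.evaluation import (
    RepeatPlan,
    auc,
    auc_ci_logit,
    label_noise_auc_bound,
    metrics_at_specificity,
    predictor_summary,
    regression_diagnostics,
    repeated_cv,
    risk_ratio,
    stratified_kfold,
)
from ehgterm.models import PreparedCohort


def brute_force_auc(scores, labels):
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestStratifiedKfold:
    def test_study_sized_folds_are_exactly_balanced(self):
        labels = np.r_[np.ones(30), np.zeros(129)].astype(int)
        rng = np.random.default_rng(0)
        folds = stratified_kfold(labels, 5, rng)
        for f in range(5):
            mask = folds == f
            assert labels[mask].sum() == 6
            assert mask.sum() in (31, 32)

    def test_every_row_assigned_once(self):
        labels = (np.random.default_rng(1).random(57) < 0.3).astype(int)
        folds = stratified_kfold(labels, 5, np.random.default_rng(2))
        assert folds.size == 57
        assert set(folds) == set(range(5))

    def test_degenerate_single_fold_warned(self):
        with pytest.warns(UserWarning):
            folds = stratified_kfold(np.array([0, 1, 0, 1]), 1, np.random.default_rng(3))
        assert np.all(folds == 0)

    def test_small_class_rejected(self):
        labels = np.r_[np.ones(4), np.zeros(40)].astype(int)
        with pytest.raises(ValueError):
            stratified_kfold(labels, 5, np.random.default_rng(4))


class TestAuc:
    def test_boundary_cases(self):
        assert auc(np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0])) == 1.0
        assert auc(np.full(6, 0.5), np.array([1, 0, 1, 0, 1, 0])) == 0.5

    def test_worked_four_pair_example(self):
        scores = np.array([0.9, 0.7, 0.8, 0.2])
        labels = np.array([1, 1, 0, 0])
        assert auc(scores, labels) == pytest.approx(0.75)

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            n = int(rng.integers(6, 30))
            labels = np.zeros(n, int)
            labels[: max(1, n // 3)] = 1
            rng.shuffle(labels)
            scores = np.round(rng.random(n), 1)  # force ties
            assert abs(auc(scores, labels) - brute_force_auc(scores, labels)) < 1e-12

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            auc(np.array([0.5, 0.6]), np.array([1, 1]))


class TestAucCiLogit:
    def test_symmetric_about_half(self):
        lo, hi = auc_ci_logit(0.5, 500, 500)
        assert lo + hi == pytest.approx(1.0, abs=1e-9)

    def test_always_inside_unit_interval(self):
        for a in (0.51, 0.7, 0.9, 0.99):
            lo, hi = auc_ci_logit(a, 10, 40)
            assert 0.0 < lo < a < hi < 1.0

    def test_matches_bootstrap_oracle(self):
        # Binormal scores tuned near AUC 0.7 with the study's class sizes.
        rng = np.random.default_rng(6)
        n_pos, n_neg = 30, 129
        pos = rng.normal(0.74, 1.0, n_pos)
        neg = rng.normal(0.0, 1.0, n_neg)
        scores = np.r_[pos, neg]
        labels = np.r_[np.ones(n_pos), np.zeros(n_neg)].astype(int)
        point = auc(scores, labels)
        boots = []
        for _ in range(10_000):
            ip = rng.integers(0, n_pos, n_pos)
            ineg = rng.integers(0, n_neg, n_neg)
            boots.append(auc(np.r_[pos[ip], neg[ineg]], np.r_[labels[:n_pos], labels[n_pos:]]))
        b_lo, b_hi = np.percentile(boots, [2.5, 97.5])
        lo, hi = auc_ci_logit(point, n_pos, n_neg)
        assert abs(lo - b_lo) < 0.02
        assert abs(hi - b_hi) < 0.02

    def test_degenerate_auc_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            lo, hi = auc_ci_logit(1.0, 10, 10)
        assert 0.0 < lo < hi < 1.0


class TestRiskRatio:
    def test_equal_risks_give_unity(self):
        rr, _ = risk_ratio(5, 15, 10, 30)
        assert rr == pytest.approx(1.0)

    def test_worked_example(self):
        rr, (lo, hi) = risk_ratio(5, 5, 10, 30)
        assert rr == pytest.approx(2.0)
        assert lo == pytest.approx(0.881, abs=0.02)
        assert hi == pytest.approx(4.541, abs=0.02)

    def test_zero_event_cell_undefined(self):
        with pytest.raises(ZeroDivisionError):
            risk_ratio(0, 10, 5, 5)


class TestMetricsAtSpecificity:
    def test_perfect_classifier_hits_full_sensitivity(self):
        scores = np.r_[np.linspace(0.8, 1.0, 10), np.linspace(0.0, 0.4, 40)]
        labels = np.r_[np.ones(10), np.zeros(40)].astype(int)
        table = metrics_at_specificity(scores, labels)
        assert np.allclose(table["sensitivity"], 1.0)

    def test_prevalence_identity_holds_exactly(self):
        rng = np.random.default_rng(7)
        scores = rng.random(120)
        labels = (rng.random(120) < 0.2).astype(int)
        table = metrics_at_specificity(scores, labels)
        pi = labels.mean()
        for _, row in table.iterrows():
            sens, spec = row["sensitivity"], row["specificity"]
            expected_ppv = sens * pi / (sens * pi + (1 - spec) * (1 - pi))
            expected_npv = spec * (1 - pi) / (spec * (1 - pi) + (1 - sens) * pi)
            assert row["ppv"] == pytest.approx(expected_ppv)
            assert row["npv"] == pytest.approx(expected_npv)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            metrics_at_specificity(np.array([0.1, 0.2]), np.array([0, 0]))


class _OracleRecipe:
    """Scores equal to the labels (a deliberately leaked perfect model)."""

    needs_signals = False

    def fit_score(self, data, train_idx, test_idx, seed):
        return {"scores": data.labels[test_idx].astype(float)}


class _NoiseRecipe:
    """Pure-noise scores, independent of everything."""

    needs_signals = False

    def fit_score(self, data, train_idx, test_idx, seed):
        rng = np.random.default_rng(seed)
        return {"scores": rng.random(test_idx.size)}


def _clinical_free_cohort(n=160, prevalence=0.19, seed=0):
    rng = np.random.default_rng(seed)
    labels = (rng.random(n) < prevalence).astype(int)
    clinical = pd.DataFrame({"age": rng.normal(29, 5, n)})
    ga = np.where(labels == 1, 240.0, 280.0) + rng.normal(0, 3, n)
    return PreparedCohort(clinical=clinical, labels=labels, ga_delivery=ga)


class TestRepeatedCv:
    def test_oracle_scores_give_perfect_zero_width_auc(self):
        data = _clinical_free_cohort()
        plan = RepeatPlan(n_repeats=5, k=5, master_seed=1)
        result = repeated_cv(data, _OracleRecipe(), plan)
        assert result.auc_mean == 1.0
        assert result.auc_ci == (1.0, 1.0)

    def test_noise_scores_match_null_auc_variance(self):
        # Per-repeat pooled-AUC spread vs the closed-form Mann-Whitney
        # null sd, within a factor of two.
        data = _clinical_free_cohort(seed=2)
        plan = RepeatPlan(n_repeats=20, k=5, master_seed=3)
        result = repeated_cv(data, _NoiseRecipe(), plan)
        n1 = int(data.labels.sum())
        n0 = data.labels.size - n1
        theoretical = np.sqrt((n0 + n1 + 1) / (12 * n0 * n1))
        observed = result.aucs.std(ddof=1)
        assert theoretical / 2 < observed < theoretical * 2
        lo, hi = result.auc_ci
        assert lo <= 0.5 <= hi

    def test_plan_is_deterministic(self):
        labels = (np.random.default_rng(4).random(60) < 0.3).astype(int)
        a = RepeatPlan(3, 5, master_seed=9).build(labels)
        b = RepeatPlan(3, 5, master_seed=9).build(labels)
        for fa, fb in zip(a.assignments, b.assignments):
            np.testing.assert_array_equal(fa, fb)


class TestLabelNoiseBound:
    def test_noiseless_ages_separate_perfectly(self):
        ga = np.r_[np.linspace(200, 250, 10), np.linspace(262, 295, 40)]
        mean, (lo, hi) = label_noise_auc_bound(ga, sd_days=0.0, reps=5,
                                               rng=np.random.default_rng(8))
        assert mean == 1.0 and lo == hi == 1.0

    def test_huge_noise_collapses_to_chance(self):
        ga = np.r_[np.linspace(200, 250, 30), np.linspace(262, 295, 130)]
        mean, _ = label_noise_auc_bound(ga, sd_days=1e6, reps=40,
                                        rng=np.random.default_rng(9))
        assert abs(mean - 0.5) < 0.05

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            label_noise_auc_bound([270.0, 280.0], rng=np.random.default_rng(10))


class TestRegressionDiagnostics:
    def test_perfect_predictions(self):
        d = regression_diagnostics(np.array([260.0, 280, 300]), np.array([260.0, 280, 300]))
        assert d["rmse"] == 0 and d["r2"] == 1
        assert d["slope"] == pytest.approx(1.0, abs=1e-12)
        assert d["bland_altman_hi"] - d["bland_altman_lo"] == 0

    def test_constant_prediction_has_zero_r2(self):
        true = np.array([260.0, 280, 300])
        d = regression_diagnostics(np.full(3, true.mean()), true)
        assert d["r2"] == pytest.approx(0.0)

    def test_worked_triple(self):
        d = regression_diagnostics(np.array([270.0, 280, 290]), np.array([260.0, 280, 300]))
        assert d["rmse"] == pytest.approx(8.165, abs=0.001)
        assert d["slope"] == pytest.approx(0.5)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            regression_diagnostics(np.ones(3), np.ones(4))


class TestPredictorSummary:
    def test_percentages_use_non_missing_denominator(self):
        n = 159
        labels = np.r_[np.ones(30), np.zeros(129)].astype(int)
        placental = np.array([True] * 68 + [False] * 60 + [None] * 31, dtype=object)
        parous = np.array([True] * 51 + [False] * 108, dtype=object)
        clinical = pd.DataFrame({"placental_position": placental, "parous": parous})
        report = predictor_summary(clinical, labels)
        binary = report["binary"].set_index("variable")
        assert binary.loc["placental_position", "pct_positive"] == pytest.approx(
            100 * 68 / 128
        )
        assert binary.loc["parous", "pct_positive"] == pytest.approx(100 * 51 / 159)
        assert report["overview"]["pct_preterm"][0] == pytest.approx(100 * 30 / 159)

    def test_continuous_summary_reports_median_iqr_auc(self):
        rng = np.random.default_rng(11)
        labels = (rng.random(100) < 0.3).astype(int)
        age = rng.normal(29, 5, 100) + 2.0 * labels
        clinical = pd.DataFrame({"age": age})
        report = predictor_summary(clinical, labels)
        row = report["continuous"].iloc[0]
        assert row["median"] == pytest.approx(np.median(age))
        assert 0.5 < row["auc"] < 1.0
        assert row["auc_lo"] < row["auc"] < row["auc_hi"]
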