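"""Metrics, agreement analysis, cross-validation harnesses, strata."""

import numpy as np
import pytest

from fetalpeaks.clinical_reference import (FOLD_ACCURACY_PCT, FOLD_F1,
                                           cohort_table)
from fetalpeaks.evaluate import (EvaluationError, bland_altman,
                                 confusion_metrics, kfold_cv, loso_cv,
                                 match_peaks, pearson_r, roc_auc,
                                 round_half_even, stratified_summary)
from fetalpeaks.preprocess import FrameSet


class TestConfusionMetrics:
    def test_perfect_prediction(self):
        y = np.array([0, 1, 1, 0, 1])
        cm = confusion_metrics(y, y)
        assert cm.accuracy == 1.0 and cm.f1 == 1.0

    def test_direct_formula_evaluation(self):
        y_true = np.array([1] * 10 + [0] * 90)
        y_pred = np.array([1] * 8 + [0] * 2 + [1] * 2 + [0] * 88)
        cm = confusion_metrics(y_true, y_pred)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (8, 2, 2, 88)
        assert cm.accuracy == pytest.approx(0.96)
        assert cm.f1 == pytest.approx(0.8)
        assert cm.sensitivity == pytest.approx(0.8)
        assert cm.ppv == pytest.approx(0.8)

    def test_degenerate_all_negative_flags_f1(self):
        cm = confusion_metrics(np.zeros(10), np.zeros(10))
        assert cm.accuracy == 1.0
        assert cm.f1 == 0.0
        assert not cm.f1_defined

    def test_counts_partition_total(self):
        rng = np.random.default_rng(0)
        t, p = rng.integers(0, 2, 50), rng.integers(0, 2, 50)
        cm = confusion_metrics(t, p)
        assert cm.tp + cm.fp + cm.fn + cm.tn == 50
        for v in (cm.accuracy, cm.sensitivity, cm.ppv, cm.npv, cm.f1):
            assert 0.0 <= v <= 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(EvaluationError):
            confusion_metrics(np.zeros(3), np.zeros(4))


class TestRocAuc:
    def test_perfect_separation(self):
        y = np.array([0, 0, 1, 1])
        _, _, auc = roc_auc(y, np.array([0.1, 0.2, 0.8, 0.9]))
        assert auc == 1.0

    def test_anti_separation(self):
        y = np.array([0, 0, 1, 1])
        _, _, auc = roc_auc(y, np.array([0.9, 0.8, 0.2, 0.1]))
        assert auc == 0.0

    def test_independent_scores_give_half(self):
        rng = np.random.default_rng(42)
        y = rng.integers(0, 2, 10_000)
        _, _, auc = roc_auc(y, rng.random(10_000))
        assert auc == pytest.approx(0.5, abs=0.02)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 500)
        s = rng.random(500)
        _, _, a1 = roc_auc(y, s)
        _, _, a2 = roc_auc(y, np.exp(5 * s))
        assert a1 == pytest.approx(a2)

    def test_single_class_rejected(self):
        with pytest.raises(EvaluationError):
            roc_auc(np.ones(5), np.random.default_rng(0).random(5))


class TestPearson:
    def test_identity_and_reflection(self):
        x = np.array([1.0, 2, 3, 4])
        assert pearson_r(x, x)[0] == pytest.approx(1.0)
        assert pearson_r(x, -x)[0] == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        r, p = pearson_r([1, 2, 3, 4], [2, 1, 4, 3])
        assert r == pytest.approx(0.6)
        assert 0 < p < 1

    def test_zero_variance_rejected(self):
        with pytest.raises(EvaluationError):
            pearson_r([1, 1, 1], [1, 2, 3])


class TestBlandAltman:
    def test_identical_series(self):
        s = bland_altman([1.0, 2, 3], [1.0, 2, 3])
        assert s.bias == 0 and s.loa_low == 0 and s.loa_high == 0

    def test_constant_offset(self):
        s = bland_altman([1.0, 2, 3], [3.0, 4, 5])
        assert s.bias == pytest.approx(-2.0)
        assert s.loa_high - s.loa_low == pytest.approx(0.0)

    def test_two_point_sample_sd(self):
        s = bland_altman([0.0, 2.0], [2.0, 0.0])   # d = (-2, 2)
        assert s.bias == 0
        assert s.sd == pytest.approx(2.828, abs=1e-3)
        assert s.loa_high == pytest.approx(5.544, abs=1e-3)
        assert s.loa_low == pytest.approx(-5.544, abs=1e-3)

    def test_antisymmetry(self):
        rng = np.random.default_rng(5)
        a, b = rng.random(30), rng.random(30)
        s_ab, s_ba = bland_altman(a, b), bland_altman(b, a)
        assert s_ab.bias == pytest.approx(-s_ba.bias)
        assert (s_ab.loa_high - s_ab.loa_low) == pytest.approx(
            s_ba.loa_high - s_ba.loa_low)

    def test_insufficient_data_rejected(self):
        with pytest.raises(EvaluationError):
            bland_altman([1.0], [2.0])


def _majority_pipeline(Xtr, ytr, Xte):
    maj = int(np.bincount(ytr.astype(int)).argmax())
    return np.full(len(Xte), maj, dtype=int)


class TestKfold:
    def test_folds_partition_index_set(self):
        X = np.zeros((103, 4, 2))
        y = (np.arange(103) % 7 == 0).astype(int)
        res = kfold_cv(X, y, _majority_pipeline, k=5, seed=0)
        allidx = np.concatenate(res["fold_indices"])
        assert sorted(allidx.tolist()) == list(range(103))

    def test_same_seed_same_assignment(self):
        X = np.zeros((60, 2, 1))
        y = (np.arange(60) % 5 == 0).astype(int)
        r1 = kfold_cv(X, y, _majority_pipeline, k=3, seed=9)
        r2 = kfold_cv(X, y, _majority_pipeline, k=3, seed=9)
        for a, b in zip(r1["fold_indices"], r2["fold_indices"]):
            assert np.array_equal(a, b)

    def test_published_fold_average(self):
        assert round_half_even(float(np.mean(FOLD_ACCURACY_PCT)), 1) == 93.0
        assert round_half_even(float(np.mean(FOLD_F1)), 2) == 0.96

    def test_too_many_folds_rejected(self):
        with pytest.raises(EvaluationError):
            kfold_cv(np.zeros((3, 1, 1)), np.array([0, 1, 0]),
                     _majority_pipeline, k=5)


class TestLoso:
    def _cohort(self, n_subjects=4, n_frames=50):
        rng = np.random.default_rng(0)
        sets = []
        for i in range(n_subjects):
            y = (rng.random(n_frames) < 0.2).astype(int)
            sets.append(FrameSet(frames=rng.normal(size=(n_frames, 4, 2)),
                                 labels=y,
                                 starts=np.arange(n_frames) * 4,
                                 subject_id=f"s{i:02d}", fs=1000.0))
        return sets

    def test_majority_baseline_accuracy_equals_class0_fraction(self):
        sets = self._cohort()
        res = loso_cv(sets, _majority_pipeline)
        for fs in sets:
            acc = res["per_subject"][fs.subject_id].accuracy
            assert acc == pytest.approx(np.mean(fs.labels == 0))

    def test_single_subject_rejected(self):
        with pytest.raises(EvaluationError):
            loso_cv(self._cohort(1), _majority_pipeline)

    def test_cohort_mean_and_sd_match_reference_table(self):
        acc = cohort_table()["accuracy_pct"]
        assert round_half_even(float(acc.mean()), 1) == 88.8
        assert round_half_even(float(acc.std(ddof=1)), 1) == 6.4


class TestStratifiedSummary:
    def test_reference_strata_means(self):
        table = cohort_table()
        strata = {
            "ga_28_34": lambda t: (t.gestational_age_weeks >= 28)
            & (t.gestational_age_weeks <= 34),
            "ga_over_34": lambda t: t.gestational_age_weeks > 34,
            "ga_under_30": lambda t: t.gestational_age_weeks < 30,
            "no_condition": lambda t: t.status.isin(["normal", "none"]),
        }
        out = stratified_summary(table, strata, decimals=1)
        assert out["ga_28_34"] == 86.7
        assert round_half_even(out["ga_over_34"], 0) == 93.0
        assert round_half_even(out["ga_under_30"], 0) == 88.0
        assert round_half_even(out["no_condition"], 0) == 91.0

    def test_whole_cohort_stratum_equals_footer_mean(self):
        table = cohort_table()
        out = stratified_summary(table, {"all": lambda t: t.subject > 0},
                                 decimals=1)
        assert out["all"] == 88.8

    def test_empty_stratum_flagged_as_nan(self):
        out = stratified_summary(cohort_table(),
                                 {"none": lambda t: t.subject > 99})
        assert np.isnan(out["none"])


class TestMatchPeaks:
    def test_tolerant_one_to_one_matching(self):
        ref = np.array([1000, 2000, 3000])
        det = np.array([1010, 1950, 2500, 3049])
        out = match_peaks(det, ref, fs=1000.0, tol_ms=50.0)
        assert out["tp"] == 3 and out["fp"] == 1 and out["fn"] == 0

    def test_empty_detection(self):
        out = match_peaks(np.array([]), np.array([100, 200]), 1000.0)
        assert out["tp"] == 0 and out["fn"] == 2
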