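"""Confusion matrices, per-class metrics, ROC curves and both AUC variants."""

import numpy as np
import pytest

from causalcyto.evaluation import (
    ConfusionMatrix,
    auc_paper,
    classification_metrics,
    confusion_matrix,
    evaluate_predictions,
    roc_curve,
)
from causalcyto.exceptions import DataError, ValidationError


def brute_force_per_class(y_true, y_pred, c):
    tp = np.sum((y_true == c) & (y_pred == c))
    fp = np.sum((y_true != c) & (y_pred == c))
    fn = np.sum((y_true == c) & (y_pred != c))
    tn = np.sum((y_true != c) & (y_pred != c))
    return tp, fp, fn, tn


class TestConfusionMatrix:
    def test_perfect_predictions_are_diagonal(self):
        y = np.array([1, 2, 3, 1, 2, 3])
        cm = confusion_matrix(y, y, 3)
        assert (cm.counts == np.diag([2, 2, 2])).all()

    def test_hand_counted_example(self):
        cm = confusion_matrix([1, 1, 2, 2], [1, 2, 2, 2], 2)
        np.testing.assert_array_equal(cm.counts, [[1, 1], [0, 2]])

    def test_empty_input_gives_zero_matrix_and_metrics_error(self):
        cm = confusion_matrix([], [], 2)
        assert cm.total == 0
        with pytest.raises(DataError):
            classification_metrics(cm)

    def test_out_of_range_label_rejected(self):
        with pytest.raises(ValidationError):
            confusion_matrix([1, 4], [1, 2], 3)


class TestClassificationMetrics:
    def test_worked_binary_example(self):
        report = classification_metrics(ConfusionMatrix(np.array([[50, 0], [10, 40]])))
        assert report.accuracy == pytest.approx(0.90)
        assert report.precision[1] == pytest.approx(50 / 60, abs=1e-4)
        assert report.recall[1] == pytest.approx(1.0)
        assert report.f1[1] == pytest.approx(0.9091, abs=1e-4)

    def test_diagonal_matrix_scores_one(self):
        report = classification_metrics(ConfusionMatrix(np.diag([5, 7, 3])))
        assert report.accuracy == 1.0
        assert report.macro_f1 == 1.0

    def test_never_predicted_class_gets_zero_precision(self):
        cm = ConfusionMatrix(np.array([[3, 0], [2, 0]]))
        report = classification_metrics(cm)
        assert report.precision[2] == 0.0
        assert report.f1[2] == 0.0

    def test_f1_is_harmonic_mean(self, rng):
        counts = rng.integers(0, 30, size=(4, 4))
        counts[0, 0] += 1  # ensure non-empty
        report = classification_metrics(ConfusionMatrix(counts))
        for c in report.precision:
            p, r = report.precision[c], report.recall[c]
            expected = 0.0 if p + r == 0 else 2 * p * r / (p + r)
            assert report.f1[c] == pytest.approx(expected)

    def test_agrees_with_brute_force_counter(self, rng):
        y_true = rng.integers(1, 4, size=200)
        y_pred = rng.integers(1, 4, size=200)
        report = classification_metrics(confusion_matrix(y_true, y_pred, 3))
        for c in (1, 2, 3):
            tp, fp, fn, _ = brute_force_per_class(y_true, y_pred, c)
            assert report.precision[c] == pytest.approx(
                tp / (tp + fp) if tp + fp else 0.0
            )
            assert report.recall[c] == pytest.approx(
                tp / (tp + fn) if tp + fn else 0.0
            )


class TestAucPaper:
    def test_perfect_and_chance_points(self):
        assert auc_paper(1.0, 0.0) == 1.0
        for t in (0.0, 0.3, 1.0):
            assert auc_paper(t, t) == 0.5

    def test_direct_substitution(self):
        assert auc_paper(0.8, 0.2) == pytest.approx(0.8)

    def test_equals_balanced_accuracy(self, rng):
        for _ in range(20):
            tpr, fpr = rng.random(), rng.random()
            assert auc_paper(tpr, fpr) == pytest.approx((tpr + (1 - fpr)) / 2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            auc_paper(1.2, 0.0)


class TestRocCurve:
    def test_perfect_separation_gives_unit_area(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        y = np.array([1, 1, 0, 0])
        fpr, tpr, auc = roc_curve(scores, y)
        assert auc == pytest.approx(1.0)
        assert fpr[0] == 0 and tpr[0] == 0 and fpr[-1] == 1 and tpr[-1] == 1

    def test_matches_sklearn_on_random_scores(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.normal(size=300)
        y = rng.integers(2, size=300)
        _, _, auc = roc_curve(scores, y)
        assert auc == pytest.approx(roc_auc_score(y, scores), abs=1e-12)

    def test_null_scores_near_half(self, rng):
        scores = rng.normal(size=2000)
        y = rng.integers(2, size=2000)
        _, _, auc = roc_curve(scores, y)
        assert abs(auc - 0.5) < 0.04

    def test_sign_flip_complements_area(self, rng):
        scores = rng.normal(size=100)
        y = rng.integers(2, size=100)
        _, _, auc = roc_curve(scores, y)
        _, _, auc_neg = roc_curve(-scores, y)
        assert auc_neg == pytest.approx(1.0 - auc, abs=1e-12)

    def test_single_class_truth_rejected(self):
        with pytest.raises(DataError):
            roc_curve([0.1, 0.2], [1, 1])

    def test_curve_monotone(self, rng):
        scores = rng.normal(size=50)
        y = rng.integers(2, size=50)
        fpr, tpr, _ = roc_curve(scores, y)
        assert (np.diff(fpr) >= 0).all() and (np.diff(tpr) >= 0).all()


class TestEvaluatePredictions:
    def test_full_report_on_soft_predictions(self, rng):
        y = rng.integers(1, 4, size=120)
        proba = rng.dirichlet(np.ones(3), size=120)
        # make predictions informative for class 1
        proba[y == 1, 0] += 1.0
        proba /= proba.sum(axis=1, keepdims=True)
        report = evaluate_predictions(y, proba, 3)
        assert 0 <= report.accuracy <= 1
        assert set(report.auc_trapezoid) == {1, 2, 3, "macro"}
        assert report.auc_trapezoid[1] > 0.8
        assert 0 <= report.auc_point["macro"] <= 1
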