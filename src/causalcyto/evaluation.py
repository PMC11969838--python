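"""Classification evaluation: confusion matrices, per-class metrics, ROC/AUC.

Per-class scores follow the usual one-vs-rest reduction of the confusion
matrix: precision = TP/(TP+FP), recall = TP/(TP+FN), F1 the harmonic mean,
accuracy = trace/total, with the 0/0 -> 0 convention.  Macro averages are
unweighted means over classes (micro averaging is available).

Two AUC variants are reported and clearly labeled:

* ``auc_trapezoid`` — area under the ROC curve from a full threshold sweep
  (the standard definition);
* ``auc_point`` — the single-operating-point quantity
  (TPR - FPR + 1) / 2 evaluated at the argmax decision, which equals the
  balanced accuracy of that operating point.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .exceptions import DataError, ValidationError

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion_matrix",
    "classification_metrics",
    "auc_paper",
    "roc_curve",
    "evaluate_predictions",
]

log = logging.getLogger(__name__)


@dataclass
class ConfusionMatrix:
    """C x C count matrix; rows are true classes, columns predictions."""

    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValidationError("confusion matrix must be square")
        if np.any(self.counts < 0):
            raise ValidationError("confusion matrix counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def n_classes(self) -> int:
        return self.counts.shape[0]

    def plot(self, path=None, class_names=None):
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4.5, 4))
        ax.imshow(self.counts, cmap="Blues")
        names = class_names or [str(i + 1) for i in range(self.n_classes)]
        ax.set_xticks(range(self.n_classes), names, rotation=45)
        ax.set_yticks(range(self.n_classes), names)
        ax.set_xlabel("predicted")
        ax.set_ylabel("true")
        for i in range(self.n_classes):
            for j in range(self.n_classes):
                ax.text(j, i, str(self.counts[i, j]), ha="center", va="center")
        if path is not None:
            fig.savefig(path, dpi=120, bbox_inches="tight")
            plt.close(fig)
        return ax


def confusion_matrix(y_true, y_pred, n_classes: int) -> ConfusionMatrix:
    """Count matrix with labels coded 1..C."""
    y_true = np.asarray(y_true, dtype=int).ravel()
    y_pred = np.asarray(y_pred, dtype=int).ravel()
    if y_true.shape != y_pred.shape:
        raise ValidationError("y_true and y_pred must have equal length")
    for name, y in (("y_true", y_true), ("y_pred", y_pred)):
        if y.size and (y.min() < 1 or y.max() > n_classes):
            raise ValidationError(f"{name} labels must lie in 1..{n_classes}")
    counts = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(counts, (y_true - 1, y_pred - 1), 1)
    return ConfusionMatrix(counts=counts)


@dataclass
class MetricsReport:
    precision: dict
    recall: dict
    f1: dict
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    cm: ConfusionMatrix
    auc_trapezoid: dict = field(default_factory=dict)   # per class + "macro"
    auc_point: dict = field(default_factory=dict)       # per class + "macro"

    def to_json(self, path=None) -> str:
        payload = {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "per_class": {
                str(c): {
                    "precision": self.precision[c],
                    "recall": self.recall[c],
                    "f1": self.f1[c],
                }
                for c in self.precision
            },
            "auc_trapezoid": {str(k): v for k, v in self.auc_trapezoid.items()},
            "auc_point": {str(k): v for k, v in self.auc_point.items()},
            "confusion_matrix": self.cm.counts.tolist(),
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def summary(self) -> str:
        lines = [
            f"{'class':>8} {'precision':>10} {'recall':>8} {'f1':>8}",
        ]
        for c in self.precision:
            lines.append(
                f"{c:>8} {self.precision[c]:>10.3f} {self.recall[c]:>8.3f} "
                f"{self.f1[c]:>8.3f}"
            )
        lines.append(
            f"{'macro':>8} {self.macro_precision:>10.3f} {self.macro_recall:>8.3f} "
            f"{self.macro_f1:>8.3f}"
        )
        lines.append(f"accuracy: {self.accuracy:.4f}")
        if self.auc_trapezoid:
            lines.append(f"macro AUC (trapezoid): {self.auc_trapezoid['macro']:.3f}")
        return "\n".join(lines)


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def classification_metrics(
    cm: ConfusionMatrix, average: str = "macro"
) -> MetricsReport:
    """Per-class and averaged precision/recall/F1/accuracy from a count matrix."""
    if cm.total == 0:
        raise DataError("cannot compute metrics from an empty evaluation")
    counts = cm.counts
    C = cm.n_classes
    precision, recall, f1 = {}, {}, {}
    for c in range(C):
        tp = counts[c, c]
        fp = counts[:, c].sum() - tp
        fn = counts[c, :].sum() - tp
        if tp + fp == 0:
            log.warning("class %d never predicted; precision set to 0", c + 1)
        p = _safe_div(tp, tp + fp)
        r = _safe_div(tp, tp + fn)
        precision[c + 1] = p
        recall[c + 1] = r
        f1[c + 1] = _safe_div(2 * p * r, p + r)
    accuracy = counts.trace() / cm.total
    if average == "micro":
        tp_all = counts.trace()
        macro_p = macro_r = macro_f = tp_all / cm.total
    else:
        macro_p = float(np.mean(list(precision.values())))
        macro_r = float(np.mean(list(recall.values())))
        macro_f = float(np.mean(list(f1.values())))
    return MetricsReport(
        precision=precision,
        recall=recall,
        f1=f1,
        accuracy=float(accuracy),
        macro_precision=macro_p,
        macro_recall=macro_r,
        macro_f1=macro_f,
        cm=cm,
    )


def auc_paper(tpr: float, fpr: float) -> float:
    """Single-operating-point AUC: (TPR - FPR + 1) / 2.

    Algebraically identical to the balanced accuracy of the operating point
    ((TPR + TNR) / 2 with TNR = 1 - FPR).
    """
    for name, v in (("tpr", tpr), ("fpr", fpr)):
        if not 0 <= v <= 1:
            raise ValidationError(f"{name} must be in [0, 1], got {v}")
    return (tpr - fpr + 1.0) / 2.0


def roc_curve(scores, y_true_binary):
    """Threshold sweep over unique scores.

    Returns ``(fpr, tpr, auc)`` with the curve running monotonically from
    (0, 0) to (1, 1) and the trapezoidal area under it.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    y = np.asarray(y_true_binary).ravel().astype(bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise DataError("ROC undefined: need at least one positive and one negative")
    order = np.argsort(-scores, kind="stable")
    ys = y[order]
    tps = np.cumsum(ys)
    fps = np.cumsum(~ys)
    # collapse ties: keep the last point of each distinct score value
    distinct = np.r_[np.diff(scores[order]) != 0, True]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def evaluate_predictions(y_true, proba, n_classes: int) -> MetricsReport:
    """Full report from true labels (1..C) and a class-probability matrix."""
    proba = np.asarray(proba, dtype=float)
    y_true = np.asarray(y_true, dtype=int).ravel()
    y_pred = proba.argmax(axis=1) + 1
    cm = confusion_matrix(y_true, y_pred, n_classes)
    report = classification_metrics(cm)
    trap, point = {}, {}
    for c in range(n_classes):
        positive = y_true == c + 1
        if positive.all() or not positive.any():
            continue
        _, _, auc = roc_curve(proba[:, c], positive)
        trap[c + 1] = auc
        predicted_pos = y_pred == c + 1
        tpr = _safe_div(np.sum(predicted_pos & positive), positive.sum())
        fpr = _safe_div(np.sum(predicted_pos & ~positive), (~positive).sum())
        point[c + 1] = auc_paper(tpr, fpr)
    if trap:
        trap["macro"] = float(np.mean([v for k, v in trap.items() if k != "macro"]))
        point["macro"] = float(np.mean([v for k, v in point.items() if k != "macro"]))
    report.auc_trapezoid = trap
    report.auc_point = point
    return report
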