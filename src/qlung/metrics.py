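"""Confusion matrices, classification metrics and ROC/AUC.

The three-class task (normal / benign / malignant) is summarized by a 3x3
confusion matrix (rows = true, columns = predicted). Binary metrics use a
one-vs-rest collapse with a designated positive class (malignant by
default): sensitivity TP/(TP+FN), specificity TN/(TN+FP), precision
TP/(TP+FP), F1 the harmonic mean of precision and sensitivity, and the
Matthews correlation coefficient. Rates are reported as percentages; any
0/0 cell is defined as 0 and flagged rather than raised, so batch
evaluation always completes.

ROC curves sweep a threshold over the unique scores (ties grouped) and the
area is the trapezoidal integral, which equals the pairwise concordance
probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .imaging import CLASSES

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion_3class",
    "collapse_binary",
    "compute_metrics",
    "roc_auc",
]


@dataclass
class ConfusionCounts:
    """Binary confusion cells; all nonnegative."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValidationError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricReport:
    """The standard metric column set; rate fields are percentages."""

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    mcc: float
    auc: float | None = None
    flags: list[str] = field(default_factory=list)

    def to_row(self) -> dict:
        row = {
            "accuracy_pct": round(self.accuracy, 2),
            "sensitivity_pct": round(self.sensitivity, 2),
            "specificity_pct": round(self.specificity, 2),
            "f1_pct": round(self.f1, 2),
            "precision_pct": round(self.precision, 2),
            "mcc": round(self.mcc, 4),
        }
        if self.auc is not None:
            row["auc"] = round(self.auc, 4)
        return row


def confusion_3class(y_true, y_pred, classes=CLASSES) -> np.ndarray:
    """3x3 count matrix, rows = true class, columns = predicted class."""
    y_true, y_pred = list(y_true), list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValidationError("label vectors must have equal length")
    index = {c: i for i, c in enumerate(classes)}
    mat = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        if t not in index or p not in index:
            raise ValidationError(f"unknown label in ({t!r}, {p!r}); known: {classes}")
        mat[index[t], index[p]] += 1
    return mat


def collapse_binary(matrix3: np.ndarray, positive_class: str = "malignant",
                    classes=CLASSES) -> ConfusionCounts:
    """One-vs-rest collapse of a multi-class confusion matrix."""
    matrix3 = np.asarray(matrix3)
    k = len(classes)
    if matrix3.shape != (k, k) or (matrix3 < 0).any():
        raise ValidationError(f"expected a nonnegative {k}x{k} matrix")
    if positive_class not in classes:
        raise ValidationError(f"unknown positive class {positive_class!r}")
    p = classes.index(positive_class)
    tp = int(matrix3[p, p])
    fn = int(matrix3[p].sum() - tp)
    fp = int(matrix3[:, p].sum() - tp)
    tn = int(matrix3.sum() - tp - fn - fp)
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def _safe_rate(num: float, den: float, name: str, flags: list[str]) -> float:
    if den == 0:
        flags.append(f"{name}: 0/0 defined as 0")
        return 0.0
    return num / den


def compute_metrics(counts: ConfusionCounts, auc: float | None = None) -> MetricReport:
    """Full metric report from binary confusion counts."""
    if counts.total == 0:
        raise ValidationError("cannot compute metrics on zero samples")
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    flags: list[str] = []
    accuracy = (tp + tn) / counts.total
    sensitivity = _safe_rate(tp, tp + fn, "sensitivity", flags)
    specificity = _safe_rate(tn, tn + fp, "specificity", flags)
    precision = _safe_rate(tp, tp + fp, "precision", flags)
    f1 = _safe_rate(2 * precision * sensitivity, precision + sensitivity, "f1", flags)
    mcc_den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    if mcc_den == 0:
        flags.append("mcc: undefined denominator defined as 0")
        mcc = 0.0
    else:
        mcc = (tp * tn - fp * fn) / mcc_den
    return MetricReport(
        accuracy=100.0 * accuracy,
        sensitivity=100.0 * sensitivity,
        specificity=100.0 * specificity,
        precision=100.0 * precision,
        f1=100.0 * f1,
        mcc=float(mcc),
        auc=auc,
        flags=flags,
    )


def roc_auc(y_true, scores) -> tuple[np.ndarray, float]:
    """ROC curve points and trapezoidal AUC for binary labels vs scores.

    ``y_true`` holds 0/1 (or booleans); ``scores`` rank the positive class.
    Tied scores are grouped into a single threshold step. Returns an
    (m, 2) array of (fpr, tpr) points from (0, 0) to (1, 1) and the area.
    """
    y = np.asarray(y_true).astype(int).ravel()
    s = np.asarray(scores, dtype=float).ravel()
    if y.size != s.size or y.size == 0:
        raise ValidationError("labels and scores must be equal-length, nonempty")
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("ROC requires both classes present")

    order = np.argsort(-s, kind="stable")
    y_sorted, s_sorted = y[order], s[order]
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    n = y.size
    while i < n:
        j = i
        while j < n and s_sorted[j] == s_sorted[i]:  # group tied scores
            tp += y_sorted[j]
            fp += 1 - y_sorted[j]
            j += 1
        points.append((fp / n_neg, tp / n_pos))
        i = j
    pts = np.asarray(points)
    auc = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    return pts, auc
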