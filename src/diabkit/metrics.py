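"""Multi-class evaluation: confusion matrix, macro metrics, macro ROC.

All rates are computed from per-class true/false positive/negative counts:

    accuracy        = sum_i TP_i / sum_i (TP_i + FN_i)
    macro-precision = (1/n) sum_i TP_i / (TP_i + FP_i)
    macro-recall    = (1/n) sum_i TP_i / (TP_i + FN_i)
    macro-F1        = harmonic mean of macro-precision and macro-recall

together with the bookkeeping identity
sum_i (TP_i + FN_i) = sum_i (TP_i + FP_i) = total samples, asserted on
every report.  The macro ROC averages one-vs-rest curves for each class on
a common false-positive-rate grid; AUC is the trapezoid integral.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ClassAbsentError",
    "MetricsReport",
    "confusion_matrix",
    "classification_metrics",
    "macro_roc",
    "FPR_GRID",
]

#: common false-positive-rate grid used for one-vs-rest curve averaging
FPR_GRID = np.linspace(0.0, 1.0, 101)


class ClassAbsentError(ValueError):
    """A class with no true instances makes recall undefined."""


@dataclass
class MetricsReport:
    classes: np.ndarray
    confusion: np.ndarray  # rows = true class, columns = predicted
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    per_class_precision: np.ndarray = field(default=None)
    per_class_recall: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        n = int(self.confusion.sum())
        tp = np.diag(self.confusion)
        fn = self.confusion.sum(axis=1) - tp
        fp = self.confusion.sum(axis=0) - tp
        assert int((tp + fn).sum()) == n == int((tp + fp).sum()), (
            "TP/FN/FP bookkeeping identity violated"
        )
        for v in (self.accuracy, self.macro_precision, self.macro_recall, self.macro_f1):
            assert -1e-12 <= v <= 1 + 1e-12


def confusion_matrix(y_true, y_pred, classes=None) -> tuple[np.ndarray, np.ndarray]:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    if classes is None:
        classes = np.unique(np.concatenate([y_true, y_pred]))
    classes = np.asarray(classes)
    index = {c: i for i, c in enumerate(classes)}
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[index[t], index[p]] += 1
    return classes, cm


def classification_metrics(y_true, y_pred, classes=None) -> MetricsReport:
    """Accuracy and macro precision/recall/F1 from labels.

    Raises :class:`ClassAbsentError` when a requested class never occurs in
    ``y_true`` (its recall would be 0/0); precision for a never-predicted
    class is taken as 0, the usual conservative convention.
    """
    classes, cm = confusion_matrix(y_true, y_pred, classes)
    tp = np.diag(cm).astype(float)
    fn = cm.sum(axis=1) - tp
    fp = cm.sum(axis=0) - tp
    if np.any(tp + fn == 0):
        empty = classes[(tp + fn) == 0]
        raise ClassAbsentError(
            f"classes {empty.tolist()} absent from y_true; recall undefined"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(tp + fp > 0, tp / np.where(tp + fp > 0, tp + fp, 1), 0.0)
    recall = tp / (tp + fn)
    macro_p = float(precision.mean())
    macro_r = float(recall.mean())
    macro_f1 = (
        0.0 if macro_p + macro_r == 0 else 2 * macro_p * macro_r / (macro_p + macro_r)
    )
    return MetricsReport(
        classes=classes,
        confusion=cm,
        accuracy=float(tp.sum() / (tp + fn).sum()),
        macro_precision=macro_p,
        macro_recall=macro_r,
        macro_f1=macro_f1,
        per_class_precision=precision,
        per_class_recall=recall,
    )


def _binary_roc(y_bin: np.ndarray, score: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-vs-rest ROC points (fpr, tpr) by threshold sweep."""
    order = np.argsort(-score, kind="stable")
    y = y_bin[order]
    tps = np.cumsum(y)
    fps = np.cumsum(1 - y)
    # keep the last point of each distinct score (threshold boundaries)
    distinct = np.r_[np.diff(score[order]) != 0, True]
    tps, fps = tps[distinct], fps[distinct]
    tpr = np.r_[0.0, tps / max(tps[-1], 1)]
    fpr = np.r_[0.0, fps / max(fps[-1], 1)]
    return fpr, tpr


def macro_roc(y_true, proba, classes) -> tuple[np.ndarray, np.ndarray, float]:
    """Macro-average one-vs-rest ROC on the common FPR grid.

    Returns ``(fpr_grid, mean_tpr, auc)`` with AUC the trapezoid integral
    of the averaged curve.
    """
    y_true = np.asarray(y_true)
    proba = np.asarray(proba, dtype=float)
    if proba.shape != (len(y_true), len(classes)):
        raise ValueError(
            f"probability matrix shape {proba.shape} does not match "
            f"{len(y_true)} samples x {len(classes)} classes"
        )
    tprs = []
    for j, c in enumerate(classes):
        y_bin = (y_true == c).astype(int)
        if y_bin.sum() == 0:
            raise ClassAbsentError(f"class {c} absent from y_true; ROC undefined")
        fpr, tpr = _binary_roc(y_bin, proba[:, j])
        tprs.append(np.interp(FPR_GRID, fpr, tpr))
    mean_tpr = np.mean(tprs, axis=0)
    mean_tpr[0] = 0.0
    auc = float(np.trapezoid(mean_tpr, FPR_GRID))
    return FPR_GRID.copy(), mean_tpr, auc
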