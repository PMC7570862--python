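"""Confusion matrix and multiclass Accuracy / Precision / Recall / F1.

Per-class values come from one-vs-rest TP/FP/FN/TN counts:

    Accuracy  = (TP + TN) / (TP + TN + FP + FN)
    Precision = TP / (TP + FP)
    Recall    = TP / (TP + FN)
    F1        = 2 * Precision * Recall / (Precision + Recall)

Values are reported in percent (2 decimals in tables, full precision
internally).  The per-class "accuracy" column in the report equals recall,
matching the convention of per-activity recognition tables in this field.
Overall summaries are available micro-averaged (pool all counts; for
single-label multiclass this makes precision = recall = accuracy) or
support-weighted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion",
    "per_class_metrics",
    "overall_metrics",
    "f1_score_percent",
    "evaluate",
]


@dataclass
class ConfusionMatrix:
    """C x C count table; rows are true classes, columns predicted classes."""

    counts: np.ndarray
    classes: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        c = len(self.classes)
        if self.counts.shape != (c, c):
            raise ValueError("counts must be square with one row per class")
        if np.any(self.counts < 0):
            raise ValueError("counts must be nonnegative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def one_vs_rest(self) -> pd.DataFrame:
        """Per-class TP/FP/FN/TN derived from the matrix."""
        cm = self.counts
        tp = np.diag(cm)
        fp = cm.sum(axis=0) - tp
        fn = cm.sum(axis=1) - tp
        tn = cm.sum() - tp - fp - fn
        return pd.DataFrame(
            {"TP": tp, "FP": fp, "FN": fn, "TN": tn}, index=list(self.classes)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)


def confusion(
    y_true: Sequence[str], y_pred: Sequence[str], class_order: Sequence[str]
) -> ConfusionMatrix:
    """Count (true, predicted) pairs into a matrix under ``class_order``."""
    y_true = np.asarray(y_true, dtype=object)
    y_pred = np.asarray(y_pred, dtype=object)
    if len(y_true) != len(y_pred):
        raise ValueError("y_true and y_pred must have equal length")
    classes = list(class_order)
    index = {c: i for i, c in enumerate(classes)}
    unknown = sorted({l for l in np.concatenate([y_true, y_pred]) if l not in index})
    if unknown:
        raise ValueError(f"labels outside class_order: {unknown}")
    cm = np.zeros((len(classes), len(classes)), dtype=int)
    for t, p in zip(y_true, y_pred):
        cm[index[t], index[p]] += 1
    return ConfusionMatrix(cm, classes)


def _safe_div(num: np.ndarray, den: np.ndarray, what: str) -> np.ndarray:
    zero = den == 0
    if np.any(zero):
        warnings.warn(
            f"{what}: zero denominator for class(es) "
            f"{np.flatnonzero(zero).tolist()}; reporting 0",
            RuntimeWarning,
            stacklevel=3,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(zero, 0.0, num / np.where(zero, 1.0, den))
    return out


def per_class_metrics(cm: ConfusionMatrix) -> pd.DataFrame:
    """Per-class accuracy/precision/recall/F1 in percent.

    The accuracy column repeats recall (the per-activity convention); the
    one-vs-rest accuracy (TP+TN)/total is included as ``ovr_accuracy``.
    F1 is 0 where precision + recall is 0.
    """
    ovr = cm.one_vs_rest()
    tp, fp, fn, tn = (ovr[c].to_numpy(float) for c in ("TP", "FP", "FN", "TN"))
    precision = _safe_div(tp, tp + fp, "precision")
    recall = _safe_div(tp, tp + fn, "recall")
    denom = precision + recall
    with np.errstate(divide="ignore", invalid="ignore"):
        f1 = np.where(denom > 0, 2.0 * precision * recall / np.where(denom > 0, denom, 1.0), 0.0)
    ovr_acc = _safe_div(tp + tn, tp + tn + fp + fn, "ovr accuracy")
    return pd.DataFrame(
        {
            "accuracy": recall * 100.0,
            "precision": precision * 100.0,
            "recall": recall * 100.0,
            "f1": f1 * 100.0,
            "ovr_accuracy": ovr_acc * 100.0,
            "support": (tp + fn).astype(int),
        },
        index=list(cm.classes),
    )


def overall_metrics(cm: ConfusionMatrix, mode: str = "micro") -> pd.Series:
    """Overall accuracy/precision/recall/F1 in percent.

    micro: pool all one-vs-rest counts; precision = recall = F1 = accuracy
    = trace/total exactly.  weighted: support-weighted means of the
    per-class values (zero-support classes are excluded with a warning);
    accuracy remains trace/total.
    """
    if mode not in ("micro", "weighted"):
        raise ValueError("mode must be 'micro' or 'weighted'")
    total = cm.total
    acc = float(np.trace(cm.counts)) / total * 100.0 if total else 0.0
    if mode == "micro":
        return pd.Series(
            {"accuracy": acc, "precision": acc, "recall": acc, "f1": acc, "mode": "micro"}
        )
    per = per_class_metrics(cm)
    support = per["support"].to_numpy(float)
    if np.any(support == 0):
        warnings.warn(
            "weighted averages exclude zero-support class(es): "
            f"{[c for c, s in zip(cm.classes, support) if s == 0]}",
            RuntimeWarning,
            stacklevel=2,
        )
    w = support / support.sum() if support.sum() else support
    return pd.Series(
        {
            "accuracy": acc,
            "precision": float(per["precision"].to_numpy() @ w),
            "recall": float(per["recall"].to_numpy() @ w),
            "f1": float(per["f1"].to_numpy() @ w),
            "mode": "weighted",
        }
    )


def f1_score_percent(precision_pct: float, recall_pct: float) -> float:
    """Harmonic mean of a precision/recall pair given in percent."""
    if precision_pct + recall_pct == 0:
        return 0.0
    return 2.0 * precision_pct * recall_pct / (precision_pct + recall_pct)


@dataclass
class MetricsReport:
    """Confusion matrix plus per-class and overall metric tables."""

    cm: ConfusionMatrix
    per_class: pd.DataFrame
    overall: pd.Series
    mode: str = "micro"

    def to_csv(self, per_class_path, confusion_path) -> None:
        self.per_class.round(2).to_csv(per_class_path)
        self.cm.to_frame().to_csv(confusion_path)

    def __str__(self) -> str:
        lines = ["Per-class metrics (%):", self.per_class.round(2).to_string(), ""]
        ov = self.overall.drop(labels=["mode"])
        lines.append(
            f"Overall ({self.overall['mode']}): "
            + "  ".join(f"{k}={float(v):.2f}" for k, v in ov.items())
        )
        return "\n".join(lines)


def evaluate(
    y_true: Sequence[str],
    y_pred: Sequence[str],
    class_order: Sequence[str],
    mode: str = "micro",
) -> MetricsReport:
    """Build the full report from label sequences."""
    cm = confusion(y_true, y_pred, class_order)
    return MetricsReport(
        cm=cm,
        per_class=per_class_metrics(cm),
        overall=overall_metrics(cm, mode),
        mode=mode,
    )
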