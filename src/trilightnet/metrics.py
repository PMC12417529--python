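"""Classification metrics for the pMCI/sMCI task.

Balanced accuracy is the mean of sensitivity and specificity,
(TP/(TP+FN) + TN/(TN+FP)) / 2, which is robust to the roughly 1:2.4
class imbalance of the cohort.  AUROC is computed threshold-free from
the Mann-Whitney U statistic with midranks for tied scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_from_predictions",
    "auroc",
    "compute_metrics",
]


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    accuracy: float
    sensitivity: float
    precision: float
    auroc: float
    f1: float
    balanced_accuracy: float
    specificity: float = float("nan")
    n_params: int = 0
    flops: int = 0

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "precision": self.precision,
            "auroc": self.auroc,
            "f1": self.f1,
            "balanced_accuracy": self.balanced_accuracy,
            "specificity": self.specificity,
            "n_params": self.n_params,
            "flops": self.flops,
        }


def confusion_from_predictions(probabilities, labels, threshold: float = 0.5) -> ConfusionCounts:
    """Count TP/TN/FP/FN comparing ``p >= threshold`` to binary labels."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    if p.shape != y.shape:
        raise ValueError(f"length mismatch: {p.shape} probabilities vs {y.shape} labels")
    pred = (p >= threshold).astype(int)
    return ConfusionCounts(
        tp=int(np.sum((pred == 1) & (y == 1))),
        tn=int(np.sum((pred == 0) & (y == 0))),
        fp=int(np.sum((pred == 1) & (y == 0))),
        fn=int(np.sum((pred == 0) & (y == 1))),
    )


def auroc(labels, scores) -> float:
    """AUROC via the midrank Mann-Whitney statistic (ties get half credit)."""
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        warnings.warn("AUROC undefined: one class is empty", stacklevel=2)
        return float("nan")
    ranks = rankdata(s)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (empty denominator); reporting NaN", stacklevel=3)
        return float("nan")
    return num / den


def compute_metrics(c: ConfusionCounts, probabilities=None, labels=None) -> MetricsReport:
    """All threshold metrics from a confusion table; AUROC from scores
    when provided (NaN otherwise)."""
    sens = _ratio(c.tp, c.tp + c.fn, "sensitivity")
    spec = _ratio(c.tn, c.tn + c.fp, "specificity")
    prec = _ratio(c.tp, c.tp + c.fp, "precision")
    acc = _ratio(c.tp + c.tn, c.total, "accuracy")
    if np.isnan(sens) or np.isnan(prec) or (sens + prec) == 0:
        f1 = float("nan")
        if not (np.isnan(sens) or np.isnan(prec)):
            warnings.warn("F1 undefined (sensitivity + precision = 0)", stacklevel=2)
    else:
        f1 = 2 * prec * sens / (prec + sens)
    bal = 0.5 * (sens + spec)
    auc = auroc(labels, probabilities) if probabilities is not None else float("nan")
    return MetricsReport(
        accuracy=acc,
        sensitivity=sens,
        precision=prec,
        auroc=auc,
        f1=f1,
        balanced_accuracy=bal,
        specificity=spec,
    )
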