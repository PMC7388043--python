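"""Performance metrics: confusion-based scores, ROC/PR curves, Bland-Altman.

Metrics with a zero denominator are reported as ``None`` (undefined) rather
than 0, so downstream aggregation can never silently bias a summary.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
from sklearn.metrics import precision_recall_curve, roc_curve

__all__ = [
    "ConfusionCounts",
    "NightCountRecord",
    "confusion_metrics",
    "roc_pr_curves",
    "bland_altman",
    "count_difference_histogram",
]


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)


@dataclasses.dataclass(frozen=True)
class NightCountRecord:
    """Automated vs annotated event count for one night."""

    night_id: str
    automated_count: int
    annotated_count: int

    def __post_init__(self):
        if self.automated_count < 0 or self.annotated_count < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def difference(self) -> int:
        return self.automated_count - self.annotated_count


def _ratio(num: float, den: float) -> float | None:
    return num / den if den else None


def confusion_metrics(c: ConfusionCounts) -> dict:
    """Sensitivity, specificity, accuracy, MCC, PPV and NPV of a confusion table.

    MCC = (tp*tn - fp*fn) / sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn)); any metric
    whose denominator is zero comes back as None.
    """
    if c.total < 1:
        raise ValueError("empty confusion table")
    tp, fp, fn, tn = c.tp, c.fp, c.fn, c.tn
    denom = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    return {
        "sensitivity": _ratio(tp, tp + fn),
        "specificity": _ratio(tn, tn + fp),
        "accuracy": (tp + tn) / c.total,
        "mcc": (tp * tn - fp * fn) / denom if denom else None,
        "ppv": _ratio(tp, tp + fp),
        "npv": _ratio(tn, tn + fn),
    }


def roc_pr_curves(scores: Sequence[float], labels: Sequence[bool]) -> dict:
    """ROC and precision-recall curves over all score thresholds.

    Areas are trapezoidal; the PR baseline is the positive-class prevalence
    (the precision of a random classifier).
    """
    y = np.asarray(labels, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if y.all() or not y.any():
        raise ValueError("both classes must be present")
    fpr, tpr, roc_thr = roc_curve(y, s)
    roc_auc = float(np.trapezoid(tpr, fpr))
    precision, recall, pr_thr = precision_recall_curve(y, s)
    # integrate along the traced curve (recall decreasing); tied-recall
    # segments are vertical and contribute no area
    pr_auc = float(-np.trapezoid(precision, recall))
    return {
        "roc": {"fpr": fpr, "tpr": tpr, "thresholds": roc_thr, "auc": roc_auc},
        "pr": {
            "precision": precision, "recall": recall, "thresholds": pr_thr,
            "auc": pr_auc, "baseline": float(y.mean()),
        },
    }


def bland_altman(records: Sequence[NightCountRecord]) -> dict:
    """Mean count difference and 1.96-SD limits of agreement.

    Differences are automated minus annotated; limits use the sample
    standard deviation (ddof=1).
    """
    if len(records) < 2:
        raise ValueError("need at least 2 night records")
    d = np.array([r.difference for r in records], dtype=float)
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return {
        "mean_diff": mean,
        "lower_limit": mean - 1.96 * sd,
        "upper_limit": mean + 1.96 * sd,
        "sd": sd,
        "n": len(records),
    }


def count_difference_histogram(records: Sequence[NightCountRecord]) -> dict:
    """Histogram of per-night count differences; bar heights sum to n nights."""
    d = np.array([r.difference for r in records], dtype=int)
    values, counts = np.unique(d, return_counts=True)
    return {int(v): int(c) for v, c in zip(values, counts)}
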