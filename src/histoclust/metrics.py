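"""Confusion-matrix bookkeeping and derived classification metrics.

The malignant class is the positive class throughout.  Rates follow the
clinical convention: sensitivity (TP rate) and specificity (TN rate) are
class-conditional percentages, so sensitivity + FN rate = 100 and
specificity + FP rate = 100.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .data import BENIGN, MALIGNANT  # noqa: F401  (re-exported for convenience)

__all__ = [
    "ConfusionCounts",
    "MetricReport",
    "confusion",
    "report",
    "mcc_score",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Raw confusion-matrix cells with malignant as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricReport:
    """Percentage-scale metric panel for one evaluated model.

    ``mcc`` is on the natural [-1, 1] scale; everything else is a
    percentage in [0, 100].  ``precision_undefined`` flags the degenerate
    case tp + fp = 0 where precision is reported as 0 by convention.
    """

    sensitivity_pct: float
    specificity_pct: float
    fp_rate_pct: float
    fn_rate_pct: float
    accuracy_pct: float
    precision_pct: float
    recall_pct: float
    f_measure_pct: float
    mcc: float
    precision_undefined: bool = False

    def as_dict(self) -> dict:
        return {
            "sensitivity_pct": self.sensitivity_pct,
            "specificity_pct": self.specificity_pct,
            "fp_rate_pct": self.fp_rate_pct,
            "fn_rate_pct": self.fn_rate_pct,
            "accuracy_pct": self.accuracy_pct,
            "precision_pct": self.precision_pct,
            "recall_pct": self.recall_pct,
            "f_measure_pct": self.f_measure_pct,
            "mcc": self.mcc,
        }


def confusion(labels, predictions) -> ConfusionCounts:
    """Count TP/FP/TN/FN for binary labels (0 = benign, 1 = malignant)."""
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if labels.shape != predictions.shape:
        raise ValueError(
            f"labels and predictions differ in length: {labels.shape} vs {predictions.shape}"
        )
    if labels.size == 0:
        raise ValueError("cannot build a confusion matrix from empty input")
    pos = labels == MALIGNANT
    pred_pos = predictions == MALIGNANT
    return ConfusionCounts(
        tp=int(np.sum(pos & pred_pos)),
        fp=int(np.sum(~pos & pred_pos)),
        tn=int(np.sum(~pos & ~pred_pos)),
        fn=int(np.sum(pos & ~pred_pos)),
    )


def mcc_score(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when a marginal is empty."""
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def report(c: ConfusionCounts) -> MetricReport:
    """Derive the full metric panel from confusion counts.

    Requires at least one actual positive and one actual negative,
    otherwise the class-conditional rates are undefined.
    """
    if c.tp + c.fn == 0:
        raise ValueError("no actual positives: sensitivity undefined")
    if c.tn + c.fp == 0:
        raise ValueError("no actual negatives: specificity undefined")

    sens = 100.0 * c.tp / (c.tp + c.fn)
    spec = 100.0 * c.tn / (c.tn + c.fp)
    acc = 100.0 * (c.tp + c.tn) / c.n

    precision_undefined = (c.tp + c.fp) == 0
    if precision_undefined:
        warnings.warn(
            "no predicted positives: precision undefined, reporting 0",
            RuntimeWarning,
            stacklevel=2,
        )
        prec = 0.0
    else:
        prec = 100.0 * c.tp / (c.tp + c.fp)

    rec = sens
    f = 0.0 if prec + rec == 0 else 2.0 * prec * rec / (prec + rec)

    return MetricReport(
        sensitivity_pct=sens,
        specificity_pct=spec,
        fp_rate_pct=100.0 - spec,
        fn_rate_pct=100.0 - sens,
        accuracy_pct=acc,
        precision_pct=prec,
        recall_pct=rec,
        f_measure_pct=f,
        mcc=mcc_score(c),
        precision_undefined=precision_undefined,
    )
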