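"""Confusion-count based segmentation metrics.

All five metrics used throughout the package — Dice similarity coefficient
(DSC), Jaccard index (JI), sensitivity, specificity and precision — are
computed from a single pixelwise confusion pass over a (prediction, truth)
pair of binary masks.  DSC doubles as the optimizer's fitness.

Degenerate denominators follow the "perfect agreement" convention: a ratio
whose denominator is zero (e.g. precision with no positive predictions, DSC
with two empty masks) is defined as 1.0.  Slices without tumor are common in
abdominal CT, and an empty prediction on an empty truth is a correct result
that must not poison aggregates.

Counting is per 2-D pixel: the networks operate on individual axial slices,
so per-slice pixel counts are the natural unit even when the masks originate
from a 3-D label volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class ShapeMismatchError(ValueError):
    """Raised when a prediction/truth mask pair disagree in shape."""


def _as_bool(mask: np.ndarray) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.dtype == bool:
        return arr
    vals = np.unique(arr)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"mask contains values other than 0/1: {vals[:10]}")
    return arr.astype(bool)


def _check_pair(pred: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p, t = _as_bool(pred), _as_bool(truth)
    if p.shape != t.shape:
        raise ShapeMismatchError(f"pred shape {p.shape} != truth shape {t.shape}")
    return p, t


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel counts of the four prediction/truth agreement classes."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricReport:
    """The five segmentation metrics for one mask pair (or an aggregate)."""

    dsc: float
    ji: float
    sensitivity: float
    specificity: float
    precision: float

    def as_dict(self) -> dict[str, float]:
        return {
            "dsc": self.dsc,
            "ji": self.ji,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
        }


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Tally TP/FP/FN/TN pixels between a predicted and a ground-truth mask."""
    p, t = _check_pair(pred, truth)
    tp = int(np.count_nonzero(p & t))
    fp = int(np.count_nonzero(p & ~t))
    fn = int(np.count_nonzero(~p & t))
    tn = int(np.count_nonzero(~p & ~t))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def _ratio(num: float, den: float) -> float:
    return 1.0 if den == 0 else num / den


def dsc(pred: np.ndarray, truth: np.ndarray) -> float:
    """Dice similarity coefficient 2|P∩Q| / (|P|+|Q|); 1.0 if both empty."""
    p, t = _check_pair(pred, truth)
    inter = int(np.count_nonzero(p & t))
    size_sum = int(np.count_nonzero(p)) + int(np.count_nonzero(t))
    return _ratio(2.0 * inter, size_sum)


def jaccard(pred: np.ndarray, truth: np.ndarray) -> float:
    """Jaccard index |P∩Q| / |P∪Q| (intersection over union); 1.0 if both empty."""
    p, t = _check_pair(pred, truth)
    inter = int(np.count_nonzero(p & t))
    union = int(np.count_nonzero(p | t))
    return _ratio(float(inter), union)


def precision(counts: ConfusionCounts) -> float:
    """TP / (TP + FP); 1.0 when there are no positive predictions."""
    return _ratio(float(counts.tp), counts.tp + counts.fp)


def sensitivity(counts: ConfusionCounts) -> float:
    """TP / (TP + FN), a.k.a. recall; 1.0 when the truth has no positives."""
    return _ratio(float(counts.tp), counts.tp + counts.fn)


def specificity(counts: ConfusionCounts) -> float:
    """TN / (TN + FP); 1.0 when the truth has no negatives."""
    return _ratio(float(counts.tn), counts.tn + counts.fp)


def metric_report(pred: np.ndarray, truth: np.ndarray) -> MetricReport:
    """All five metrics from one confusion-count pass."""
    c = confusion_counts(pred, truth)
    inter = c.tp
    size_sum = 2 * c.tp + c.fp + c.fn  # |P| + |Q|
    union = c.tp + c.fp + c.fn
    return MetricReport(
        dsc=_ratio(2.0 * inter, size_sum),
        ji=_ratio(float(inter), union),
        sensitivity=sensitivity(c),
        specificity=specificity(c),
        precision=precision(c),
    )


def mean_report(reports: list[MetricReport]) -> MetricReport:
    """Aggregate per-case reports by the per-case mean (the dominant DSC
    reporting convention), not by pooling confusion counts."""
    if not reports:
        raise ValueError("cannot aggregate an empty list of reports")
    return MetricReport(
        dsc=float(np.mean([r.dsc for r in reports])),
        ji=float(np.mean([r.ji for r in reports])),
        sensitivity=float(np.mean([r.sensitivity for r in reports])),
        specificity=float(np.mean([r.specificity for r in reports])),
        precision=float(np.mean([r.precision for r in reports])),
    )
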