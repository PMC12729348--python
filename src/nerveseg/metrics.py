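"""Pixel-overlap metrics for binary segmentation masks.

Six standard metrics computed from the pixel confusion counts of a
predicted mask against its ground truth:

    Dice        = 2·TP / ((TP+FP) + (TP+FN))
    IoU         = TP / (TP+FP+FN)
    accuracy    = (TP+TN) / (TP+TN+FP+FN)
    precision   = TP / (TP+FP)
    specificity = TN / (TN+FP)
    sensitivity = TP / (TP+FN)

Conventions: when both masks are empty (TP+FP+FN = 0) Dice and IoU are 1;
any other zero denominator yields ``nan`` (an "undefined" marker, not an
exception). Aggregation reports per-metric mean and sample (n-1) SD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "MetricRecord",
    "confusion",
    "dice",
    "iou",
    "accuracy",
    "precision",
    "specificity",
    "sensitivity",
    "all_metrics",
    "summarize",
]

METRIC_NAMES = ("dice", "iou", "accuracy", "precision", "specificity", "sensitivity")


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel tallies of a predicted mask against ground truth."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Exact TP/TN/FP/FN pixel tallies for two same-shaped binary masks."""
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))
    tn = pred.size - tp - fp - fn
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def dice(c: ConfusionCounts) -> float:
    if c.tp + c.fp + c.fn == 0:
        return 1.0
    return 2.0 * c.tp / ((c.tp + c.fp) + (c.tp + c.fn))


def iou(c: ConfusionCounts) -> float:
    if c.tp + c.fp + c.fn == 0:
        return 1.0
    return c.tp / (c.tp + c.fp + c.fn)


def accuracy(c: ConfusionCounts) -> float:
    return (c.tp + c.tn) / c.total if c.total else float("nan")


def precision(c: ConfusionCounts) -> float:
    return c.tp / (c.tp + c.fp) if c.tp + c.fp else float("nan")


def specificity(c: ConfusionCounts) -> float:
    return c.tn / (c.tn + c.fp) if c.tn + c.fp else float("nan")


def sensitivity(c: ConfusionCounts) -> float:
    return c.tp / (c.tp + c.fn) if c.tp + c.fn else float("nan")


_FUNCS = (dice, iou, accuracy, precision, specificity, sensitivity)


@dataclass(frozen=True)
class MetricRecord:
    """All six metrics for one image."""

    image_id: str
    dice: float
    iou: float
    accuracy: float
    precision: float
    specificity: float
    sensitivity: float


def all_metrics(pred: np.ndarray, truth: np.ndarray, image_id: str = "") -> MetricRecord:
    c = confusion(pred, truth)
    vals = {f.__name__: f(c) for f in _FUNCS}
    return MetricRecord(image_id=image_id, **vals)


def summarize(records: list[MetricRecord], strict: bool = True) -> pd.DataFrame:
    """Per-metric mean and sample SD (n-1) across images.

    With a single record the sample SD is undefined; strict mode raises,
    otherwise SD is reported as 0 and the frame carries a ``degenerate_n``
    attribute flag.
    """
    if not records:
        raise ValueError("no records to summarize")
    frame = pd.DataFrame([r.__dict__ for r in records]).set_index("image_id")
    if frame[list(METRIC_NAMES)].isna().any().any():
        raise ValueError("records contain undefined (nan) metrics")
    if len(records) == 1:
        if strict:
            raise ValueError("sample SD undefined for a single record")
        out = pd.DataFrame({"mean": frame.iloc[0][list(METRIC_NAMES)], "sd": 0.0})
        out.attrs["degenerate_n"] = True
        return out
    out = pd.DataFrame(
        {"mean": frame[list(METRIC_NAMES)].mean(), "sd": frame[list(METRIC_NAMES)].std(ddof=1)}
    )
    out.attrs["degenerate_n"] = False
    return out
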