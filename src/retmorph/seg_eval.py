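"""Pixelwise segmentation evaluation: confusion counts and derived ratios."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .mask import BinaryMask

__all__ = ["ConfusionCounts", "confusion", "seg_metrics"]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")


def confusion(pred: BinaryMask, truth: BinaryMask) -> ConfusionCounts:
    """Per-pixel confusion counts; foreground is the positive class."""
    if pred.shape != truth.shape:
        raise ValueError(
            f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    p, t = pred.grid, truth.grid
    return ConfusionCounts(
        tp=int((p & t).sum()),
        fp=int((p & ~t).sum()),
        tn=int((~p & ~t).sum()),
        fn=int((~p & t).sum()),
    )


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (0/0 denominator); returning NaN")
        return float("nan")
    return num / den


def seg_metrics(c: ConfusionCounts) -> dict[str, float]:
    """Accuracy, sensitivity, specificity and IoU from confusion counts.

    Accuracy = (TP+TN)/(TP+TN+FP+FN), sensitivity = TP/(TP+FN),
    specificity = TN/(TN+FP), IoU = TP/(TP+FP+FN). A zero denominator
    yields NaN with a warning.
    """
    if c.total == 0:
        raise ValueError("all confusion counts are zero")
    return {
        "accuracy": _ratio(c.tp + c.tn, c.total, "accuracy"),
        "sensitivity": _ratio(c.tp, c.tp + c.fn, "sensitivity"),
        "specificity": _ratio(c.tn, c.tn + c.fp, "specificity"),
        "iou": _ratio(c.tp, c.tp + c.fp + c.fn, "iou"),
    }
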