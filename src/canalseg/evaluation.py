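"""Confusion counting and segmentation metrics, in two formulations.

The study's typeset metric definitions differ from the community-standard
ones: its per-class "pixel accuracy" is a precision (TP/(TP+FP)), and its
canal IoU denominator includes the true negatives (TP/(FN+TP+TN)) rather
than the false positives.  Both formulations are first-class here — the
``printed`` variant reproduces the study's arithmetic, the ``standard``
variant (recall-style pixel accuracy, IoU = TP/(TP+FP+FN)) is for external
comparability — and every report is stamped with its variant.  Metrics with
a zero denominator are reported as NaN, never silently 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd

from .errors import CanalSegError
from .volume_io import BinaryMask

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_counts",
    "compute_metrics",
    "evaluate_run",
    "class_accuracy",
    "relative_improvement",
]

Variant = Literal["printed", "standard"]


@dataclass(frozen=True)
class ConfusionCounts:
    """Voxel confusion counts with canal as the positive class."""

    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN, self.TN) < 0:
            raise CanalSegError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


@dataclass(frozen=True)
class MetricsReport:
    pixel_acc_canal: float
    pixel_acc_background: float
    global_acc: float
    class_acc: float
    iou_canal: float
    iou_background: float
    mean_iou: float
    variant: Variant
    counts: ConfusionCounts

    def to_row(self) -> dict:
        return {
            "variant": self.variant,
            "pixel_acc_canal": self.pixel_acc_canal,
            "pixel_acc_background": self.pixel_acc_background,
            "global_acc": self.global_acc,
            "class_acc": self.class_acc,
            "iou_canal": self.iou_canal,
            "iou_background": self.iou_background,
            "mean_iou": self.mean_iou,
            "TP": self.counts.TP,
            "FP": self.counts.FP,
            "FN": self.counts.FN,
            "TN": self.counts.TN,
        }


def _as_bool(a) -> np.ndarray:
    return a.data if isinstance(a, BinaryMask) else np.asarray(a, dtype=bool)


def confusion_counts(pred, truth) -> ConfusionCounts:
    """Count TP/FP/FN/TN over all voxels (canal = positive)."""
    p, t = _as_bool(pred), _as_bool(truth)
    if p.shape != t.shape:
        raise CanalSegError(f"shape mismatch: pred {p.shape} vs truth {t.shape}")
    tp = int(np.sum(p & t))
    fp = int(np.sum(p & ~t))
    fn = int(np.sum(~p & t))
    tn = int(np.sum(~p & ~t))
    return ConfusionCounts(tp, fp, fn, tn)


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else math.nan


def class_accuracy(pixel_acc_canal: float, pixel_acc_background: float) -> float:
    """Class accuracy = the average of the two per-class pixel accuracies."""
    return (pixel_acc_canal + pixel_acc_background) / 2.0


def relative_improvement(new: float, reference: float) -> float:
    """Fractional improvement of ``new`` over ``reference``."""
    if reference == 0:
        raise CanalSegError("reference value must be nonzero")
    return (new - reference) / reference


def compute_metrics(c: ConfusionCounts, variant: Variant = "printed") -> MetricsReport:
    """The five metrics from raw counts, in the requested formulation."""
    if variant == "printed":
        pa_canal = _ratio(c.TP, c.TP + c.FP)
        pa_bg = _ratio(c.TN, c.TN + c.FN)
        iou_canal = _ratio(c.TP, c.FN + c.TP + c.TN)
        iou_bg = _ratio(c.TN, c.FP + c.TN + c.TP)
    elif variant == "standard":
        pa_canal = _ratio(c.TP, c.TP + c.FN)
        pa_bg = _ratio(c.TN, c.TN + c.FP)
        iou_canal = _ratio(c.TP, c.TP + c.FP + c.FN)
        iou_bg = _ratio(c.TN, c.TN + c.FN + c.FP)
    else:
        raise CanalSegError(f"unknown metrics variant {variant!r}")
    return MetricsReport(
        pixel_acc_canal=pa_canal,
        pixel_acc_background=pa_bg,
        global_acc=_ratio(c.TP + c.TN, c.total),
        class_acc=class_accuracy(pa_canal, pa_bg),
        iou_canal=iou_canal,
        iou_background=iou_bg,
        mean_iou=(iou_canal + iou_bg) / 2.0,
        variant=variant,
        counts=c,
    )


def evaluate_run(
    pred,
    truth,
    variant: Variant | Literal["both"] = "both",
) -> pd.DataFrame:
    """Confusion counting plus metrics for aligned volumes.

    Returns one row per requested variant; degenerate classes (e.g. an
    empty truth canal) yield NaN metrics without failing the run.
    """
    c = confusion_counts(pred, truth)
    variants = ("printed", "standard") if variant == "both" else (variant,)
    return pd.DataFrame([compute_metrics(c, v).to_row() for v in variants])
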