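"""Fundus tessellated density and segmentation performance metrics.

FTD is the area ratio rho = S1 / S, where S1 is the exposed-choroid pixel
count and S the ROI pixel count. Segmentation quality is summarized by
pixel-wise accuracy, sensitivity and specificity inside the ROI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyROI, MaskShapeMismatch, UndefinedMetric
from .image import BinaryMask


@dataclass(frozen=True)
class FTDResult:
    """Density rho = s1_px / s_px with its constituent pixel counts."""

    rho: float
    s1_px: int
    s_px: int


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel-wise confusion counts restricted to the ROI."""

    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _check_shapes(*masks: BinaryMask) -> None:
    shapes = {m.shape for m in masks}
    if len(shapes) > 1:
        raise MaskShapeMismatch(f"mask shapes differ: {sorted(shapes)}")


def compute_ftd(choroid: BinaryMask, roi: BinaryMask) -> FTDResult:
    """Density of exposed choroid per unit ROI area.

    The choroid mask is intersected with the ROI before counting, so
    predictions leaking outside the imaged field never inflate rho.
    """
    _check_shapes(choroid, roi)
    s = int(roi.pixels.sum())
    if s == 0:
        raise EmptyROI("ROI mask has no pixels")
    s1 = int((choroid.pixels & roi.pixels).sum())
    return FTDResult(rho=s1 / s, s1_px=s1, s_px=s)


def confusion(pred: BinaryMask, truth: BinaryMask, roi: BinaryMask) -> ConfusionCounts:
    """Pixel-wise confusion counts of ``pred`` against ``truth`` inside ``roi``."""
    _check_shapes(pred, truth, roi)
    sel = roi.pixels
    p = pred.pixels[sel]
    t = truth.pixels[sel]
    return ConfusionCounts(
        tp=int((p & t).sum()),
        tn=int((~p & ~t).sum()),
        fp=int((p & ~t).sum()),
        fn=int((~p & t).sum()),
    )


def metrics(c: ConfusionCounts) -> tuple[float, float, float]:
    """(accuracy, sensitivity, specificity) from confusion counts.

    Raises
    ------
    UndefinedMetric
        Naming the metric whose denominator is zero.
    """
    if c.total == 0:
        raise UndefinedMetric("accuracy undefined: no pixels in evaluation")
    if c.tp + c.fn == 0:
        raise UndefinedMetric("sensitivity undefined: no positive truth pixels")
    if c.tn + c.fp == 0:
        raise UndefinedMetric("specificity undefined: no negative truth pixels")
    accuracy = (c.tp + c.tn) / c.total
    sensitivity = c.tp / (c.tp + c.fn)
    specificity = c.tn / (c.tn + c.fp)
    return accuracy, sensitivity, specificity
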