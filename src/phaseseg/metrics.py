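"""Segmentation evaluation: dice coefficient, intersection-over-union, and
the relative error of the measured cell-growth area, plus corpus-level
aggregation.

All values are proportions internally; percent formatting (two decimals)
happens only at the reporting layer.  For two masks ``X`` and ``Y``::

    dice = 2|X ∩ Y| / (|X| + |Y|)        iou = |X ∩ Y| / |X ∪ Y|

counting 255-pixels, with the empty-vs-empty convention dice = iou = 1
(perfect agreement on absence).  The algebraic identity
``iou = dice / (2 - dice)`` holds per image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import MetricUndefinedError, ParameterError
from .imaging import BinaryMask, as_binary_mask


def _counts(x: BinaryMask, y: BinaryMask) -> tuple[int, int, int]:
    x = as_binary_mask(x)
    y = as_binary_mask(y)
    if x.shape != y.shape:
        raise ParameterError(f"mask shapes differ: {x.shape} vs {y.shape}")
    xo = x == 255
    yo = y == 255
    return int((xo & yo).sum()), int(xo.sum()), int(yo.sum())


def dice(x: BinaryMask, y: BinaryMask) -> float:
    inter, nx, ny = _counts(x, y)
    if nx + ny == 0:
        return 1.0
    return 2.0 * inter / (nx + ny)


def iou(x: BinaryMask, y: BinaryMask) -> float:
    inter, nx, ny = _counts(x, y)
    union = nx + ny - inter
    if union == 0:
        return 1.0
    return inter / union


def relative_area_error(measured: float, actual: float) -> float:
    """|measured - actual| / actual; undefined when the true area is zero."""
    if actual <= 0:
        raise MetricUndefinedError("relative area error is undefined for zero actual area")
    return abs(measured - actual) / actual


def area_fraction(mask: BinaryMask) -> float:
    mask = as_binary_mask(mask)
    return float((mask == 255).sum()) / mask.size


@dataclass
class MetricsReport:
    """Per-image metrics with corpus mean and std for each quantity."""

    per_image: pd.DataFrame  # columns: name, dice, iou, rel_area_err
    n_images: int
    mean_dice: float
    std_dice: float
    mean_iou: float
    std_iou: float
    mean_rel_area_err: float
    std_rel_area_err: float
    std_mode: str = "population"

    def summary(self) -> str:
        return (
            f"dice {100 * self.mean_dice:.2f}% (std: {100 * self.std_dice:.2f}%), "
            f"IoU {100 * self.mean_iou:.2f}% (std: {100 * self.std_iou:.2f}%), "
            f"relative area error {100 * self.mean_rel_area_err:.2f}% "
            f"(std: {100 * self.std_rel_area_err:.2f}%) over {self.n_images} images"
        )

    def to_dict(self) -> dict:
        return {
            "n_images": self.n_images,
            "std_mode": self.std_mode,
            "mean_dice": self.mean_dice,
            "std_dice": self.std_dice,
            "mean_iou": self.mean_iou,
            "std_iou": self.std_iou,
            "mean_rel_area_err": self.mean_rel_area_err,
            "std_rel_area_err": self.std_rel_area_err,
            "per_image": self.per_image.to_dict(orient="records"),
        }


def evaluate_corpus(
    pairs: list[tuple[BinaryMask, BinaryMask]],
    names: list[str] | None = None,
    std_mode: str = "population",
) -> MetricsReport:
    """Score a corpus of (predicted, truth) mask pairs.

    The relative area error compares the two masks' area fractions.  The
    std is population (divide by n) by default, matching how a fixed corpus
    is summarized; ``std_mode="sample"`` divides by n-1.
    """
    if not pairs:
        raise ParameterError("evaluate_corpus needs at least one (predicted, truth) pair")
    if std_mode not in ("population", "sample"):
        raise ParameterError(f"std_mode must be 'population' or 'sample', got {std_mode!r}")
    if names is None:
        names = [f"image_{i:04d}" for i in range(len(pairs))]
    if len(names) != len(pairs):
        raise ParameterError("names and pairs must have equal length")

    rows = []
    for name, (pred, truth) in zip(names, pairs):
        rows.append(
            {
                "name": name,
                "dice": dice(pred, truth),
                "iou": iou(pred, truth),
                "rel_area_err": relative_area_error(area_fraction(pred), area_fraction(truth)),
            }
        )
    table = pd.DataFrame(rows)
    ddof = 0 if std_mode == "population" else 1
    n = len(table)

    def _std(col: str) -> float:
        if n <= ddof:
            return 0.0
        return float(table[col].std(ddof=ddof))

    return MetricsReport(
        per_image=table,
        n_images=n,
        mean_dice=float(table["dice"].mean()),
        std_dice=_std("dice"),
        mean_iou=float(table["iou"].mean()),
        std_iou=_std("iou"),
        mean_rel_area_err=float(table["rel_area_err"].mean()),
        std_rel_area_err=_std("rel_area_err"),
        std_mode=std_mode,
    )
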