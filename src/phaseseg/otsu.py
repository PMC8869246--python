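"""Otsu automatic binarization.

The threshold is the candidate ``t`` in 0..255 minimizing the weighted
within-class variance

    W_bg(t) * var_bg(t) + W_fg(t) * var_fg(t)

where background = pixels <= t, foreground = pixels > t, and each class
weight is its pixel count divided by the total pixel count.  Empty classes
contribute zero.  By the classical duality this argmin coincides with the
argmax of the between-class variance.

Conventions fixed here: ties resolve to the smallest t (deterministic,
retains faint edges); a constant image returns its own value, yielding an
empty foreground when the threshold is applied.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np

from .imaging import BinaryMask, GrayImage, as_gray_image
from .exceptions import ParameterError


class OtsuResult(NamedTuple):
    """Threshold plus the full 256-candidate objective curve."""

    threshold: int
    objective_curve: np.ndarray  # shape (256,), weighted within-class variance per t


def otsu_threshold(img: GrayImage) -> OtsuResult:
    """Histogram-based exhaustive minimization of within-class variance."""
    img = as_gray_image(img)
    hist = np.bincount(img.ravel(), minlength=256).astype(np.float64)
    n = hist.sum()
    levels = np.arange(256, dtype=np.float64)

    p = hist / n
    w_b = np.cumsum(p)                       # weight of class <= t
    s1_b = np.cumsum(p * levels)             # first moment, background
    s2_b = np.cumsum(p * levels**2)          # second moment, background
    w_f = 1.0 - w_b
    s1_f = s1_b[-1] - s1_b
    s2_f = s2_b[-1] - s2_b

    with np.errstate(divide="ignore", invalid="ignore"):
        var_b = np.maximum(s2_b / w_b - (s1_b / w_b) ** 2, 0.0)
        var_f = np.maximum(s2_f / w_f - (s1_f / w_f) ** 2, 0.0)
    objective = np.where(w_b > 0, w_b * var_b, 0.0) + np.where(w_f > 0, w_f * var_f, 0.0)

    nonzero = np.flatnonzero(hist)
    if nonzero.size == 1:
        # Degenerate constant image: threshold at its own value -> empty foreground.
        return OtsuResult(int(nonzero[0]), objective)
    return OtsuResult(int(np.argmin(objective)), objective)


def apply_threshold(img: GrayImage, t: int) -> BinaryMask:
    """Binarize: pixels strictly above ``t`` become 255, the rest 0."""
    img = as_gray_image(img)
    if not 0 <= int(t) <= 255:
        raise ParameterError(f"threshold must be in [0, 255], got {t}")
    return np.where(img > t, 255, 0).astype(np.uint8)
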