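"""Morphological edge synthesis.

Instead of a convolution-based edge detector (Sobel/Canny), edges are built
from grayscale morphology: the *external* edge is dilation minus the image,
the *internal* edge is the image minus erosion, and the *middle* edge is the
morphological gradient (dilation minus erosion).  The three are summed with
saturation into the combined edge image the rest of the pipeline binarizes.

Because dilation >= image >= erosion pointwise (extensivity), the three
differences are true non-negative differences; the only saturation point is
the combined sum, clamped at 255.  Below saturation the algebraic identity
``combined = 2 * middle`` holds exactly, since external + internal = middle.
"""

from __future__ import annotations

import numpy as np

from .imaging import (
    GrayImage,
    StructuringElement,
    as_gray_image,
    check_se,
    full_se,
    gray_dilate,
    gray_erode,
)

EdgeImage = GrayImage


def _se(se: StructuringElement | None) -> StructuringElement:
    return full_se() if se is None else check_se(se)


def external_edge(f: GrayImage, se: StructuringElement | None = None) -> EdgeImage:
    """Dilation minus the image: a line on the dark side of each step."""
    f = as_gray_image(f)
    se = _se(se)
    return (gray_dilate(f, se).astype(np.int16) - f).astype(np.uint8)


def internal_edge(f: GrayImage, se: StructuringElement | None = None) -> EdgeImage:
    """Image minus erosion: a line on the bright side of each step."""
    f = as_gray_image(f)
    se = _se(se)
    return (f.astype(np.int16) - gray_erode(f, se)).astype(np.uint8)


def middle_edge(f: GrayImage, se: StructuringElement | None = None) -> EdgeImage:
    """Morphological gradient: dilation minus erosion."""
    f = as_gray_image(f)
    se = _se(se)
    return (gray_dilate(f, se).astype(np.int16) - gray_erode(f, se)).astype(np.uint8)


def combined_edge(f: GrayImage, se: StructuringElement | None = None) -> EdgeImage:
    """Saturating sum of the external, middle and internal edges."""
    f = as_gray_image(f)
    se = _se(se)
    d = gray_dilate(f, se).astype(np.int32)
    e = gray_erode(f, se).astype(np.int32)
    g = f.astype(np.int32)
    total = (d - g) + (d - e) + (g - e)
    return np.clip(total, 0, 255).astype(np.uint8)
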