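"""Mask construction and the end-to-end segmentation pipeline.

From the binarized edge image two mask branches are built:

* branch A (*small cells*): every external contour — the outer boundary of
  an 8-connected component — is filled solid, and filled components below
  the debris-area floor are discarded;
* branch B (*clusters*): the edge image is closed then opened with a 9x9
  rectangular SE, the resulting blobs are filled, and each interior hole
  ("tiny gap") is classified by intensity — kept open when its mean gray
  value is closer to the background mean than to the foreground mean,
  filled otherwise.

The union of the two branches is the final mask, which splits the working
grayscale image into an exact foreground/background partition.  The whole
pipeline is deterministic: identical inputs give bit-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .config import PipelineConfig
from .edges import combined_edge
from .exceptions import ParameterError
from .imaging import (
    BinaryMask,
    GrayImage,
    as_binary_mask,
    as_gray_image,
    binary_open,
    binary_close,
    full_se,
    gaussian_blur,
    resize,
    sharpen,
)
from .otsu import apply_threshold, otsu_threshold

log = logging.getLogger(__name__)

# 8-connectivity for foreground components, 4-connectivity for holes:
# the standard dual pair that avoids topological paradoxes.
_CONN8 = np.ones((3, 3), dtype=bool)
_CONN4 = ndimage.generate_binary_structure(2, 1)


@dataclass
class Region:
    """A connected pixel region with its bookkeeping attributes."""

    area: int
    mean_intensity: float
    kind: str = "gap"  # one of {cell_candidate, cluster, gap, background}
    label: int | None = None


@dataclass
class SegmentationResult:
    """Final mask plus the exact foreground/background image partition."""

    final_mask: BinaryMask
    foreground: GrayImage
    background: GrayImage
    area_fraction: float
    otsu_threshold: int
    blob_count: int
    image: GrayImage  # the working (resized) grayscale input
    intermediate: dict[str, np.ndarray] | None = field(default=None, repr=False)


def _fill_external_contours(mask: np.ndarray) -> np.ndarray:
    """Fill every 4-connected hole enclosed by 8-connected components."""
    return ndimage.binary_fill_holes(mask, structure=_CONN4)


def small_cell_mask(edge_binary: BinaryMask, debris_floor: int = 20) -> BinaryMask:
    """Branch A: fill external contours, drop sub-floor components."""
    b = as_binary_mask(edge_binary).astype(bool)
    filled = _fill_external_contours(b)
    if debris_floor > 0 and filled.any():
        labels, n = ndimage.label(filled, structure=_CONN8)
        if n:
            areas = np.bincount(labels.ravel())
            keep = areas >= debris_floor
            keep[0] = False
            filled = keep[labels]
    return np.where(filled, 255, 0).astype(np.uint8)


def classify_gap(gap: Region, background_mean: float, foreground_mean: float) -> str:
    """Decide whether an interior hole is background or enclosed cell matter.

    Returns ``"keep_open"`` when the gap's mean intensity is strictly closer
    to the background mean than to the foreground mean, else ``"fill"``
    (ties fill: conservative toward cells).
    """
    if abs(gap.mean_intensity - background_mean) < abs(gap.mean_intensity - foreground_mean):
        return "keep_open"
    return "fill"


def cluster_mask(
    edge_binary: BinaryMask,
    gray: GrayImage,
    cluster_se_size: int = 9,
    gap_area_ceiling: float = 0.01,
) -> BinaryMask:
    """Branch B: 9x9 close/open cluster detection with conditional gap filling.

    ``gray`` is the working (resized, pre-edge) grayscale image the gap and
    background intensity statistics are read from.
    """
    edge_binary = as_binary_mask(edge_binary)
    gray = as_gray_image(gray)
    if edge_binary.shape != gray.shape:
        raise ParameterError(
            f"edge mask shape {edge_binary.shape} does not match image shape {gray.shape}"
        )
    se = full_se(cluster_se_size, cluster_se_size)
    m = binary_open(binary_close(edge_binary, se), se).astype(bool)
    if not m.any():
        return np.zeros_like(edge_binary)

    solid = _fill_external_contours(m)
    holes = solid & ~m

    background = ~solid
    background_mean = float(gray[background].mean()) if background.any() else float(gray.mean())
    foreground_mean = float(gray[m].mean())

    out = m.copy()
    if holes.any():
        labels, n = ndimage.label(holes, structure=_CONN4)
        ceiling = gap_area_ceiling * gray.size
        areas = np.bincount(labels.ravel())
        means = ndimage.mean(gray, labels=labels, index=np.arange(1, n + 1))
        fill_ids = []
        for i in range(1, n + 1):
            gap = Region(area=int(areas[i]), mean_intensity=float(means[i - 1]), kind="gap", label=i)
            if gap.area <= ceiling and classify_gap(gap, background_mean, foreground_mean) == "fill":
                fill_ids.append(i)
        if fill_ids:
            out |= np.isin(labels, fill_ids)
    return np.where(out, 255, 0).astype(np.uint8)


def combine_masks(a: BinaryMask, b: BinaryMask) -> BinaryMask:
    """Pixelwise union of two binary masks."""
    a = as_binary_mask(a)
    b = as_binary_mask(b)
    if a.shape != b.shape:
        raise ParameterError(f"mask shapes differ: {a.shape} vs {b.shape}")
    return np.maximum(a, b)


def segment(img: GrayImage, config: PipelineConfig | None = None) -> SegmentationResult:
    """Run the full automated segmentation pipeline on one grayscale image.

    Stages, in order: resize -> Gaussian pre-blur -> grayscale morphological
    edge synthesis (3x3 SE) -> blur + sharpen of the combined edge image ->
    Otsu binarization -> noise-removal opening -> branch A / branch B ->
    union -> foreground/background split and area fraction.
    """
    cfg = config if config is not None else PipelineConfig()
    gray = as_gray_image(img)

    if cfg.resize_target is not None and cfg.resize_stage == "input":
        gray = resize(gray, *cfg.resize_target)

    work = gaussian_blur(gray, cfg.pre_blur_kernel, cfg.gaussian_sigma)
    edge = combined_edge(work, full_se(cfg.edge_se_size, cfg.edge_se_size))

    if cfg.blur_before_sharpen:
        edge = gaussian_blur(edge, cfg.pre_blur_kernel, cfg.gaussian_sigma)
        if cfg.sharpen:
            edge = sharpen(edge)
    else:
        if cfg.sharpen:
            edge = sharpen(edge)
        edge = gaussian_blur(edge, cfg.pre_blur_kernel, cfg.gaussian_sigma)

    if cfg.resize_target is not None and cfg.resize_stage == "after_sharpen":
        edge = resize(edge, *cfg.resize_target)
        gray = resize(gray, *cfg.resize_target)

    ot = otsu_threshold(edge)
    edge_bin = apply_threshold(edge, ot.threshold)
    noise_se = full_se(cfg.noise_open_se_size, cfg.noise_open_se_size)
    if cfg.noise_morphology == "close_open":
        denoised = binary_open(binary_close(edge_bin, noise_se), noise_se)
    elif cfg.noise_morphology == "open":
        denoised = binary_open(edge_bin, noise_se)
    else:
        denoised = edge_bin

    branch_a = small_cell_mask(denoised, cfg.debris_floor)
    branch_b = cluster_mask(edge_bin, gray, cfg.cluster_se_size, cfg.gap_area_ceiling)
    final = combine_masks(branch_a, branch_b)

    on = final == 255
    foreground = np.where(on, gray, 0).astype(np.uint8)
    background = np.where(on, 0, gray).astype(np.uint8)
    area_fraction = float(on.sum()) / final.size
    _, blob_count = ndimage.label(on, structure=_CONN8)

    log.info(
        "segment: otsu=%d area_fraction=%.4f blobs=%d (A=%d px, B=%d px)",
        ot.threshold, area_fraction, blob_count,
        int((branch_a == 255).sum()), int((branch_b == 255).sum()),
    )

    intermediate = None
    if cfg.debug_dump:
        intermediate = {
            "edge_sharpened": edge,
            "edge_binary": edge_bin,
            "edge_denoised": denoised,
            "branch_small_cells": branch_a,
            "branch_clusters": branch_b,
        }
    return SegmentationResult(
        final_mask=final,
        foreground=foreground,
        background=background,
        area_fraction=area_fraction,
        otsu_threshold=ot.threshold,
        blob_count=int(blob_count),
        image=gray,
        intermediate=intermediate,
    )
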