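"""Robustness perturbation protocols.

Three families of deterministic image degradations probe how the pipeline's
accuracy decays: blurring (Gaussian or mean/box kernels, odd sizes 3..49),
isotropic resizing (scalars 0.5..3 applied to both dimensions), and
illumination reduction (either rescaling the normalized image by
``(255 - s) / 255`` or directly subtracting ``s``, scalars 0..150 in steps
of 5).  ``run_sweep`` applies one family over a corpus, segments every
perturbed image, scores it against its ground truth, and tabulates the
metric-versus-level curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .exceptions import ParameterError, PhasesegError
from .imaging import BinaryMask, GrayImage, as_gray_image, gaussian_blur, resize, resize_mask
from .metrics import area_fraction, dice, iou, relative_area_error
from .segmentation import segment

AXES = ("blur_gaussian", "blur_mean", "resize", "illum_normalize", "illum_subtract")

#: Default level grids per axis (blur kernels step by 2: even kernels lack a
#: center anchor; illumination scalars step by 5; resize steps by 0.25).
DEFAULT_LEVELS: dict[str, list] = {
    "blur_gaussian": list(range(3, 50, 2)),
    "blur_mean": list(range(3, 50, 2)),
    "resize": [round(0.5 + 0.25 * i, 2) for i in range(11)],
    "illum_normalize": list(range(0, 151, 5)),
    "illum_subtract": list(range(0, 151, 5)),
}


def _check_blur_k(k: int) -> int:
    k = int(k)
    if k % 2 == 0 or not 3 <= k <= 49:
        raise ParameterError(f"blur kernel size must be odd and in [3, 49], got {k}")
    return k


def _check_illum_s(s: int) -> int:
    s = int(s)
    if not 0 <= s <= 150 or s % 5 != 0:
        raise ParameterError(f"illumination scalar must be a multiple of 5 in [0, 150], got {s}")
    return s


def blur_perturb(img: GrayImage, method: str, k: int) -> GrayImage:
    """Blur with a Gaussian or uniform (mean/box) kernel of odd size ``k``."""
    img = as_gray_image(img)
    k = _check_blur_k(k)
    if method == "gaussian":
        return gaussian_blur(img, k)
    if method == "mean":
        from scipy import ndimage

        out = ndimage.uniform_filter(img.astype(np.float64), size=k, mode="nearest")
        return np.clip(np.rint(out), 0, 255).astype(np.uint8)
    raise ParameterError(f"blur method must be 'gaussian' or 'mean', got {method!r}")


def resize_perturb(img: GrayImage, scalar: float) -> GrayImage:
    """Scale both dimensions by ``scalar`` (aspect ratio preserved).

    ``scalar = 1`` is the exact identity.
    """
    img = as_gray_image(img)
    if not 0.5 <= scalar <= 3:
        raise ParameterError(f"resize scalar must be in [0.5, 3], got {scalar}")
    if scalar == 1:
        return img.copy()
    h, w = img.shape
    return resize(img, max(1, round(w * scalar)), max(1, round(h * scalar)))


def illum_normalize(img: GrayImage, s: int) -> GrayImage:
    """Rescale the 0-1 normalized image by ``255 - s``: out = round(img/255 * (255-s)).

    A monotone map; the maximum attainable value is ``255 - s``.
    """
    img = as_gray_image(img)
    s = _check_illum_s(s)
    return np.rint(img.astype(np.float64) * (255 - s) / 255.0).astype(np.uint8)


def illum_subtract(img: GrayImage, s: int) -> GrayImage:
    """Subtract ``s`` from every pixel, clamping at zero."""
    img = as_gray_image(img)
    s = _check_illum_s(s)
    return np.maximum(img.astype(np.int16) - s, 0).astype(np.uint8)


def apply_perturbation(img: GrayImage, axis: str, level) -> GrayImage:
    """Dispatch one perturbation by axis name."""
    if axis == "blur_gaussian":
        return blur_perturb(img, "gaussian", level)
    if axis == "blur_mean":
        return blur_perturb(img, "mean", level)
    if axis == "resize":
        return resize_perturb(img, float(level))
    if axis == "illum_normalize":
        return illum_normalize(img, level)
    if axis == "illum_subtract":
        return illum_subtract(img, level)
    raise ParameterError(f"unknown perturbation axis {axis!r}; valid axes: {AXES}")


@dataclass
class SweepSpec:
    """One perturbation axis plus the ordered list of levels to sweep."""

    axis: str
    levels: list | None = None

    def __post_init__(self) -> None:
        if self.axis not in AXES:
            raise ParameterError(f"unknown sweep axis {self.axis!r}; valid axes: {AXES}")
        if self.levels is None:
            self.levels = list(DEFAULT_LEVELS[self.axis])
        if not self.levels:
            raise ParameterError("sweep needs at least one level")


@dataclass
class SweepReport:
    """Per-(level, image) metric table plus per-level means."""

    axis: str
    table: pd.DataFrame   # columns: level, image, dice, iou, rel_area_err, rel_err_over_100
    summary: pd.DataFrame  # per-level mean dice/iou/rel_area_err
    failures: list[tuple[object, str, str]] = field(default_factory=list)

    def plot(self, path: str) -> None:
        """Write metric-vs-level curves as a figure (matplotlib optional)."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
        for ax, col, label in zip(
            axes, ("dice", "iou", "rel_area_err"), ("Dice", "IoU", "Relative area error")
        ):
            ax.plot(self.summary.index, self.summary[col], marker="o", ms=3)
            ax.set_xlabel(self.axis)
            ax.set_ylabel(label)
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def run_sweep(
    corpus: list[tuple[GrayImage, BinaryMask]],
    spec: SweepSpec,
    config: PipelineConfig | None = None,
    names: list[str] | None = None,
) -> SweepReport:
    """Perturb, segment and score every corpus image at every level.

    For the resize axis the truth mask is co-resized (nearest-neighbor) so
    scoring happens at the perturbed resolution.  If the pipeline's working
    frame differs from the truth grid, the predicted mask is brought onto
    the truth grid the same way.  A per-image failure is recorded in
    ``failures`` and skipped, not raised.
    """
    if not corpus:
        raise ParameterError("run_sweep needs a nonempty corpus")
    if names is None:
        names = [f"image_{i:04d}" for i in range(len(corpus))]

    rows = []
    failures: list[tuple[object, str, str]] = []
    for level in spec.levels:
        for name, (img, truth) in zip(names, corpus):
            try:
                pert = apply_perturbation(img, spec.axis, level)
                t = truth
                if spec.axis == "resize":
                    ph, pw = pert.shape
                    t = resize_mask(truth, pw, ph)
                res = segment(pert, config)
                pred = res.final_mask
                if pred.shape != t.shape:
                    th, tw = t.shape
                    pred = resize_mask(pred, tw, th)
                d = dice(pred, t)
                j = iou(pred, t)
                rel = relative_area_error(area_fraction(pred), area_fraction(t))
            except PhasesegError as exc:
                failures.append((level, name, str(exc)))
                continue
            rows.append(
                {
                    "level": level,
                    "image": name,
                    "dice": d,
                    "iou": j,
                    "rel_area_err": rel,
                    "rel_err_over_100": rel > 1.0,
                }
            )
    table = pd.DataFrame(rows)
    if table.empty:
        raise ParameterError("every (level, image) evaluation failed")
    summary = table.groupby("level")[["dice", "iou", "rel_area_err"]].mean()
    return SweepReport(axis=spec.axis, table=table, summary=summary, failures=failures)
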