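"""Raster I/O, grayscale conversion, resizing, filtering, and the grayscale /
binary morphological operators every later stage composes.

Conventions
-----------
Images are 2-D ``uint8`` numpy arrays, row-major, origin at the top-left,
pixel coordinates 0-based.  A *gray image* holds intensities in [0, 255]; a
*binary mask* holds exactly {0, 255}.  A *structuring element* (SE) is a
small boolean array with odd side lengths whose anchor is its geometric
center.  All window operators handle the border by edge replication, so no
artificial dark or bright frame can seed spurious edges.
"""

from __future__ import annotations

import os

import numpy as np
from numpy.typing import NDArray
from scipy import ndimage

from .exceptions import FormatError, InputFileError, ParameterError

GrayImage = NDArray[np.uint8]
BinaryMask = NDArray[np.uint8]
StructuringElement = NDArray[np.bool_]

#: ITU-R BT.601 luminance weights for RGB -> gray conversion.
BT601_WEIGHTS = (0.299, 0.587, 0.114)

#: Standard 3x3 Laplacian-sharpening kernel (unit sum: flat regions are
#: fixed points; applied with saturating arithmetic).
SHARPEN_KERNEL = np.array([[0, -1, 0], [-1, 5, -1], [0, -1, 0]], dtype=np.int32)


# ---------------------------------------------------------------------------
# validation helpers


def as_gray_image(arr) -> GrayImage:
    """Validate and coerce ``arr`` into a gray image (2-D uint8)."""
    a = np.asarray(arr)
    if a.ndim != 2 or a.size == 0:
        raise ParameterError(f"expected a non-empty 2-D image, got shape {a.shape}")
    if a.dtype != np.uint8:
        if np.issubdtype(a.dtype, np.integer) and a.min() >= 0 and a.max() <= 255:
            a = a.astype(np.uint8)
        else:
            raise ParameterError(f"expected uint8 intensities in [0, 255], got dtype {a.dtype}")
    return a


def as_binary_mask(arr) -> BinaryMask:
    """Validate ``arr`` as a binary mask over exactly {0, 255}."""
    a = as_gray_image(arr)
    if not np.isin(a, (0, 255)).all():
        raise ParameterError("binary mask must contain only the values 0 and 255")
    return a


def check_se(se) -> StructuringElement:
    """Validate a structuring element: odd side lengths, at least one active element."""
    s = np.asarray(se).astype(bool)
    if s.ndim != 2:
        raise ParameterError(f"structuring element must be 2-D, got shape {s.shape}")
    if s.shape[0] % 2 == 0 or s.shape[1] % 2 == 0:
        raise ParameterError(f"structuring element side lengths must be odd, got {s.shape}")
    if not s.any():
        raise ParameterError("structuring element has no active elements")
    return s


def full_se(height: int = 3, width: int | None = None) -> StructuringElement:
    """Full rectangular structuring element (all elements active)."""
    if width is None:
        width = height
    return check_se(np.ones((height, width), dtype=bool))


# ---------------------------------------------------------------------------
# I/O


def read_image(path: str | os.PathLike) -> GrayImage:
    """Read a PNG/TIFF image as an 8-bit gray image.

    3-channel (or RGBA) inputs are converted to BT.601 luminance; 16-bit
    inputs are rescaled full-scale to [0, 255].
    """
    import imageio.v3 as iio

    try:
        arr = iio.imread(os.fspath(path))
    except FileNotFoundError as exc:
        raise InputFileError(f"input image not found: {path}") from exc
    except Exception as exc:  # decoder errors vary by plugin
        raise InputFileError(f"cannot decode image file: {path} ({exc})") from exc

    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[..., :3]
        if arr.shape[2] != 3:
            raise FormatError(f"unsupported channel count {arr.shape[2]} in {path}")
        flat = arr.astype(np.float64) @ np.asarray(BT601_WEIGHTS)
    elif arr.ndim == 2:
        flat = arr.astype(np.float64)
    else:
        raise FormatError(f"unsupported image layout with shape {arr.shape} in {path}")

    if arr.dtype == np.uint8:
        scale = 1.0
    elif arr.dtype == np.uint16:
        scale = 255.0 / 65535.0
    elif arr.dtype == np.bool_:
        scale = 255.0
    else:
        raise FormatError(f"unsupported bit depth {arr.dtype} in {path}")

    return np.clip(np.rint(flat * scale), 0, 255).astype(np.uint8)


def write_image(path: str | os.PathLike, img: GrayImage) -> None:
    """Write a gray image (or mask) as an 8-bit single-channel file."""
    import imageio.v3 as iio

    iio.imwrite(os.fspath(path), as_gray_image(img))


# ---------------------------------------------------------------------------
# resize / smoothing / sharpening


def resize(img: GrayImage, target_width: int, target_height: int) -> GrayImage:
    """Resize to exactly ``target_width`` x ``target_height``.

    Shrinking uses area averaging (box filter); enlarging uses bilinear
    interpolation.  Resizing to the current size is the identity.
    """
    from PIL import Image

    img = as_gray_image(img)
    if target_width < 1 or target_height < 1:
        raise ParameterError(f"target dimensions must be >= 1, got {target_width}x{target_height}")
    h, w = img.shape
    if (w, h) == (target_width, target_height):
        return img.copy()
    shrink = target_width * target_height < w * h
    resample = Image.Resampling.BOX if shrink else Image.Resampling.BILINEAR
    out = Image.fromarray(img).resize((target_width, target_height), resample)
    return np.asarray(out, dtype=np.uint8)


def resize_mask(mask: BinaryMask, target_width: int, target_height: int) -> BinaryMask:
    """Resize a binary mask with nearest-neighbor interpolation.

    Nearest-neighbor preserves binarity; the result is defensively
    re-thresholded at 128 so the {0, 255} contract is exact.
    """
    from PIL import Image

    mask = as_binary_mask(mask)
    if target_width < 1 or target_height < 1:
        raise ParameterError(f"target dimensions must be >= 1, got {target_width}x{target_height}")
    h, w = mask.shape
    if (w, h) == (target_width, target_height):
        return mask.copy()
    out = Image.fromarray(mask).resize((target_width, target_height), Image.Resampling.NEAREST)
    return np.where(np.asarray(out) > 127, 255, 0).astype(np.uint8)


def gaussian_sigma_for_kernel(kernel_size: int) -> float:
    """Default Gaussian sigma for a given odd kernel size.

    The common size-to-sigma convention ``0.3*((k-1)/2 - 1) + 0.8``.
    """
    return 0.3 * ((kernel_size - 1) / 2 - 1) + 0.8


def gaussian_kernel_1d(kernel_size: int, sigma: float | None = None) -> NDArray[np.float64]:
    """Normalized 1-D discrete Gaussian kernel (weights sum to 1)."""
    if kernel_size < 1 or kernel_size % 2 == 0:
        raise ParameterError(f"Gaussian kernel size must be odd and >= 1, got {kernel_size}")
    if sigma is None:
        sigma = gaussian_sigma_for_kernel(kernel_size)
    if sigma <= 0:
        raise ParameterError(f"Gaussian sigma must be > 0, got {sigma}")
    x = np.arange(kernel_size, dtype=np.float64) - kernel_size // 2
    k = np.exp(-(x**2) / (2.0 * sigma**2))
    return k / k.sum()


def gaussian_blur(img: GrayImage, kernel_size: int = 3, sigma: float | None = None) -> GrayImage:
    """Convolve with the normalized discrete Gaussian kernel.

    The separable product of two 1-D kernels equals the full 2-D kernel;
    the result is rounded back to integers in [0, 255].  A constant image
    is a fixed point because the kernel is normalized.
    """
    img = as_gray_image(img)
    k = gaussian_kernel_1d(kernel_size, sigma)
    out = ndimage.correlate1d(img.astype(np.float64), k, axis=0, mode="nearest")
    out = ndimage.correlate1d(out, k, axis=1, mode="nearest")
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def sharpen(img: GrayImage) -> GrayImage:
    """Apply the fixed 3x3 Laplacian-sharpening kernel with saturation.

    Constant regions are unchanged (unit-sum kernel); results clamp to
    [0, 255].
    """
    img = as_gray_image(img)
    out = ndimage.correlate(img.astype(np.int32), SHARPEN_KERNEL, mode="nearest")
    return np.clip(out, 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# morphology

# The window at pixel x is { x + (i - anchor) : SE[i] active }, values taken
# with replicate-border semantics; grayscale dilation assigns the window
# maximum, erosion the window minimum.  scipy's maximum/minimum_filter with
# footprint + mode='nearest' implements exactly this window scan.


def gray_dilate(img: GrayImage, se: StructuringElement | None = None) -> GrayImage:
    """Grayscale dilation: window maximum over the SE."""
    img = as_gray_image(img)
    se = full_se() if se is None else check_se(se)
    return ndimage.maximum_filter(img, footprint=se, mode="nearest")


def gray_erode(img: GrayImage, se: StructuringElement | None = None) -> GrayImage:
    """Grayscale erosion: window minimum over the SE."""
    img = as_gray_image(img)
    se = full_se() if se is None else check_se(se)
    return ndimage.minimum_filter(img, footprint=se, mode="nearest")


def binary_dilate(mask: BinaryMask, se: StructuringElement | None = None) -> BinaryMask:
    """Binary dilation: 255 iff any window pixel is 255."""
    mask = as_binary_mask(mask)
    se = full_se() if se is None else check_se(se)
    return ndimage.maximum_filter(mask, footprint=se, mode="nearest")


def binary_erode(mask: BinaryMask, se: StructuringElement | None = None) -> BinaryMask:
    """Binary erosion: 0 iff any window pixel is 0."""
    mask = as_binary_mask(mask)
    se = full_se() if se is None else check_se(se)
    return ndimage.minimum_filter(mask, footprint=se, mode="nearest")


def binary_close(mask: BinaryMask, se: StructuringElement | None = None) -> BinaryMask:
    """Binary closing: dilate then erode (fills sub-SE gaps; idempotent)."""
    se = full_se() if se is None else check_se(se)
    return binary_erode(binary_dilate(mask, se), se)


def binary_open(mask: BinaryMask, se: StructuringElement | None = None) -> BinaryMask:
    """Binary opening: erode then dilate (removes sub-SE specks; idempotent)."""
    se = full_se() if se is None else check_se(se)
    return binary_dilate(binary_erode(mask, se), se)


def complement(mask: BinaryMask) -> BinaryMask:
    """Pixelwise complement of a binary mask."""
    return (255 - as_binary_mask(mask)).astype(np.uint8)
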