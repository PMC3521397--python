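"""Micrograph pre-processing: contrast equalization, grayscale conversion,
binarization with complement, and 3x3 median filtering.

Images are numpy float64 arrays with intensities in [0, 1]: shape ``(H, W)``
for grayscale, ``(H, W, 3)`` for RGB.  Binary masks are boolean ``(H, W)``
arrays with ``True`` = object (white) and ``False`` = background, the
convention produced by complementing a thresholded bright-field micrograph
(dark organisms on a bright background).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

# ITU-R 601 luminance weights, the classic rgb2gray convention.
_LUMA = np.array([0.299, 0.587, 0.114])


def _validate_image(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.ndim not in (2, 3):
        raise ValueError(f"expected a 2-D gray or (H, W, 3) RGB array, got shape {img.shape}")
    if img.ndim == 3 and img.shape[2] != 3:
        raise ValueError(f"RGB image must have 3 planes, got {img.shape[2]}")
    if img.shape[0] < 1 or img.shape[1] < 1:
        raise ValueError("image must have height >= 1 and width >= 1")
    return img


def load_image(path: str | Path) -> np.ndarray:
    """Load a PNG/TIFF/JPEG micrograph as an RGB float image in [0, 1].

    Grayscale files are promoted to three identical planes; an alpha
    channel, if present, is dropped.
    """
    path = Path(path)
    try:
        raw = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # decoder errors vary by backend
        raise IOError(f"could not decode image file {path}: {exc}") from exc
    if raw.size == 0:
        raise ValueError(f"image file {path} has zero size")
    img = np.asarray(raw, dtype=float)
    if np.issubdtype(raw.dtype, np.integer):
        img /= 255.0
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    elif img.ndim == 3 and img.shape[2] == 4:
        img = img[:, :, :3]
    return np.clip(_validate_image(img), 0.0, 1.0)


def save_image(path: str | Path, img: np.ndarray) -> None:
    """Write an image or mask as 8-bit PNG/TIFF (masks become {0, 255})."""
    arr = np.asarray(img)
    if arr.dtype == bool:
        out = arr.astype(np.uint8) * 255
    else:
        out = np.clip(np.round(np.asarray(arr, dtype=float) * 255.0), 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), out)


def _equalize_channel(chan: np.ndarray) -> np.ndarray:
    # Classic 256-bin CDF remap: the minimum occupied bin maps to 0, the
    # maximum to 1, and the mapping is monotone in the input intensity.
    levels = np.clip(np.round(chan * 255.0), 0, 255).astype(np.intp)
    hist = np.bincount(levels.ravel(), minlength=256)
    cdf = np.cumsum(hist).astype(float)
    cdf_min = cdf[np.nonzero(hist)[0][0]]
    denom = cdf[-1] - cdf_min
    if denom <= 0:  # constant image: single occupied bin
        return chan.copy()
    lut = (cdf - cdf_min) / denom
    return lut[levels]


def equalize_contrast(img: np.ndarray) -> np.ndarray:
    """Histogram-equalize image contrast.

    For RGB input the equalization is applied to the intensity (luminance)
    channel only and each colour plane is rescaled by the intensity gain,
    which enhances contrast without distorting hue.
    """
    img = _validate_image(img)
    if img.ndim == 2:
        return _equalize_channel(img)
    intensity = img @ _LUMA
    eq = _equalize_channel(intensity)
    with np.errstate(divide="ignore", invalid="ignore"):
        gain = np.where(intensity > 1e-12, eq / np.maximum(intensity, 1e-12), 0.0)
    return np.clip(img * gain[:, :, None], 0.0, 1.0)


def to_gray(img: np.ndarray) -> np.ndarray:
    """Convert RGB to grayscale with ITU-R 601 weights (0.299, 0.587, 0.114)."""
    img = _validate_image(img)
    if img.ndim == 2:
        return img.copy()
    return img @ _LUMA


def binarize_complement(img: np.ndarray) -> np.ndarray:
    """Threshold a gray image (Otsu) and complement it.

    Dark organisms on a bright background become ``True`` (object) and the
    background ``False``.  A constant image has no threshold; an all-background
    mask is returned with a warning.  The same happens when the histogram is
    not meaningfully bimodal: Otsu always returns *some* threshold, and on an
    object-free noisy field it would split the background noise itself.  The
    threshold is accepted only if the two classes separate by at least four
    within-class standard deviations (a split of a single Gaussian mode
    separates its halves by ~1.6 sigma = 2.7 half-widths, well below four).
    """
    img = _validate_image(img)
    if img.ndim != 2:
        raise ValueError("binarize_complement expects a grayscale image")
    if np.ptp(img) == 0:
        warnings.warn("constant image: no threshold exists, returning all-background mask")
        return np.zeros(img.shape, dtype=bool)
    thresh = threshold_otsu(img, nbins=256)
    mask = img <= thresh  # complement: dark pixels are foreground
    lo, hi = img[mask], img[~mask]
    spread = max(lo.std(), hi.std(), 1e-6)
    if hi.mean() - lo.mean() < 4.0 * spread:
        warnings.warn("histogram is not bimodal (no dark objects on the bright "
                      "background); returning all-background mask")
        return np.zeros(img.shape, dtype=bool)
    return mask


def median_filter3(mask: np.ndarray) -> np.ndarray:
    """3x3 median filter on a binary mask (edge-replicated borders).

    Removes isolated salt noise while preserving solid regions up to 1-px
    boundary smoothing.
    """
    mask = np.asarray(mask)
    if mask.dtype != bool:
        if not np.isin(mask, (0, 1)).all():
            raise ValueError("mask values must be in {0, 1}")
        mask = mask.astype(bool)
    filtered = ndi.median_filter(mask.astype(np.uint8), size=3, mode="nearest")
    return filtered.astype(bool)
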