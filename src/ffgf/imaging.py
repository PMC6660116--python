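"""Grayscale image I/O, region-of-interest handling and enhancement.

Images are plain 2-D :class:`numpy.ndarray` grids of intensities, row-major
and 0-based, indexed ``(row, column)``.  Integer images live in ``[0, 255]``;
float images only need finite values.  Masks are same-shape boolean arrays,
``True`` marking pixels inside the region of interest.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from .exceptions import ContractError, FormatError, InputError

logger = logging.getLogger(__name__)

#: Minimum number of rows/columns a usable image must have.
MIN_SIDE = 8

_LUMA = np.array([0.2125, 0.7154, 0.0721])


def validate_image(img: np.ndarray) -> np.ndarray:
    """Check invariants of a grayscale image and return it as a 2-D array."""
    arr = np.asarray(img)
    if arr.ndim != 2:
        raise FormatError(f"expected a 2-D grayscale image, got ndim={arr.ndim}")
    if arr.shape[0] < MIN_SIDE or arr.shape[1] < MIN_SIDE:
        raise FormatError(
            f"image must be at least {MIN_SIDE}x{MIN_SIDE}, got {arr.shape}"
        )
    if not np.all(np.isfinite(arr.astype(float))):
        raise FormatError("image contains non-finite intensities")
    if np.issubdtype(arr.dtype, np.integer) and (arr.min() < 0 or arr.max() > 255):
        raise FormatError("integer image intensities must lie in [0, 255]")
    return arr


def validate_mask(mask: np.ndarray, img: np.ndarray | None = None) -> np.ndarray:
    """Check invariants of an ROI mask (optionally against its image)."""
    m = np.asarray(mask).astype(bool)
    if m.ndim != 2:
        raise FormatError(f"mask must be 2-D, got ndim={m.ndim}")
    if img is not None and m.shape != np.asarray(img).shape:
        raise ContractError(
            f"mask shape {m.shape} does not match image shape {np.asarray(img).shape}"
        )
    if not m.any():
        raise ContractError("mask has no pixels inside the region of interest")
    return m


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG or TIFF file as a 2-D grayscale image.

    Color inputs are collapsed to grayscale by the standard luma weighting
    (0.2125 R + 0.7154 G + 0.0721 B); an alpha channel, if present, is dropped.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"image file not found: {path}")
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[:, :, :3]
        if arr.shape[2] == 3:
            gray = arr.astype(float) @ _LUMA
            # keep integer type when all channels agreed exactly
            if np.issubdtype(arr.dtype, np.integer):
                gray = np.rint(gray).astype(arr.dtype)
            arr = gray
        else:
            raise FormatError(f"unsupported channel count {arr.shape[2]} in {path}")
    if arr.ndim != 2 or arr.size == 0:
        raise FormatError(f"{path} is not a 2-D image")
    arr = validate_image(arr)
    logger.debug("loaded %s: shape=%s dtype=%s", path, arr.shape, arr.dtype)
    return arr


def write_image(path: str | Path, img: np.ndarray) -> None:
    """Write an image as 8-bit PNG/TIFF (dtype preserved if already uint8)."""
    arr = np.asarray(img)
    if arr.dtype != np.uint8:
        arr = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), arr)


def load_mask(path: str | Path) -> np.ndarray:
    """Read a mask image; nonzero pixels are inside the ROI."""
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[..., :3].max(axis=2)
    return validate_mask(arr != 0)


def apply_roi(img: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Crop an image to the bounding box of a mask.

    Pixels inside the box but outside the mask are replaced with the mean
    intensity of the masked pixels, so the crop boundary does not inject an
    artificial hard edge into the downstream spectrum.
    """
    arr = validate_image(img)
    m = validate_mask(mask, arr)
    rows, cols = np.nonzero(m)
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    crop = arr[r0:r1, c0:c1].astype(float, copy=True)
    sub = m[r0:r1, c0:c1]
    fill = arr[m].mean()
    crop[~sub] = fill
    if np.issubdtype(arr.dtype, np.integer):
        crop = np.clip(np.rint(crop), 0, 255).astype(arr.dtype)
    return crop


@dataclass(frozen=True)
class EnhanceConfig:
    """Settings for the enhancement pipeline.

    median: apply a 3x3 median filter (speckle suppression).
    stretch: linearly map the [p_low, p_high] intensity percentiles to [0, 255].
    """

    median: bool = True
    stretch: bool = True
    p_low: float = 1.0
    p_high: float = 99.0


def enhance(img: np.ndarray, cfg: EnhanceConfig | None = None) -> np.ndarray:
    """Median-filter then contrast-stretch an image; shape is preserved."""
    cfg = cfg or EnhanceConfig()
    arr = validate_image(img).astype(float)
    out = arr
    if cfg.median:
        out = ndimage.median_filter(out, size=3, mode="reflect")
    if cfg.stretch:
        lo, hi = np.percentile(out, [cfg.p_low, cfg.p_high])
        if hi > lo:
            out = np.clip((out - lo) * (255.0 / (hi - lo)), 0.0, 255.0)
        else:
            warnings.warn("constant image: contrast stretch skipped", stacklevel=2)
    return out
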