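"""Fourier-spectrum geometric feature extraction.

The descriptor of an image is the triple ``(major, minor, area)`` of the
moment-ellipse fitted to the central blob of its thresholded log power
spectrum:

1. compute the 2-D DFT of the image with 1/(M*N) normalization;
2. shift the zero-frequency term to the grid center;
3. binarize ``log(1 + modulus)`` at a per-image quantile threshold
   (the quantile itself is trained on labeled data, see
   :func:`train_threshold`);
4. take the 8-connected component containing the center cell and report the
   full axis lengths of the ellipse with the same second central moments,
   plus the component's pixel count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .exceptions import ContractError
from .imaging import validate_image

#: Default quantile grid searched when training the binarization threshold.
DEFAULT_QUANTILE_GRID = (0.90, 0.925, 0.95, 0.975, 0.99, 0.995)

_EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class SpectrumImage:
    """Complex 2-D DFT of an image, with polar representation attached."""

    real: np.ndarray
    imag: np.ndarray
    modulus: np.ndarray
    phase: np.ndarray
    centered: bool = False

    @property
    def shape(self) -> tuple[int, int]:
        return self.real.shape

    @property
    def center(self) -> tuple[int, int]:
        """Grid cell holding the zero-frequency term once centered."""
        m, n = self.shape
        return (m // 2, n // 2)


@dataclass(frozen=True)
class BinarySpectrum:
    """Thresholded spectrum: True where log(1+modulus) exceeds the threshold."""

    mask: np.ndarray
    threshold_used: float
    quantile_used: float
    center: tuple[int, int]


@dataclass(frozen=True)
class FFGFVector:
    """The 3-D descriptor: full major/minor axis lengths and blob pixel count."""

    major: float
    minor: float
    area: int

    def as_array(self) -> np.ndarray:
        return np.array([self.major, self.minor, self.area], dtype=float)


def compute_dft(img: np.ndarray) -> SpectrumImage:
    """2-D DFT of a grayscale image with 1/(M*N) normalization.

    For an M x N image f, coefficient (u, v) is
    ``(1/(M*N)) * sum_{x,y} f(x,y) exp(-2*pi*i*(u*x/M + v*y/N))``,
    so the (0, 0) term equals the mean intensity.
    """
    arr = validate_image(img).astype(float)
    m, n = arr.shape
    coeffs = np.fft.fft2(arr) / (m * n)
    re, im = coeffs.real, coeffs.imag
    return SpectrumImage(
        real=re,
        imag=im,
        modulus=np.hypot(re, im),
        phase=_phase(re, im),
        centered=False,
    )


def spectrum_modulus(spec: SpectrumImage) -> np.ndarray:
    """Elementwise ``sqrt(Re^2 + Im^2)``."""
    return np.hypot(spec.real, spec.imag)


def _phase(re: np.ndarray, im: np.ndarray) -> np.ndarray:
    phase = np.arctan2(im, re)
    # arctan2 yields -pi for (negative, -0.0); fold onto (-pi, pi]
    phase[phase == -np.pi] = np.pi
    return phase


def spectrum_phase(spec: SpectrumImage) -> np.ndarray:
    """Four-quadrant angle of (Re, Im) in radians, in (-pi, pi]; 0 at origin."""
    return _phase(np.asarray(spec.real, dtype=float), np.asarray(spec.imag, dtype=float))


def center_spectrum(spec: SpectrumImage) -> SpectrumImage:
    """Cyclically shift all grids so (0, 0) moves to (M//2, N//2)."""
    if spec.centered:
        raise ContractError("spectrum is already centered")
    return SpectrumImage(
        real=np.fft.fftshift(spec.real),
        imag=np.fft.fftshift(spec.imag),
        modulus=np.fft.fftshift(spec.modulus),
        phase=np.fft.fftshift(spec.phase),
        centered=True,
    )


def uncenter_spectrum(spec: SpectrumImage) -> SpectrumImage:
    """Inverse of :func:`center_spectrum`."""
    if not spec.centered:
        raise ContractError("spectrum is not centered")
    return SpectrumImage(
        real=np.fft.ifftshift(spec.real),
        imag=np.fft.ifftshift(spec.imag),
        modulus=np.fft.ifftshift(spec.modulus),
        phase=np.fft.ifftshift(spec.phase),
        centered=False,
    )


def binarize_spectrum(spec: SpectrumImage, q: float) -> BinarySpectrum:
    """Threshold ``log(1 + modulus)`` at its q-quantile over all cells.

    The center (zero-frequency) cell is always set True: it carries the total
    image energy and anchors the central blob.
    """
    if not (0.0 < q < 1.0):
        raise ContractError(f"quantile must lie in (0, 1), got {q}")
    if not spec.centered:
        raise ContractError("binarize_spectrum requires a centered spectrum")
    logmod = np.log1p(spec.modulus)
    threshold = float(np.quantile(logmod, q))
    mask = logmod > threshold
    center = spec.center
    mask[center] = True
    return BinarySpectrum(
        mask=mask, threshold_used=threshold, quantile_used=q, center=center
    )


def _component_moments(rows: np.ndarray, cols: np.ndarray) -> tuple[float, float]:
    """Full axis lengths of the moment-ellipse of a pixel set.

    Each pixel is treated as a unit square, contributing 1/12 to each
    coordinate variance, so collinear components still have a positive minor
    axis.  Axis length = 4 * sqrt(eigenvalue of the coordinate covariance);
    this reproduces 2a and 2b exactly for an ideal filled ellipse with
    semi-axes a, b.
    """
    r = rows - rows.mean()
    c = cols - cols.mean()
    n = r.size
    crr = float(r @ r) / n + 1.0 / 12.0
    ccc = float(c @ c) / n + 1.0 / 12.0
    crc = float(r @ c) / n
    # eigenvalues of [[crr, crc], [crc, ccc]]
    tr, det = crr + ccc, crr * ccc - crc * crc
    disc = max((tr / 2.0) ** 2 - det, 0.0) ** 0.5
    lam1, lam2 = tr / 2.0 + disc, max(tr / 2.0 - disc, 0.0)
    return 4.0 * lam1**0.5, 4.0 * lam2**0.5


def central_ellipse(binary: BinarySpectrum) -> FFGFVector:
    """Fit the moment-ellipse to the 8-connected blob containing the center.

    A single-pixel component degenerates to (1, 1, 1).
    """
    mask = binary.mask
    if not mask.any():
        raise ContractError("binary spectrum has no True pixels")
    if not mask[binary.center]:
        raise ContractError("center cell of the binary spectrum must be True")
    labels, _ = ndimage.label(mask, structure=_EIGHT_CONNECTED)
    blob = labels == labels[binary.center]
    rows, cols = np.nonzero(blob)
    area = int(rows.size)
    if area == 1:
        return FFGFVector(major=1.0, minor=1.0, area=1)
    major, minor = _component_moments(rows.astype(float), cols.astype(float))
    return FFGFVector(major=major, minor=minor, area=area)


def extract_ffgf(img: np.ndarray, q: float) -> FFGFVector:
    """Run the full extraction on one image at binarization quantile q."""
    spec = center_spectrum(compute_dft(img))
    return central_ellipse(binarize_spectrum(spec, q))


def fisher_ratio(values: np.ndarray, labels: np.ndarray) -> float:
    """Between-class over within-class variance of a scalar feature.

    Computed as (mean difference)^2 / (sum of per-class population variances).
    Returns ``inf`` when the classes are separated with zero within-class
    spread, and 0.0 when the class means coincide.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    pos = values[labels == 1]
    neg = values[labels == -1]
    if pos.size == 0 or neg.size == 0:
        raise ContractError("fisher_ratio requires both classes present")
    between = (pos.mean() - neg.mean()) ** 2
    within = pos.var() + neg.var()
    if within == 0.0:
        return np.inf if between > 0.0 else 0.0
    return float(between / within)


def train_threshold(
    spectra: list[SpectrumImage],
    labels: np.ndarray,
    grid: tuple[float, ...] = DEFAULT_QUANTILE_GRID,
) -> float:
    """Pick the binarization quantile maximizing class separation.

    For every candidate quantile each spectrum is binarized at its own
    quantile of log(1+modulus); the Fisher ratio of the resulting blob-area
    feature selects the winner.  Ties (and the all-zero case) resolve toward
    the smaller quantile.  A candidate that separates the classes with zero
    within-class variance wins immediately.
    """
    labels = np.asarray(labels)
    if len(spectra) != len(labels):
        raise ContractError("spectra and labels must have equal length")
    if len(spectra) < 2 or not ({1, -1} <= set(labels.tolist())):
        raise ContractError("threshold training needs >=2 spectra with both labels")
    areas = area_table(spectra, grid)
    return select_quantile(areas, labels, grid)


def area_table(
    spectra: list[SpectrumImage], grid: tuple[float, ...]
) -> np.ndarray:
    """Blob areas for every (spectrum, quantile) pair; shape (n, len(grid))."""
    out = np.empty((len(spectra), len(grid)), dtype=float)
    for i, spec in enumerate(spectra):
        centered = spec if spec.centered else center_spectrum(spec)
        for j, q in enumerate(grid):
            out[i, j] = central_ellipse(binarize_spectrum(centered, q)).area
    return out


def select_quantile(
    areas: np.ndarray, labels: np.ndarray, grid: tuple[float, ...]
) -> float:
    """Fisher-ratio argmax over a precomputed area table (ties -> smaller q)."""
    order = np.argsort(grid)
    best_q, best_ratio = None, -np.inf
    for j in order:
        ratio = fisher_ratio(areas[:, j], labels)
        if np.isinf(ratio):
            return float(grid[j])
        if ratio > best_ratio:
            best_q, best_ratio = float(grid[j]), ratio
    return best_q
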