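"""Image statistics for biomolecular condensation.

Two complementary statistics quantify how much of a fluorescence signal has
redistributed from a diffuse field into puncta:

* **condensation ratio** (Fourier space): the image is mean-subtracted,
  zero-padded (600² inputs pad to 1024², matching the general rule of the
  next power of two >= 1.7x the largest dimension), and the fraction of the
  non-DC power spectrum lying beyond a radius cutoff (default 6 px) is
  reported.  Puncta inject high-spatial-frequency power, so the ratio rises
  with the condensed fraction; it lies in [0, 1] and is invariant to additive
  offsets (which land in the excluded DC term) and to positive rescaling.

* **granulosity index** (real space): after removing low frequencies with a
  circular high-pass Fourier mask, the standard deviation of the filtered
  signal within an ROI is divided by the ROI mean of the background-subtracted
  original image.  Being computed in real space it can be restricted to an
  ROI such as a segmented nucleus, which the Fourier-space ratio cannot.

Also here: the ring power profile the ratio is built from, a cortical/cytosolic
intensity ratio for membrane-recruitment assays, per-cell baseline
normalization, and an Otsu-threshold nuclear segmentation fallback.
Images are 2-D nonnegative numpy arrays (row-major, origin top-left); masks
are boolean arrays of the same shape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import filters, morphology

__all__ = [
    "PowerSpectrumProfile",
    "CondensationMetrics",
    "default_pad_size",
    "radial_power_profile",
    "condensation_ratio",
    "high_pass_filter",
    "granulosity_index",
    "normalize_to_baseline",
    "cortical_ratio",
    "segment_nuclei_threshold",
]


@dataclass
class PowerSpectrumProfile:
    """Fraction of non-DC spectral power per concentric Fourier ring."""

    ring_edges: np.ndarray  # inner radii, rings are [r, r + ring_width)
    fraction: np.ndarray
    total_power: float
    ring_width: int = 3


@dataclass
class CondensationMetrics:
    condensation_ratio: float
    granulosity_index: float = np.nan
    normalized_granulosity: float = np.nan


def _check_image(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if min(img.shape) < 16:
        raise ValueError("image dimensions must be >= 16 px")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    return img


def default_pad_size(shape: tuple[int, int]) -> int:
    """Next power of two >= 1.7x the largest dimension (600² -> 1024)."""
    target = 1.7 * max(shape)
    return int(2 ** np.ceil(np.log2(target)))


def _radius_grid(n: int) -> np.ndarray:
    c = n // 2
    yy, xx = np.ogrid[:n, :n]
    return np.hypot(yy - c, xx - c)


def radial_power_profile(
    image: np.ndarray,
    pad_size: int | None = None,
    ring_width: int = 3,
) -> PowerSpectrumProfile:
    """Ring-binned power spectrum of a mean-subtracted, zero-padded image.

    Power |FFT|² is centered and binned into half-open rings [r, r+w) of
    ``ring_width`` px from the Fourier-space origin; fractions are normalized
    by the total non-DC power, so they sum to 1.
    """
    img = _check_image(image)
    if ring_width < 1:
        raise ValueError("ring_width must be >= 1")
    if pad_size is None:
        pad_size = default_pad_size(img.shape)
    if pad_size < max(img.shape):
        raise ValueError("pad_size must be >= both image dimensions")

    img = img - img.mean()
    if not np.any(img):
        raise ValueError("image is uniform: power spectrum undefined after mean subtraction")
    padded = np.zeros((pad_size, pad_size))
    padded[: img.shape[0], : img.shape[1]] = img
    power = np.abs(np.fft.fftshift(np.fft.fft2(padded))) ** 2

    r = _radius_grid(pad_size)
    dc = r == 0
    total = float(power[~dc].sum())
    nbins = int(np.ceil(r.max() / ring_width)) + 1
    idx = (r / ring_width).astype(int)
    sums = np.bincount(idx[~dc].ravel(), weights=power[~dc].ravel(), minlength=nbins)
    edges = np.arange(nbins) * ring_width
    return PowerSpectrumProfile(
        ring_edges=edges, fraction=sums / total, total_power=total, ring_width=ring_width
    )


def condensation_ratio(
    image: np.ndarray,
    cutoff_radius: float = 6.0,
    pad_size: int | None = None,
    blank_policy: str = "error",
) -> float:
    """Fraction of non-DC spectral power beyond ``cutoff_radius`` px.

    Uniform (blank) inputs have no non-DC power; by default this raises, or
    returns 0.0 with ``blank_policy="zero"``.
    """
    img = _check_image(image)
    if pad_size is None:
        pad_size = default_pad_size(img.shape)
    centered = img - img.mean()
    if not np.any(centered):
        if blank_policy == "zero":
            return 0.0
        raise ValueError("uniform image: condensation ratio undefined (see blank_policy)")
    padded = np.zeros((pad_size, pad_size))
    padded[: img.shape[0], : img.shape[1]] = centered
    power = np.abs(np.fft.fftshift(np.fft.fft2(padded))) ** 2
    r = _radius_grid(pad_size)
    nondc = r > 0
    total = power[nondc].sum()
    high = power[nondc & (r > cutoff_radius)].sum()
    return float(high / total)


def high_pass_filter(image: np.ndarray, cutoff_radius: float) -> np.ndarray:
    """Zero all Fourier coefficients with radius <= cutoff (incl. DC); return
    the real part of the inverse transform.  Linear in the image."""
    img = _check_image(image)
    if cutoff_radius < 1:
        raise ValueError("cutoff_radius must be >= 1")
    f = np.fft.fftshift(np.fft.fft2(img))
    n0, n1 = img.shape
    yy, xx = np.ogrid[:n0, :n1]
    r = np.hypot(yy - n0 // 2, xx - n1 // 2)
    f[r <= cutoff_radius] = 0.0
    return np.real(np.fft.ifft2(np.fft.ifftshift(f)))


def granulosity_index(
    image: np.ndarray,
    roi: np.ndarray | None = None,
    cutoff_radius: float = 6.0,
    background: float | None = None,
) -> float:
    """s.d. of the high-pass-filtered signal in the ROI over the ROI mean of
    the background-subtracted image.

    ``background`` defaults to the median intensity outside the ROI (a
    homogeneous background estimate); pass 0.0 for pre-subtracted images.
    Scale-invariant by construction; 0 for a uniform ROI.
    """
    img = _check_image(image)
    if roi is None:
        roi = np.ones(img.shape, dtype=bool)
        if background is None:
            background = 0.0
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != img.shape:
        raise ValueError("ROI mask must match the image shape")
    if roi.sum() < 32:
        raise ValueError("ROI has < 32 foreground pixels: metric not valid")
    if background is None:
        outside = img[~roi]
        background = float(np.median(outside)) if outside.size else 0.0
    sub = np.clip(img - background, 0.0, None)
    denom = float(sub[roi].mean())
    if denom <= 0:
        raise ValueError("ROI mean <= 0 after background subtraction: index undefined")
    hp = high_pass_filter(sub, cutoff_radius)
    return float(hp[roi].std() / denom)


def normalize_to_baseline(
    series: list[tuple[object, float]],
    baseline_id: object,
) -> list[tuple[object, float]]:
    """Divide every (frame, value) by the baseline frame's value."""
    values = dict(series)
    if baseline_id not in values:
        raise KeyError(f"baseline frame {baseline_id!r} not in series")
    base = values[baseline_id]
    if base <= 0:
        raise ValueError("baseline value must be positive")
    return [(fid, v / base) for fid, v in series]


def cortical_ratio(
    image: np.ndarray,
    cell_mask: np.ndarray,
    band_width: int = 3,
) -> float:
    """Median cortical over median cytosolic intensity, background-subtracted.

    The cortical band is the mask minus its erosion by ``band_width`` px (the
    peripheral-most pixels); the cytosol is the eroded interior.  The
    background estimate (median outside the mask) is subtracted from both, so
    the ratio is invariant to a constant offset.
    """
    img = _check_image(image)
    mask = np.asarray(cell_mask, dtype=bool)
    if mask.shape != img.shape:
        raise ValueError("cell mask must match the image shape")
    interior = ndimage.binary_erosion(mask, morphology.disk(band_width))
    if not interior.any():
        raise ValueError("mask interior empty after erosion: cell too small for band_width")
    band = mask & ~interior
    outside = img[~mask]
    background = float(np.median(outside)) if outside.size else 0.0
    cortical = np.median(img[band]) - background
    cytosolic = np.median(img[interior]) - background
    if cytosolic <= 0:
        raise ValueError("cytosolic signal <= 0 after background subtraction")
    return float(cortical / cytosolic)


def segment_nuclei_threshold(
    nuclear_stain: np.ndarray,
    min_area: int = 64,
) -> list[np.ndarray]:
    """Otsu threshold -> hole fill -> small-object removal -> one boolean mask
    per connected component.  Touching nuclei come back as one component;
    a blank image yields an empty list."""
    img = _check_image(nuclear_stain)
    if img.max() == img.min():
        return []
    binary = img > filters.threshold_otsu(img)
    binary = ndimage.binary_fill_holes(binary)
    labels, n = ndimage.label(binary)
    areas = np.bincount(labels.ravel())
    return [labels == i for i in range(1, n + 1) if areas[i] >= min_area]
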