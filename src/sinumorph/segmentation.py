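"""Segmentation of the blood-vessel cast from the denoised scan.

The cast resin is the bright phase, so the vessel lumen network is the
foreground of a global threshold.  The workflow is: 7x7x7 median
filter, Otsu threshold, filling of enclosed background holes, and a size-3
cubical opening against segmentation noise.

Connectivity conventions: 26-adjacency for foreground, 6-adjacency for
background.  A background component counts as an enclosed hole only when it
does not touch the volume boundary — a cavity whose only outlet leaves the
image cannot be proven enclosed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from . import _morph
from .volume_io import BinaryVolume, GrayVolume


class SegmentationError(RuntimeError):
    pass


@dataclass
class SegmentationParams:
    median_size: int = 7
    noise_opening_size: int = 3
    threshold_override: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.median_size < 1 or self.median_size % 2 == 0:
            raise ValueError("median_size must be odd and >= 1")
        if self.noise_opening_size < 1:
            raise ValueError("noise_opening_size must be >= 1")
        if self.threshold_override is not None:
            lo, hi = self.threshold_override
            if not lo < hi:
                raise ValueError("threshold override requires t_low < t_high")


def median_denoise(volume: GrayVolume, size: int = 7) -> GrayVolume:
    """Median filter with a cubic ``size^3`` mask; boundary by reflection."""
    if size % 2 == 0:
        raise ValueError("median filter size must be odd")
    out = ndi.median_filter(volume.data, size=size, mode="reflect")
    return GrayVolume(out, volume.spacing)


def _masked_values(volume: GrayVolume, window: np.ndarray | None) -> np.ndarray:
    if window is None:
        return volume.data.ravel()
    return volume.data[window]


def otsu_threshold(
    volume: GrayVolume, window: np.ndarray | None = None, nbins: int = 256
) -> float:
    """Otsu's threshold on an ``nbins``-bin histogram spanning the observed
    intensity range; ties resolved towards the lowest maximizing bin.

    Returns the lower edge of the first bin of the upper class; voxels with
    intensity >= the returned value belong to the bright (cast) class.
    """
    values = np.asarray(_masked_values(volume, window), dtype=np.float64)
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        raise SegmentationError("degenerate histogram: volume is constant")
    hist, edges = np.histogram(values, bins=nbins, range=(lo, hi))
    return float(edges[_otsu_split(hist) + 1])


def _otsu_split(hist: np.ndarray) -> int:
    """Index k maximizing between-class variance for the split
    ``bins[0..k] | bins[k+1..]``; lowest k on ties."""
    hist = np.asarray(hist, dtype=np.float64)
    centers = np.arange(hist.size)
    w0 = np.cumsum(hist)[:-1]
    w1 = hist.sum() - w0
    m = np.cumsum(hist * centers)
    mu0 = np.divide(m[:-1], w0, out=np.zeros_like(w0), where=w0 > 0)
    mu1 = np.divide(m[-1] - m[:-1], w1, out=np.zeros_like(w1), where=w1 > 0)
    valid = (w0 > 0) & (w1 > 0)
    sigma_b = np.where(valid, w0 * w1 * (mu0 - mu1) ** 2, -np.inf)
    if not np.isfinite(sigma_b).any():
        raise SegmentationError("degenerate histogram: single occupied bin")
    return int(np.argmax(sigma_b))


def binarize(volume: GrayVolume, t_low: float, t_high: float = np.inf) -> BinaryVolume:
    """Band threshold: mask = { t_low <= intensity < t_high }."""
    if not t_low < t_high:
        raise ValueError("t_low must be below t_high")
    mask = (volume.data >= t_low) & (volume.data < t_high)
    return BinaryVolume(mask, volume.spacing)


def fill_enclosed_holes(mask: BinaryVolume) -> BinaryVolume:
    """Fill every 6-connected background component that does not touch the
    volume boundary.  Foreground is never removed."""
    labels, faces, nlab = _morph.background_face_counts(mask.mask)
    if nlab == 0:
        return BinaryVolume(mask.mask.copy(), mask.spacing)
    enclosed = faces == 0
    enclosed[0] = False
    out = mask.mask | enclosed[labels]
    return BinaryVolume(out, mask.spacing)


def remove_small_noise(mask: BinaryVolume, size: int = 3) -> BinaryVolume:
    """Morphological opening with a ``size^3`` cube."""
    return BinaryVolume(_morph.open_cube(mask.mask, size), mask.spacing)


def segment_vessels(
    volume: GrayVolume, params: SegmentationParams | None = None
) -> tuple[BinaryVolume, dict]:
    """Full segmentation chain: median denoise, Otsu (or override) threshold,
    hole filling, small-noise opening.

    Returns the vessel mask and a provenance dict with the threshold used.
    """
    params = params or SegmentationParams()
    den = median_denoise(volume, params.median_size)
    if params.threshold_override is not None:
        t_low, t_high = params.threshold_override
    else:
        t_low, t_high = otsu_threshold(den), np.inf
    mask = binarize(den, t_low, t_high)
    mask = fill_enclosed_holes(mask)
    mask = remove_small_noise(mask, params.noise_opening_size)
    info = {
        "threshold_low": float(t_low),
        "threshold_high": float(t_high) if np.isfinite(t_high) else None,
        "median_size": params.median_size,
        "noise_opening_size": params.noise_opening_size,
    }
    return mask, info
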