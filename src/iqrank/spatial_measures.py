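"""Contrast quantification: masked-histogram Shannon entropy.

Fluorescence micrographs are mostly dark background, so an unmasked
intensity histogram is dominated by background counts and says little
about the signal.  The detail mask selects the ~20% of pixels whose
*locally averaged* intensity is highest: the image is smoothed with a
large uniform mean filter (radius 100 px by default, so isolated bright
specks such as dust cannot qualify on their own) and thresholded at the
80th percentile of the smoothed values.  The histogram of the original
pixel values inside that mask is then scored by Shannon entropy — high
entropy means the selected region occupies many distinct gray levels,
i.e. the image has contrast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ParameterError
from .image_io import GrayImage

DEFAULT_FILTER_RADIUS = 100
DEFAULT_PERCENTILE = 80.0
DEFAULT_BINS = 256


@dataclass(frozen=True)
class DetailMask:
    """Boolean mask of the high-content neighborhoods of an image."""

    selected: np.ndarray

    @property
    def coverage(self) -> float:
        """Fraction of pixels selected (≤ ~0.20 by construction)."""
        return float(self.selected.mean())

    @property
    def n_selected(self) -> int:
        return int(self.selected.sum())


@dataclass(frozen=True)
class NormalizedHistogram:
    """Histogram normalized to unit mass: P_i ≥ 0, Σ P_i = 1."""

    probabilities: np.ndarray
    bin_edges: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=np.float64)
        if p.min() < 0 or abs(p.sum() - 1.0) > 1e-9:
            raise ParameterError("histogram probabilities must be ≥ 0 and sum to 1")
        object.__setattr__(self, "probabilities", p)


def compute_detail_mask(
    img: GrayImage,
    filter_radius: int = DEFAULT_FILTER_RADIUS,
    percentile: float = DEFAULT_PERCENTILE,
) -> DetailMask:
    """Mask of pixels whose mean-filtered intensity exceeds the given percentile.

    The uniform filter is square with side ``2*filter_radius + 1`` and
    reflect boundary handling (avoids dark-edge artifacts near borders).
    For images smaller than the filter, the radius is clamped to
    ``min_dim//2 - 1`` with a warning.  Thresholding uses a strict
    inequality, so ties at the percentile value are excluded and coverage
    stays ≤ (100 - percentile)%; a constant image (nothing strictly above
    the threshold) falls back to an all-true mask.
    """
    if filter_radius < 1:
        raise ParameterError(f"filter_radius must be ≥ 1, got {filter_radius}")
    if not 0 < percentile < 100:
        raise ParameterError(f"percentile must be in (0, 100), got {percentile}")
    min_dim = min(img.height, img.width)
    if filter_radius > max(img.height, img.width):
        raise ParameterError(
            f"filter_radius {filter_radius} exceeds both image dimensions {img.pixels.shape}"
        )
    side = 2 * filter_radius + 1
    if side > min_dim:
        clamped = min_dim // 2 - 1
        warnings.warn(
            f"mean-filter radius {filter_radius} too large for image "
            f"{img.pixels.shape}; clamped to {clamped}",
            stacklevel=2,
        )
        filter_radius = clamped
        side = 2 * filter_radius + 1
    smoothed = ndimage.uniform_filter(img.pixels, size=side, mode="reflect")
    threshold = np.percentile(smoothed, percentile)
    selected = smoothed > threshold
    if not selected.any():
        selected = np.ones_like(selected, dtype=bool)
    return DetailMask(selected)


def masked_histogram(
    img: GrayImage, mask: DetailMask, n_bins: int = DEFAULT_BINS,
    value_range: tuple[float, float] | None = None,
) -> NormalizedHistogram:
    """Unit-mass histogram of the original pixel values inside the mask.

    Bins are equal-width over [min, max] of the selected values (so the
    entropy measures occupancy of the values actually present), or over
    ``value_range`` when a fixed sensor range is preferred.
    """
    if mask.selected.shape != img.pixels.shape:
        raise ParameterError("mask shape does not match image shape")
    if n_bins < 2:
        raise ParameterError(f"n_bins must be ≥ 2, got {n_bins}")
    values = img.pixels[mask.selected]
    if values.size == 0:
        raise ParameterError("mask selects no pixels")
    if value_range is None:
        lo, hi = float(values.min()), float(values.max())
        if lo == hi:
            hi = lo + 1.0  # constant selection: all mass lands in bin 0
    else:
        lo, hi = value_range
    counts, edges = np.histogram(values, bins=n_bins, range=(lo, hi))
    return NormalizedHistogram(counts / counts.sum(), edges)


def shannon_entropy(hist: NormalizedHistogram) -> float:
    """Shannon entropy −Σ P_i·log2(P_i) in bits, with 0·log2(0) = 0.

    Lies in [0, log2(n_bins)]; 0 for a single-bin histogram, log2(n_bins)
    for a uniform one.
    """
    p = hist.probabilities
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())
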