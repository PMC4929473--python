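"""Classical autofocus metrics used as benchmarks for the ranking measures.

Brenner's focus function is a spatial-domain derivative: the sum of
squared intensity differences between pixels two columns apart.  The
Spectral Moments metric is a frequency-domain score: a log-index-weighted
sum over the *entire* normalized 1D power spectrum (no tail crop), where
the logarithmic weight grows with the spectral index and so emphasizes
high frequencies relative to an unweighted sum.  Both decrease with
defocus and are classic baselines for blur detection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError
from .image_io import GrayImage
from .spectral_measures import power_spectrum_2d, reduce_summed


@dataclass(frozen=True)
class FocusScore:
    value: float
    metric_name: str


def _brenner_sum(pixels: np.ndarray) -> float:
    # F = sum_ij (G[i, j+2] - G[i, j])^2, two-sample shift along rows
    diff = pixels[:, 2:] - pixels[:, :-2]
    return float((diff * diff).sum())


def brenner(img: GrayImage) -> FocusScore:
    """Brenner autofocus score: Σ_ij (G_{i,j+2} − G_{i,j})².

    The two-pixel shift runs along the row (horizontal) direction; a
    constant image scores 0, and the score decreases monotonically with
    Gaussian blur on any structured image.
    """
    if img.width < 3:
        raise ParameterError("Brenner metric requires image width ≥ 3")
    return FocusScore(_brenner_sum(img.pixels), "brenner")


def _spectral_moment_sum(power_1d: np.ndarray) -> float:
    # F = sum_i log2(1 + i) * P_i with P normalized to unit mass
    total = power_1d.sum()
    if total <= 0:
        raise ParameterError("power spectrum sums to zero")
    p = power_1d / total
    i = np.arange(p.size)
    return float((np.log2(1.0 + i) * p).sum())


def spectral_moments(img: GrayImage) -> FocusScore:
    """Spectral Moments autofocus score over the entire 1D power spectrum.

    The summed 1D reduction is normalized to unit mass and each component
    is weighted by log2(1 + index): blur shifts spectral mass toward low
    indices and lowers the score.  No threshold crop is applied.
    """
    ps1d = reduce_summed(power_spectrum_2d(img))
    return FocusScore(_spectral_moment_sum(ps1d.power), "spectral_moments")
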