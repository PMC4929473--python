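"""Power-spectrum tail statistics for detail, blur and noise detection.

Blur attenuates the high-frequency tail of an image's power spectrum;
noise amplifies it.  Large spatial structures, which differ from image
to image, live at low frequencies — so all statistics here are computed
on the tail above a frequency threshold (default 40% of the maximum
representable frequency; 2% when a wide blur-detection dynamic range is
wanted, e.g. for autofocus series).

The 2D spectrum is the squared magnitude of the centered Fourier
transform, divided by the image's mean gray level and its pixel count so
that a common brightness scale largely cancels between images.  Two 1D
reductions are provided: a radial average (mean power at each integer
radius from the zero-frequency center) and a faster summed profile (rows
and columns summed, negative frequencies folded onto positive ones).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import ParameterError
from .image_io import GrayImage

DEFAULT_THRESHOLD = 0.40
HIGH_TAIL_FRACTION = 0.90
MEANBIN_WIDTH = 5


@dataclass(frozen=True)
class PowerSpectrum2D:
    """Zero-frequency-centered normalized power spectrum of an image."""

    power: np.ndarray
    mean_gray: float
    n_pixels: int


@dataclass(frozen=True)
class PowerSpectrum1D:
    """1D power profile over the fraction of the maximum frequency.

    ``freq_fraction`` is strictly increasing from 0 to 1; ``method``
    records which reduction produced it.
    """

    freq_fraction: np.ndarray
    power: np.ndarray
    method: str

    def __post_init__(self) -> None:
        f = np.asarray(self.freq_fraction, dtype=np.float64)
        p = np.asarray(self.power, dtype=np.float64)
        if f.size != p.size or f.size < 8:
            raise ParameterError("1D spectrum needs ≥ 8 matching samples")
        if f[0] != 0.0 or abs(f[-1] - 1.0) > 1e-12 or np.any(np.diff(f) <= 0):
            raise ParameterError("freq_fraction must increase strictly from 0 to 1")
        object.__setattr__(self, "freq_fraction", f)
        object.__setattr__(self, "power", p)


@dataclass(frozen=True)
class SpectralStats:
    """Statistics of the power-spectrum tail above ``threshold``.

    fMean/fSTD: mean and standard deviation of the tail power values;
    cv = fSTD/fMean; skewness and (excess) kurtosis of the tail values;
    spectral_entropy: Shannon entropy (bits) of the tail renormalized to
    unit mass; high90_power: summed power above 90% of the maximum
    frequency; MeanBin: mean of the first five tail samples.
    """

    fMean: float
    fSTD: float
    cv: float
    kurtosis: float
    spectral_entropy: float
    skewness: float
    high90_power: float
    MeanBin: float
    threshold: float

    def as_dict(self) -> dict[str, float]:
        return {
            "fMean": self.fMean,
            "fSTD": self.fSTD,
            "cv": self.cv,
            "kurtosis": self.kurtosis,
            "spectral_entropy": self.spectral_entropy,
            "skewness": self.skewness,
            "high90": self.high90_power,
            "MeanBin": self.MeanBin,
        }


def power_spectrum_2d(img: GrayImage) -> PowerSpectrum2D:
    """Centered |FFT|², divided by (mean gray level × pixel count).

    Before the division the spectrum satisfies Parseval's identity
    Σ|F|²/N = Σ g².  The brightness normalization makes the spectrum
    scale linearly (not quadratically) with a common intensity factor.
    """
    mean = img.mean
    if mean <= 0:
        raise ParameterError("image mean is zero; power-spectrum normalization undefined")
    fourier = np.fft.fftshift(np.fft.fft2(img.pixels))
    power = (fourier.real**2 + fourier.imag**2) / (mean * img.pixels.size)
    return PowerSpectrum2D(power, mean_gray=mean, n_pixels=img.pixels.size)


def reduce_radial(ps: PowerSpectrum2D) -> PowerSpectrum1D:
    """Radial average: mean power at each integer radius from the center.

    Distances are rounded to the nearest integer bin; radii run from 0 to
    the maximum inscribed radius (so every bin is fully sampled).
    """
    h, w = ps.power.shape
    cy, cx = h // 2, w // 2
    yy, xx = np.indices((h, w))
    r = np.rint(np.hypot(yy - cy, xx - cx)).astype(np.intp)
    r_max = min(cy, cx, h - 1 - cy, w - 1 - cx)
    sums = np.bincount(r.ravel(), weights=ps.power.ravel())
    counts = np.bincount(r.ravel())
    profile = sums[: r_max + 1] / counts[: r_max + 1]
    freq = np.arange(r_max + 1) / r_max
    return PowerSpectrum1D(freq, profile, method="radial")


def _fold_centered(profile: np.ndarray) -> np.ndarray:
    """Fold a centered 1D profile: add each negative frequency to its positive twin.

    For even length n the DC sits at index n//2 and the unpaired Nyquist
    sample at index 0 becomes the last folded entry.
    """
    n = profile.size
    c = n // 2
    k_max = c  # Nyquist (even n) or (n-1)/2 (odd n)
    folded = np.empty(k_max + 1)
    folded[0] = profile[c]
    for k in range(1, k_max + 1):
        pos = c + k
        if pos < n:
            folded[k] = profile[pos] + profile[c - k]
        else:  # even n: only the negative-side Nyquist sample exists
            folded[k] = profile[c - k]
    return folded


def reduce_summed(ps: PowerSpectrum2D) -> PowerSpectrum1D:
    """Summed profile: rows and columns summed, negative frequencies folded.

    All rows are summed into a profile over horizontal frequency and all
    columns into one over vertical frequency; each is folded onto the
    positive half-axis, and the two are added.  For non-square images the
    shorter folded profile is linearly interpolated onto the longer one's
    frequency-fraction grid before summing.
    """
    row_profile = _fold_centered(ps.power.sum(axis=0))  # over horizontal frequency
    col_profile = _fold_centered(ps.power.sum(axis=1))  # over vertical frequency
    if row_profile.size >= col_profile.size:
        long_p, short_p = row_profile, col_profile
    else:
        long_p, short_p = col_profile, row_profile
    freq = np.arange(long_p.size) / (long_p.size - 1)
    if short_p.size != long_p.size:
        short_freq = np.arange(short_p.size) / (short_p.size - 1)
        short_p = np.interp(freq, short_freq, short_p)
    return PowerSpectrum1D(freq, long_p + short_p, method="summed")


def tail_stats(ps1d: PowerSpectrum1D, threshold: float = DEFAULT_THRESHOLD) -> SpectralStats:
    """Descriptive statistics of the spectrum tail above ``threshold``.

    ``threshold`` is a fraction of the maximum frequency in (0, 1); the
    cropped tail must contain at least five samples (MeanBin is the mean
    of the first five).  Skewness and kurtosis use the standard moment
    definitions (kurtosis is excess, Fisher convention).
    """
    if not 0 < threshold < 1:
        raise ParameterError(f"threshold must be in (0, 1), got {threshold}")
    tail = ps1d.power[ps1d.freq_fraction > threshold]
    if tail.size < MEANBIN_WIDTH:
        raise ParameterError(
            f"tail above threshold {threshold} has only {tail.size} samples "
            f"(needs ≥ {MEANBIN_WIDTH}); lower the threshold"
        )
    f_mean = float(tail.mean())
    f_std = float(tail.std())
    total = tail.sum()
    if total > 0:
        p = tail / total
        nz = p[p > 0]
        spec_entropy = float(-(nz * np.log2(nz)).sum())
    else:
        spec_entropy = 0.0
    high = ps1d.power[ps1d.freq_fraction > HIGH_TAIL_FRACTION]
    if f_std > 0:
        skewness = float(sps.skew(tail, bias=True))
        kurtosis = float(sps.kurtosis(tail, fisher=True, bias=True))
    else:  # constant tail: central moments vanish, define both as 0
        skewness = 0.0
        kurtosis = 0.0
    return SpectralStats(
        fMean=f_mean,
        fSTD=f_std,
        cv=f_std / f_mean if f_mean > 0 else 0.0,
        kurtosis=kurtosis,
        spectral_entropy=spec_entropy,
        skewness=skewness,
        high90_power=float(high.sum()),
        MeanBin=float(tail[:MEANBIN_WIDTH].mean()),
        threshold=threshold,
    )


def invert_measure(value: float) -> float:
    """1 − value, for dataset-normalized measures (inversion favors the opposite trait).

    Only defined after normalization, i.e. for values in [0, 1]: the
    inverse of a normalized spectral STD (invSTD) favors non-noisy
    images, because noise inflates the spectral tail.
    """
    if not 0.0 <= value <= 1.0:
        raise ParameterError(f"invert_measure expects a normalized value in [0, 1], got {value}")
    return 1.0 - value
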