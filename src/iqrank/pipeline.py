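"""Glue between per-image measures and the dataset ranking table."""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

from .errors import IQRankError
from .image_io import GrayImage, load_image, list_dataset
from .spatial_measures import (
    DEFAULT_BINS,
    DEFAULT_FILTER_RADIUS,
    DEFAULT_PERCENTILE,
    compute_detail_mask,
    masked_histogram,
    shannon_entropy,
)
from .spectral_measures import (
    DEFAULT_THRESHOLD,
    power_spectrum_2d,
    reduce_radial,
    reduce_summed,
    tail_stats,
)
from .focus_metrics import brenner, spectral_moments
from .ranking import MeasureRecord

log = logging.getLogger("iqrank")

SPECTRAL_MEASURE_NAMES = (
    "fMean", "fSTD", "cv", "kurtosis", "spectral_entropy", "skewness", "high90", "MeanBin",
)
METRIC_FUNCTIONS = {"brenner": brenner, "spectral_moments": spectral_moments}


@dataclass(frozen=True)
class MeasureConfig:
    """Per-image measurement parameters (defaults match standard practice:
    40% spectral threshold, r=100 mask filter, 80th-percentile mask,
    256 histogram bins, summed spectrum reduction)."""

    threshold: float = DEFAULT_THRESHOLD
    spectrum_method: str = "summed"
    mask_radius: int = DEFAULT_FILTER_RADIUS
    mask_percentile: float = DEFAULT_PERCENTILE
    bins: int = DEFAULT_BINS
    metrics: tuple[str, ...] = field(default=())


def measure_image(img: GrayImage, config: MeasureConfig | None = None) -> dict[str, float]:
    """All raw measures of one image: masked entropy, spectral tail stats,
    and any requested autofocus metrics."""
    cfg = config or MeasureConfig()
    mask = compute_detail_mask(img, cfg.mask_radius, cfg.mask_percentile)
    hist = masked_histogram(img, mask, cfg.bins)
    measures: dict[str, float] = {"entropy": shannon_entropy(hist)}
    ps2d = power_spectrum_2d(img)
    reduce = reduce_radial if cfg.spectrum_method == "radial" else reduce_summed
    measures.update(tail_stats(reduce(ps2d), cfg.threshold).as_dict())
    for name in cfg.metrics:
        measures[name] = METRIC_FUNCTIONS[name](img).value
    return measures


def measure_dataset(
    directory: str | os.PathLike,
    config: MeasureConfig | None = None,
    name_filter: str | None = None,
    skip_unreadable: bool = False,
) -> list[MeasureRecord]:
    """Measure every supported image in a directory, enumeration order preserved.

    With ``skip_unreadable`` (batch mode), unreadable files are logged
    and skipped instead of aborting the run; the caller is warned with a
    final count.
    """
    records = []
    n_failed = 0
    for path in list_dataset(directory, name_filter):
        try:
            img = load_image(path)
            records.append(MeasureRecord(path.name, measure_image(img, config)))
        except IQRankError as exc:
            if not skip_unreadable:
                raise
            n_failed += 1
            log.warning("skipping %s: %s", path, exc)
    if n_failed:
        log.warning("%d image(s) skipped as unreadable", n_failed)
    return records
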