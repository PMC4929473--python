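"""Dataset-level normalization, ranking, and order-preserving results output.

Ranking is *relative*: each measure is divided by its maximum within the
processed dataset, so every measure lands on a common 0–1 scale (signed
measures such as skewness are normalized on their absolute values).
Images can then be ordered by one measure or by the average of several —
e.g. the average of spatial entropy and invSTD (the inverse of the
normalized spectral STD) favors images with high contrast and non-dotty,
non-noisy structure.

Time-lapse recordings must never be reordered on disk, so the results
file always keeps the dataset enumeration order; sorting happens only in
the returned ranking lists.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ParameterError

#: Measures whose sign is irrelevant to ranking: normalized on |value|.
SIGNED_MEASURES = frozenset({"skewness"})

#: Inverse columns materialized after normalization (value -> 1 - value).
INVERSE_MEASURES = {"fSTD": "invSTD", "skewness": "invSkew", "MeanBin": "invMeanBin"}

FLAG_IN_FOCUS = "in_focus"
FLAG_BLURRED = "blurred"
FLAG_OUT_OF_FOCUS = "out_of_focus"


@dataclass(frozen=True)
class MeasureRecord:
    """Raw measure values of one image, keyed by measure name."""

    image_id: str
    raw_measures: dict[str, float]


@dataclass(frozen=True)
class RankingTable:
    """All records of a dataset plus 0–1 normalized measures.

    ``records`` keeps the dataset enumeration order at all times;
    ``normalized`` maps measure name (including inverse names such as
    ``invSTD``) to per-record values in [0, 1]; ``composite`` holds the
    averaged score when :func:`composite_score` has been applied.
    """

    records: tuple[MeasureRecord, ...]
    normalized: dict[str, np.ndarray]
    composite: np.ndarray | None = None
    composite_measures: tuple[str, ...] = field(default=())

    @property
    def image_ids(self) -> list[str]:
        return [r.image_id for r in self.records]

    @property
    def measure_names(self) -> list[str]:
        return list(self.records[0].raw_measures)

    def scores(self, key: str) -> np.ndarray:
        """Per-record values of a normalized measure or of ``"composite"``."""
        if key == "composite":
            if self.composite is None:
                raise ParameterError("no composite score computed; call composite_score first")
            return self.composite
        if key not in self.normalized:
            raise ParameterError(
                f"unknown measure {key!r}; available: {sorted(self.normalized)} + ['composite']"
            )
        return self.normalized[key]


def normalize_table(records: list[MeasureRecord]) -> RankingTable:
    """Normalize every measure column by its dataset maximum.

    Signed measures are first replaced by their absolute values.  An
    all-zero column maps to all zeros (with a warning) rather than NaN,
    so degenerate datasets stay processable.  Inverse columns (invSTD,
    invSkew, invMeanBin) are materialized for the measures they apply to.
    """
    if len(records) < 2:
        raise ParameterError("relative ranking needs at least 2 records")
    names = set(records[0].raw_measures)
    for r in records[1:]:
        if set(r.raw_measures) != names:
            raise ParameterError("all records must carry the same measure-name set")
    normalized: dict[str, np.ndarray] = {}
    for name in records[0].raw_measures:
        col = np.array([r.raw_measures[name] for r in records], dtype=np.float64)
        if name in SIGNED_MEASURES:
            col = np.abs(col)
        peak = col.max()
        if peak > 0:
            normalized[name] = col / peak
        else:
            warnings.warn(f"measure {name!r} is all-zero; normalized column set to 0", stacklevel=2)
            normalized[name] = np.zeros_like(col)
    for name, inv_name in INVERSE_MEASURES.items():
        if name in normalized:
            normalized[inv_name] = 1.0 - normalized[name]
    return RankingTable(records=tuple(records), normalized=normalized)


def composite_score(table: RankingTable, measures: list[str]) -> RankingTable:
    """Average the selected normalized measures into one composite score.

    ``measures`` may name any normalized or inverse column, e.g.
    ``["entropy", "invSTD"]`` — the recipe used to find high-contrast,
    well-labeled images in a mixed-quality dataset.
    """
    if not measures:
        raise ParameterError("composite_score needs at least one measure name")
    missing = [m for m in measures if m not in table.normalized]
    if missing:
        raise ParameterError(
            f"unknown measure(s) {missing}; available: {sorted(table.normalized)}"
        )
    stack = np.vstack([table.normalized[m] for m in measures])
    return replace(table, composite=stack.mean(axis=0), composite_measures=tuple(measures))


def rank_order(
    table: RankingTable, key: str = "composite", descending: bool = True
) -> list[tuple[str, float]]:
    """Images sorted by score (best first by default); ties broken by image_id.

    The underlying table's record order is never modified.
    """
    scores = table.scores(key)
    pairs = list(zip(table.image_ids, (float(s) for s in scores)))
    pairs.sort(key=lambda p: p[0])  # deterministic tie-break
    pairs.sort(key=lambda p: p[1], reverse=descending)
    return pairs


def to_dataframe(table: RankingTable) -> pd.DataFrame:
    """Table as a DataFrame in dataset enumeration order."""
    data: dict[str, object] = {"image_id": table.image_ids}
    for name in table.measure_names:
        data[name] = [r.raw_measures[name] for r in table.records]
    for name, col in table.normalized.items():
        key = name if name.startswith("inv") else f"norm_{name}"
        data[key] = col
    if table.composite is not None:
        data["composite"] = table.composite
    return pd.DataFrame(data)


def write_results(table: RankingTable, path: str | os.PathLike) -> None:
    """Write the results CSV: one row per image, dataset enumeration order.

    Columns: image_id, raw measures, normalized measures (``norm_``
    prefix), inverse measures, and the composite when present.  Floats
    are written at 9 significant digits.  The image files themselves are
    never touched.
    """
    df = to_dataframe(table)
    try:
        df.to_csv(path, index=False, float_format="%.9g")
    except OSError as exc:
        raise IOError(f"cannot write results to {path}: {exc}") from exc


def two_level_blur_flags(
    table: RankingTable, key: str, low_cut: float, high_cut: float
) -> list[str]:
    """Label each record by a two-threshold blur triage on a normalized score.

    score < low_cut → ``out_of_focus``; low_cut ≤ score < high_cut →
    ``blurred``; otherwise ``in_focus``.  Two levels match practice in
    screening time courses, where clearly out-of-focus frames must be
    discarded and slightly blurred ones flagged for review.
    """
    if not 0 <= low_cut <= high_cut <= 1:
        raise ParameterError(
            f"cuts must satisfy 0 ≤ low_cut ≤ high_cut ≤ 1, got ({low_cut}, {high_cut})"
        )
    scores = table.scores(key)
    labels = []
    for s in scores:
        if s < low_cut:
            labels.append(FLAG_OUT_OF_FOCUS)
        elif s < high_cut:
            labels.append(FLAG_BLURRED)
        else:
            labels.append(FLAG_IN_FOCUS)
    return labels
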