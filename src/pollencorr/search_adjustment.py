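"""Search-volume index normalization and the birch-pollen adjustment.

Public search-volume services report query frequency as an index
normalized to 0-100 over the requested period and region. Early in the
grass season such an index is contaminated by birch-pollen-driven
queries: birch flowers weeks before grass, and generic allergy keywords
do not separate the two. The adjustment multiplies the index, day by
day, by the grass fraction of the pooled pollen count,

    factor_t = grass_t / (grass_t + birch_t)  in [0, 1],

producing the *adjusted* series ("Google data (2)" in the source
terminology of such studies). Wherever birch is absent the factor is 1
and the series is untouched; the adjusted series is never re-normalized,
which is harmless downstream because cross-correlation is
scale-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from pollencorr.errors import AlignmentError, ValidationError

PROVENANCES = ("raw", "normalized", "adjusted")


@dataclass(frozen=True)
class SearchIndexSeries:
    """A region-labelled daily search-volume index with provenance tracking."""

    region: str
    values: pd.Series  # date-indexed, non-negative
    provenance: str = "raw"

    def __post_init__(self) -> None:
        if self.provenance not in PROVENANCES:
            raise ValidationError(f"unknown provenance {self.provenance!r}")
        if (self.values < 0).any():
            raise ValidationError("search index values must be non-negative")
        if self.provenance in ("normalized", "adjusted") and (self.values > 100 + 1e-9).any():
            raise ValidationError("normalized index values must lie in [0, 100]")


def normalize_index(raw: pd.Series, region: str = "") -> SearchIndexSeries:
    """Rescale a raw series so its maximum is 100 (0-100 search-volume index).

    Raises on an empty or all-zero input: there is no signal to normalize.
    Idempotent: a series whose maximum is already 100 is returned unchanged.
    """
    if raw.empty:
        raise ValidationError("no signal to normalize: empty series")
    if (raw < 0).any():
        raise ValidationError("raw search values must be non-negative")
    peak = float(raw.max())
    if peak == 0:
        raise ValidationError("no signal to normalize: all values are zero")
    return SearchIndexSeries(region=region, values=(raw / peak) * 100.0, provenance="normalized")


def _check_same_dates(a: pd.Series, b: pd.Series, what: str) -> None:
    ia, ib = pd.DatetimeIndex(a.index), pd.DatetimeIndex(b.index)
    only_a, only_b = ia.difference(ib), ib.difference(ia)
    if len(only_a) or len(only_b):
        raise AlignmentError(
            f"{what}: date mismatch; "
            f"missing from second series: {[str(d.date()) for d in only_a[:5]]}, "
            f"missing from first series: {[str(d.date()) for d in only_b[:5]]}"
        )


def birch_adjustment_factors(
    grass: pd.Series, birch: pd.Series, degenerate: str = "zero"
) -> pd.Series:
    """Per-day grass fraction grass/(grass+birch) of the pooled pollen count.

    Both series must cover the same dates. Factors are computed on raw
    counts (no smoothing); gap days must be gaps in both series and
    propagate as gaps.

    ``degenerate`` controls days where grass + birch = 0: ``"zero"``
    (default) assigns factor 0 — a day without grass pollen contributes no
    grass-attributable search signal — while ``"gap"`` drops the day.
    """
    if degenerate not in ("zero", "gap"):
        raise ValidationError(f"degenerate rule must be 'zero' or 'gap', got {degenerate!r}")
    _check_same_dates(grass, birch, "birch adjustment")
    if (grass < 0).any() or (birch < 0).any():
        raise ValidationError("pollen counts must be non-negative")
    birch = birch.reindex(grass.index)
    total = grass + birch
    with np.errstate(invalid="ignore", divide="ignore"):
        factors = grass / total
    if degenerate == "zero":
        factors = factors.where(total > 0, 0.0)
    else:
        factors = factors[total > 0]
    factors.name = "factor"
    return factors


def adjust_search_series(index: SearchIndexSeries, factors: pd.Series) -> SearchIndexSeries:
    """Multiply a normalized index day-wise by the grass-fraction factors.

    The factor series must cover every date of the index (extra factor
    dates are ignored). The result keeps the 0-100 input scale — it is
    *not* re-normalized — and carries provenance ``"adjusted"``.
    """
    if index.provenance != "normalized":
        raise ValidationError(
            f"adjustment requires a normalized index, got provenance {index.provenance!r}"
        )
    if ((factors < 0) | (factors > 1)).any():
        raise ValidationError("adjustment factors must lie in [0, 1]")
    missing = pd.DatetimeIndex(index.values.index).difference(pd.DatetimeIndex(factors.index))
    if len(missing):
        raise AlignmentError(
            f"adjustment factors missing for dates: {[str(d.date()) for d in missing[:5]]}"
        )
    adjusted = index.values * factors.reindex(index.values.index)
    return replace(index, values=adjusted, provenance="adjusted")
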