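"""Lagged cross-correlation with standard errors, significance and banding.

For two equal-length sequences x (predictor) and y (outcome) of length n,
the cross-correlation at lag k is estimated as

    ccf(k) = sum_t (x_{t+k} - xbar)(y_t - ybar) / (n * s_x * s_y),

summing over the n - |k| offsets where both terms exist, with xbar, ybar
the full-series means and s_x, s_y the full-series population standard
deviations (1/n scaling). This is the convention of mainstream
statistics packages; under it |ccf| <= 1 and ccf(x, y, k) = ccf(y, x, -k).

Sign convention: a NEGATIVE lag means the predictor x *leads* the
outcome y — at lag -1 today's predictor pairs with tomorrow's outcome,
so a best lag of -1 supports a next-day forecast reading.

The standard error of the estimate under independence is
1/sqrt(n - |k|); two-sided significance uses the normal approximation
p = 2 * (1 - Phi(|ccf| / se)). No multiple-testing correction is applied
across lags or series pairs (screening convention; see docs/methods.md).

Correlation-strength bands: 0 < ccf < 0.5 weak, 0.5 <= ccf < 0.8
moderate, 0.8 <= ccf <= 1 strong; non-positive values are banded
separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from pollencorr.errors import InsufficientOverlapError, ValidationError

#: Minimum common dates for align_series; below this the SE is meaningless.
MIN_OVERLAP = 15


@dataclass(frozen=True)
class LagWindow:
    """Inclusive range of lags (days) to scan; must contain lag 0."""

    min_lag: int = -7
    max_lag: int = 7

    def __post_init__(self) -> None:
        if not self.min_lag <= 0 <= self.max_lag:
            raise ValidationError(
                f"lag window must satisfy min_lag <= 0 <= max_lag, got [{self.min_lag}, {self.max_lag}]"
            )

    def lags(self) -> range:
        return range(self.min_lag, self.max_lag + 1)


@dataclass(frozen=True)
class CCFResult:
    """Cross-correlation at one lag: estimate, SE, two-sided p, strength band."""

    lag: int
    ccf: float
    se: float
    p_two_sided: float
    n_pairs: int
    strength: str


def align_series(x: pd.Series, y: pd.Series, min_overlap: int = MIN_OVERLAP):
    """Restrict two daily series to their common dates, chronologically.

    A gap (absent date or NaN) in either series drops that date from both,
    so one n describes the pair. Returns ``(x_values, y_values, n)``.
    """
    if x.empty or y.empty:
        raise ValidationError("cannot align an empty series")
    xs = x.dropna()
    ys = y.dropna()
    common = pd.DatetimeIndex(xs.index).intersection(pd.DatetimeIndex(ys.index)).sort_values()
    n = len(common)
    if n < min_overlap:
        raise InsufficientOverlapError(
            f"insufficient overlap: {n} common dates (< {min_overlap})"
        )
    return (
        xs.reindex(common).to_numpy(dtype=float),
        ys.reindex(common).to_numpy(dtype=float),
        n,
    )


def ccf_standard_error(n: int, lag: int) -> float:
    """SE of the CCF estimate at a given lag: 1/sqrt(n - |lag|)."""
    m = n - abs(lag)
    if m < 2:
        raise ValidationError(f"n - |lag| = {m} < 2: standard error undefined")
    return 1.0 / math.sqrt(m)


def ccf_p_value(ccf: float, se: float) -> float:
    """Two-sided p for a CCF estimate under the normal approximation."""
    if se <= 0:
        raise ValidationError("standard error must be positive")
    return float(2.0 * stats.norm.sf(abs(ccf) / se))


def classify_strength(ccf: float) -> str:
    """Band a CCF value: nonpositive / weak (<0.5) / moderate (<0.8) / strong (<=1)."""
    if abs(ccf) > 1 + 1e-12:
        raise ValidationError(f"CCF out of range [-1, 1]: {ccf}")
    if ccf <= 0:
        return "nonpositive"
    if ccf < 0.5:
        return "weak"
    if ccf < 0.8:
        return "moderate"
    return "strong"


def cross_correlation(
    x: Sequence[float], y: Sequence[float], window: LagWindow = LagWindow()
) -> list[CCFResult]:
    """CCF of predictor x against outcome y at every lag in the window.

    Inputs must be equal-length, gap-free value sequences (use
    :func:`align_series` first) with nonzero variance. Returns one
    :class:`CCFResult` per lag, in increasing lag order.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.ndim != 1 or xv.shape != yv.shape:
        raise ValidationError("x and y must be 1-D sequences of equal length")
    n = len(xv)
    max_abs_lag = max(abs(window.min_lag), abs(window.max_lag))
    if n <= max_abs_lag + 2:
        raise ValidationError(
            f"series length {n} too short for lag window +/-{max_abs_lag}"
        )
    sx = float(xv.std())  # population SD (1/n)
    sy = float(yv.std())
    if sx == 0 or sy == 0:
        raise ValidationError("constant series: cross-correlation undefined")
    xc = xv - xv.mean()
    yc = yv - yv.mean()
    denom = n * sx * sy
    results = []
    for k in window.lags():
        if k >= 0:
            num = float(np.dot(xc[k:], yc[: n - k]))
        else:
            num = float(np.dot(xc[: n + k], yc[-k:]))
        ccf = num / denom
        se = ccf_standard_error(n, k)
        results.append(
            CCFResult(
                lag=k,
                ccf=ccf,
                se=se,
                p_two_sided=ccf_p_value(ccf, se),
                n_pairs=n - abs(k),
                strength=classify_strength(ccf),
            )
        )
    return results


def best_lag(results: Sequence[CCFResult], rule: str = "signed") -> CCFResult:
    """Select the headline lag from a CCF scan.

    ``rule="signed"`` (default) maximizes the signed CCF;
    ``rule="absolute"`` maximizes |CCF|. Ties break toward smaller |lag|,
    then toward the negative (predictor-leads) lag.
    """
    if not results:
        raise ValidationError("best_lag of an empty result list")
    if rule not in ("signed", "absolute"):
        raise ValidationError(f"unknown best-lag rule {rule!r}")
    key = (lambda r: (abs(r.ccf), -abs(r.lag), -r.lag)) if rule == "absolute" else (
        lambda r: (r.ccf, -abs(r.lag), -r.lag)
    )
    return max(results, key=key)
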