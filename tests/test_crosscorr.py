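"""Lagged cross-correlation: oracle equivalence, closed forms, SE/p, banding."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pollencorr.crosscorr import (
    CCFResult,
    LagWindow,
    align_series,
    best_lag,
    ccf_p_value,
    ccf_standard_error,
    classify_strength,
    cross_correlation,
)
from pollencorr.errors import InsufficientOverlapError, ValidationError
from conftest import daily_series


def ccf_oracle(x, y, k):
    """Brute-force double loop over the definitional estimator.

    Independent of the vectorized implementation: plain Python sums,
    full-series means and population SDs, truncated sum at lag k.
    """
    n = len(x)
    xm = sum(x) / n
    ym = sum(y) / n
    sx = math.sqrt(sum((v - xm) ** 2 for v in x) / n)
    sy = math.sqrt(sum((v - ym) ** 2 for v in y) / n)
    total = 0.0
    for t in range(n):
        if 0 <= t + k < n:
            total += (x[t + k] - xm) * (y[t] - ym)
    return total / (n * sx * sy)


def random_pair(rng, n=None):
    n = n or rng.integers(15, 51)
    return rng.uniform(0, 1, n), rng.uniform(0, 1, n)


class TestEstimator:
    def test_self_correlation_is_one_at_lag_zero(self):
        x = np.random.default_rng(0).uniform(0, 1, 40)
        results = {r.lag: r for r in cross_correlation(x, x)}
        assert results[0].ccf == pytest.approx(1.0, abs=1e-12)

    def test_antiphase_pair_is_minus_one(self):
        x = [1.0, 2.0, 1.0, 2.0] * 5
        y = [2.0, 1.0, 2.0, 1.0] * 5
        results = {r.lag: r for r in cross_correlation(x, y, LagWindow(-2, 2))}
        assert results[0].ccf == pytest.approx(-1.0, abs=1e-12)

    def test_shifted_copy_peaks_at_negative_lag(self):
        """y lags x by 1 day (x leads), so the best lag is -1."""
        rng = np.random.default_rng(3)
        base = rng.uniform(0, 1, 41)
        x, y = base[1:], base[:-1]  # y_t = x_{t-1}
        results = cross_correlation(x, y, LagWindow(-3, 3))
        expected = {k: ccf_oracle(list(x), list(y), k) for k in range(-3, 4)}
        assert best_lag(results).lag == -1
        for r in results:
            assert r.ccf == pytest.approx(expected[r.lag], abs=1e-10)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            x, y = random_pair(rng)
            for r in cross_correlation(x, y):
                assert r.ccf == pytest.approx(ccf_oracle(list(x), list(y), r.lag), abs=1e-10)

    def test_cross_symmetry(self):
        rng = np.random.default_rng(5)
        x, y = random_pair(rng, 30)
        fwd = {r.lag: r.ccf for r in cross_correlation(x, y)}
        rev = {r.lag: r.ccf for r in cross_correlation(y, x)}
        for k in fwd:
            assert fwd[k] == pytest.approx(rev[-k], abs=1e-12)

    @settings(derandomize=True, max_examples=100)
    @given(
        seed=st.integers(0, 2**31 - 1),
        a=st.floats(0.01, 100),
        b=st.floats(-50, 50),
        c=st.floats(0.01, 100),
        d=st.floats(-50, 50),
    )
    def test_bounded_and_affine_invariant(self, seed, a, b, c, d):
        x, y = random_pair(np.random.default_rng(seed), 25)
        base = cross_correlation(x, y)
        scaled = cross_correlation(a * x + b, c * y + d)
        for r0, r1 in zip(base, scaled):
            assert abs(r0.ccf) <= 1 + 1e-12
            assert r1.ccf == pytest.approx(r0.ccf, abs=1e-9)

    def test_constant_series_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            cross_correlation([1.0] * 20, list(range(20)))

    def test_window_exceeding_length_rejected(self):
        with pytest.raises(ValidationError, match="too short"):
            cross_correlation(list(range(8)), list(range(8)), LagWindow(-7, 7))


class TestStandardError:
    @pytest.mark.parametrize(
        "n, lag, expected",
        [(100, 0, 0.1), (80, 3, 1 / math.sqrt(77)), (80, -3, 1 / math.sqrt(77))],
    )
    def test_closed_form(self, n, lag, expected):
        assert ccf_standard_error(n, lag) == pytest.approx(expected, abs=1e-12)

    def test_grows_with_absolute_lag(self):
        ses = [ccf_standard_error(90, k) for k in range(0, 8)]
        assert all(a < b for a, b in zip(ses, ses[1:]))

    def test_undefined_below_two_pairs(self):
        with pytest.raises(ValidationError):
            ccf_standard_error(8, 7)


class TestPValue:
    def test_zero_ccf_gives_one(self):
        assert ccf_p_value(0.0, 0.1) == pytest.approx(1.0)

    def test_1_96_se_gives_about_05(self):
        assert ccf_p_value(1.96 * 0.107, 0.107) == pytest.approx(0.05, abs=1e-3)

    def test_reported_table_value_is_highly_significant(self):
        assert ccf_p_value(0.466, 0.107) < 0.001


class TestBestLag:
    def _res(self, lag, ccf):
        return CCFResult(lag=lag, ccf=ccf, se=0.1, p_two_sided=0.5, n_pairs=90, strength="weak")

    def test_picks_maximal_signed_ccf(self):
        assert best_lag([self._res(-1, 0.715), self._res(0, 0.640)]).lag == -1

    def test_tie_prefers_smaller_abs_lag(self):
        results = [self._res(k, 0.5) for k in (-1, 0, 1)]
        assert best_lag(results).lag == 0

    def test_tie_at_equal_abs_lag_prefers_negative(self):
        assert best_lag([self._res(-2, 0.5), self._res(2, 0.5)]).lag == -2

    def test_absolute_rule(self):
        results = [self._res(0, 0.4), self._res(2, -0.9)]
        assert best_lag(results, rule="absolute").lag == 2

    def test_empty_list_rejected(self):
        with pytest.raises(ValidationError):
            best_lag([])


@pytest.mark.parametrize(
    "ccf, band",
    [
        (0.715, "moderate"),
        (0.808, "strong"),
        (0.466, "weak"),
        (0.5 - 1e-9, "weak"),
        (0.5, "moderate"),
        (0.8 - 1e-9, "moderate"),
        (0.8, "strong"),
        (1.0, "strong"),
        (0.0, "nonpositive"),
        (-0.4, "nonpositive"),
    ],
)
def test_strength_bands(ccf, band):
    assert classify_strength(ccf) == band


def test_strength_out_of_range_rejected():
    with pytest.raises(ValidationError):
        classify_strength(1.2)


class TestAlign:
    def test_identical_dates_unchanged(self):
        x = daily_series(range(20))
        xv, yv, n = align_series(x, x * 2)
        assert n == 20
        np.testing.assert_array_equal(xv * 2, yv)

    def test_gaps_drop_dates_from_both(self):
        x = daily_series(range(92))
        y = daily_series(range(92)).drop(x.index[[3, 10, 20, 40, 80]])
        _, _, n = align_series(x, y)
        assert n == 87

    def test_nan_counts_as_gap(self):
        x = daily_series(range(20))
        y = x.copy()
        y.iloc[5] = np.nan
        assert align_series(x, y)[2] == 19

    def test_disjoint_dates_raise(self):
        x = daily_series(range(20), start="2009-05-01")
        y = daily_series(range(20), start="2010-05-01")
        with pytest.raises(InsufficientOverlapError, match="insufficient overlap"):
            align_series(x, y)
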