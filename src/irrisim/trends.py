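"""Trend statistics for annual irrigation series.

Implements the Mann-Kendall trend test with Kendall's tau-b as the
correlation coefficient (tie-corrected), plus an ordinary least squares
slope and coefficient of determination for the same series.  The
Mann-Kendall test is the standard non-parametric choice for monotonic
trends in annual environmental series; no seasonal variant is provided
because the series here are annual.

P-values: for n <= 10 without ties in the values the exact null
distribution of the Kendall S statistic is enumerated (via the
inversion-number generating polynomial); tied series up to n = 6 use
full permutation enumeration; everything else uses the normal
approximation with tie-corrected variance and a continuity correction
of 1.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = ["TrendResult", "kendall_tau_b", "ols_trend", "trend_summary"]

_EXACT_N_MAX = 10
_EXACT_TIES_N_MAX = 6


@dataclass(frozen=True)
class TrendResult:
    """Trend summary of one annual series."""

    tau_b: float | None = None
    p_value: float | None = None
    s_statistic: int | None = None
    ols_slope: float | None = None
    intercept: float | None = None
    r_squared: float | None = None
    n_years: int = 0


def _as_arrays(series: Mapping[int, float]) -> tuple[np.ndarray, np.ndarray]:
    years = np.array(sorted(series), dtype=float)
    values = np.array([series[int(y)] for y in years], dtype=float)
    return years, values


def _s_statistic(x: Sequence[float], y: Sequence[float]) -> int:
    """Kendall S = sum over pairs i<j of sign(x_j - x_i) * sign(y_j - y_i)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    iu = np.triu_indices(len(x), k=1)
    dx = np.sign(x[None, :] - x[:, None])[iu]
    dy = np.sign(y[None, :] - y[:, None])[iu]
    return int(np.sum(dx * dy))


def _tie_term(values: np.ndarray) -> int:
    """sum t*(t-1)/2 over tie groups."""
    return sum(t * (t - 1) // 2 for t in Counter(values.tolist()).values())


def _exact_p_no_ties(n: int, s: int) -> float:
    """Two-sided exact p for S with distinct x and distinct y.

    The number of permutations of n distinct values with k inversions is
    the coefficient of z^k in prod_{i=1..n} (1 + z + ... + z^(i-1));
    S = n(n-1)/2 - 2k.
    """
    counts = np.array([1], dtype=object)
    for i in range(2, n + 1):
        counts = np.convolve(counts, np.ones(i, dtype=object))
    total = math.factorial(n)
    smax = n * (n - 1) // 2
    # p = P(|S| >= |s|) ; S = smax - 2k  =>  k <= (smax - |s|)/2 for the
    # upper tail, symmetric distribution.
    k_hi = (smax - abs(s)) // 2
    upper = sum(counts[: k_hi + 1])
    p = 2.0 * float(upper) / total
    return min(p, 1.0)


def _exact_p_permutation(years: np.ndarray, values: np.ndarray, s_obs: int) -> float:
    """Two-sided p by full enumeration of value permutations (small n, ties)."""
    n = len(values)
    hits = 0
    total = 0
    for perm in itertools.permutations(values):
        total += 1
        if abs(_s_statistic(years, perm)) >= abs(s_obs):
            hits += 1
    return hits / total


def kendall_tau_b(series: Mapping[int, float]) -> TrendResult:
    """Kendall's tau-b of value against year, with the Mann-Kendall p-value.

    tau_b = S / sqrt((n0 - n1)(n0 - n2)) with n0 = n(n-1)/2 and n1, n2
    the tie terms of years and values.  All-identical values make tau
    undefined; the result then carries ``tau_b=None`` rather than zero.

    Raises
    ------
    ValueError
        If fewer than three years are supplied.
    """
    years, values = _as_arrays(series)
    n = len(values)
    if n < 3:
        raise ValueError(f"need at least 3 years, got {n}")
    if np.all(values == values[0]):
        return TrendResult(tau_b=None, p_value=None, s_statistic=0, n_years=n)

    s = _s_statistic(years, values)
    n0 = n * (n - 1) // 2
    n1 = _tie_term(years)
    n2 = _tie_term(values)
    tau = s / math.sqrt((n0 - n1) * (n0 - n2))

    has_ties = n1 > 0 or n2 > 0
    if n <= _EXACT_N_MAX and not has_ties:
        p = _exact_p_no_ties(n, s)
    elif n <= _EXACT_TIES_N_MAX:
        p = _exact_p_permutation(years, values, s)
    else:
        var_s = n * (n - 1) * (2 * n + 5) / 18.0
        for t in Counter(values.tolist()).values():
            var_s -= t * (t - 1) * (2 * t + 5) / 18.0
        for t in Counter(years.tolist()).values():
            var_s -= t * (t - 1) * (2 * t + 5) / 18.0
        if var_s <= 0:
            p = 1.0
        else:
            # continuity correction of 1 toward zero
            z = (s - np.sign(s)) / math.sqrt(var_s) if s != 0 else 0.0
            p = 2.0 * stats.norm.sf(abs(z))
    return TrendResult(tau_b=tau, p_value=min(p, 1.0), s_statistic=s, n_years=n)


def ols_trend(series: Mapping[int, float]) -> TrendResult:
    """Least-squares slope (units per year) and R^2 of value on year.

    A constant series reports slope 0 and R^2 = 0 (no explained
    variance) rather than NaN.
    """
    years, values = _as_arrays(series)
    n = len(values)
    if n < 3:
        raise ValueError(f"need at least 3 years, got {n}")
    if np.ptp(years) == 0:
        raise ValueError("zero variance in years")
    if np.ptp(values) == 0:
        return TrendResult(ols_slope=0.0, intercept=float(values[0]),
                           r_squared=0.0, n_years=n)
    res = stats.linregress(years, values)
    return TrendResult(
        ols_slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_years=n,
    )


def trend_summary(series: Mapping[int, float]) -> TrendResult:
    """Combined Mann-Kendall and OLS summary of one annual series."""
    mk = kendall_tau_b(series)
    ols = ols_trend(series)
    return TrendResult(
        tau_b=mk.tau_b,
        p_value=mk.p_value,
        s_statistic=mk.s_statistic,
        ols_slope=ols.ols_slope,
        intercept=ols.intercept,
        r_squared=ols.r_squared,
        n_years=mk.n_years,
    )
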