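"""Kendall tau-b / Mann-Kendall and OLS trend summaries."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from irrisim import kendall_tau_b, ols_trend, trend_summary


def tau_b_pair_counting(x, y):
    """Exhaustive concordant/discordant pair counting with tie correction."""
    n = len(x)
    s = 0
    for i, j in itertools.combinations(range(n), 2):
        s += np.sign(x[j] - x[i]) * np.sign(y[j] - y[i])
    n0 = n * (n - 1) / 2
    ties = lambda v: sum(
        c * (c - 1) / 2 for c in np.unique(v, return_counts=True)[1])
    denom = math.sqrt((n0 - ties(x)) * (n0 - ties(y)))
    return s / denom if denom > 0 else None


class TestKendall:
    def test_strictly_increasing_is_plus_one(self):
        res = kendall_tau_b({2000 + i: float(i) for i in range(8)})
        assert res.tau_b == pytest.approx(1.0)
        assert res.p_value < 0.01

    def test_strictly_decreasing_is_minus_one(self):
        res = kendall_tau_b({2000 + i: -2.0 * i for i in range(8)})
        assert res.tau_b == pytest.approx(-1.0)

    def test_tied_example_matches_pair_counting(self):
        values = [1.0, 2.0, 2.0, 3.0, 1.0]
        res = kendall_tau_b(dict(zip(range(2001, 2006), values)))
        years = np.arange(5, dtype=float)
        assert res.tau_b == pytest.approx(tau_b_pair_counting(years,
                                                              np.array(values)))

    def test_all_short_series_match_pair_counting_and_scipy(self):
        """Every series of length <= 6 over values {0,1,2}: tau-b equals the
        exhaustive pair-count oracle and scipy's tau-b."""
        for n in (3, 4, 5, 6):
            years = np.arange(n, dtype=float)
            for vals in itertools.product((0.0, 1.0, 2.0), repeat=n):
                v = np.array(vals)
                res = kendall_tau_b(dict(zip(range(2000, 2000 + n), vals)))
                expect = tau_b_pair_counting(years, v)
                if np.ptp(v) == 0:
                    assert res.tau_b is None
                else:
                    assert res.tau_b == pytest.approx(expect)
                    sp = stats.kendalltau(years, v).statistic
                    assert res.tau_b == pytest.approx(sp)

    def test_exact_p_matches_scipy_exact_for_untied_series(self):
        rng = np.random.default_rng(3)
        for n in (4, 6, 8, 10):
            for _ in range(5):
                vals = rng.permutation(n).astype(float)
                res = kendall_tau_b(dict(zip(range(2000, 2000 + n), vals)))
                sp = stats.kendalltau(np.arange(n), vals, method="exact")
                assert res.p_value == pytest.approx(sp.pvalue, abs=1e-12)

    def test_constant_series_reports_undefined_tau(self):
        res = kendall_tau_b({y: 5.0 for y in range(2000, 2010)})
        assert res.tau_b is None and res.p_value is None

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            kendall_tau_b({2000: 1.0, 2001: 2.0})

    @given(st.lists(st.integers(-20, 20), min_size=4, max_size=12))
    @settings(max_examples=150, derandomize=True, deadline=None)
    def test_antisymmetry_and_monotone_invariance(self, vals):
        series = {2000 + i: float(v) for i, v in enumerate(vals)}
        res = kendall_tau_b(series)
        neg = kendall_tau_b({y: -v for y, v in series.items()})
        cube = kendall_tau_b({y: v**3 + 2.0 for y, v in series.items()})
        if res.tau_b is None:
            assert neg.tau_b is None and cube.tau_b is None
        else:
            assert neg.tau_b == pytest.approx(-res.tau_b)
            assert cube.tau_b == pytest.approx(res.tau_b)


class TestOls:
    def test_exact_line(self):
        series = {y: 3.0 * y + 7.0 for y in range(2000, 2010)}
        res = ols_trend(series)
        assert res.ols_slope == pytest.approx(3.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_constant_series_has_zero_slope_and_zero_r2(self):
        res = ols_trend({y: 4.2 for y in range(2000, 2008)})
        assert res.ols_slope == 0.0
        assert res.r_squared == 0.0

    def test_noisy_line_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(11)
        years = np.arange(1991.0, 2021.0)
        vals = 1.3 * years - 2500.0 + rng.normal(0, 8, size=len(years))
        res = ols_trend(dict(zip(years.astype(int), vals)))
        # closed-form normal equations
        xc = years - years.mean()
        slope = (xc * (vals - vals.mean())).sum() / (xc**2).sum()
        fitted = vals.mean() + slope * xc
        r2 = 1.0 - ((vals - fitted) ** 2).sum() / ((vals - vals.mean()) ** 2).sum()
        assert res.ols_slope == pytest.approx(slope, abs=1e-10)
        assert res.r_squared == pytest.approx(r2, abs=1e-10)

    def test_combined_summary_carries_both_parts(self):
        series = {2000 + i: float(i) + (0.5 if i % 2 else 0.0) for i in range(12)}
        res = trend_summary(series)
        assert res.tau_b is not None and res.ols_slope is not None
        assert 0.0 <= res.r_squared <= 1.0
        assert abs(res.tau_b) <= 1.0
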