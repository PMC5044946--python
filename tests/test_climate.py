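"""Synthetic climate generator, CSV round-trips and quantile-year picks."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from irrisim import (
    ClimateSeries,
    ScenarioConfig,
    generate_daily_weather,
    read_climate_csv,
    scenario_config,
    select_quantile_years,
    write_climate_csv,
)


class TestGenerator:
    def test_seed_determinism(self):
        cfg = scenario_config("Tmed", 2000, 2009, seed=42)
        a = generate_daily_weather(cfg)
        b = generate_daily_weather(cfg)
        assert a == b

    def test_different_seeds_differ(self):
        a = generate_daily_weather(ScenarioConfig(2000, 2004, seed=1))
        b = generate_daily_weather(ScenarioConfig(2000, 2004, seed=2))
        assert a != b

    def test_degenerate_config_repeats_the_climatology(self):
        """Zero noise, zero trends, uniform precipitation: every year is the
        deterministic seasonal climatology (compared on shared DOYs)."""
        cfg = ScenarioConfig(2001, 2005, seed=9, precip_mode="uniform",
                             temp_noise_sd=0.0, temp_annual_sd=0.0,
                             et0_noise_sd=0.0)
        s = generate_daily_weather(cfg)
        ref = s.year_frame(2001).set_index("doy")[["tmean_c", "precip_mm", "et0_mm"]]
        for year in (2002, 2003, 2004, 2005):
            cur = s.year_frame(year).set_index("doy")[ref.columns]
            joined = ref.join(cur, lsuffix="_a", rsuffix="_b", how="inner")
            for col in ("tmean_c", "precip_mm", "et0_mm"):
                np.testing.assert_allclose(joined[f"{col}_a"], joined[f"{col}_b"])

    def test_temperature_trend_recovery_by_ols(self):
        """OLS on annual mean temperature recovers the +1.7 C ramp over 60
        years to within 0.3 C, averaged over 20 seeds."""
        slopes = []
        for seed in range(20):
            cfg = scenario_config("Tmax", 2011, 2070, seed=seed)
            s = generate_daily_weather(cfg)
            ann = s.data.groupby("year")["tmean_c"].mean()
            res = stats.linregress(ann.index.to_numpy(float), ann.to_numpy())
            slopes.append(res.slope * (cfg.n_years - 1))
        assert np.mean(slopes) == pytest.approx(1.7, abs=0.3)

    def test_annual_precip_matches_configured_mean(self):
        """Seed-averaged annual precipitation within 5% of the config mean."""
        totals = []
        for seed in range(20):
            cfg = ScenarioConfig(2000, 2004, seed=seed)
            totals.append(generate_daily_weather(cfg).annual_precip().mean())
        assert np.mean(totals) == pytest.approx(654.4, rel=0.05)

    def test_et0_nonnegative_and_seasonal(self):
        s = generate_daily_weather(ScenarioConfig(2000, 2009, seed=5))
        df = s.data
        assert (df["et0_mm"] >= 0).all()
        month = df["date"].dt.month
        jja = df.loc[month.isin([6, 7, 8]), "et0_mm"].mean()
        djf = df.loc[month.isin([12, 1, 2]), "et0_mm"].mean()
        assert jja > djf

    def test_drivers_mode_is_consistent_with_penman_monteith(self):
        from irrisim.climate import compute_reference_et0

        s = generate_daily_weather(ScenarioConfig(2003, 2003, seed=4,
                                                  et0_mode="drivers"))
        day = s.day(2003, 180)
        assert day.et0 == pytest.approx(compute_reference_et0(day))

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError, match="year range"):
            ScenarioConfig(2010, 2005, seed=1)
        with pytest.raises(ValueError, match="positive"):
            ScenarioConfig(2000, 2001, seed=1, annual_precip_mean=-5.0)
        with pytest.raises(ValueError, match="unknown preset"):
            scenario_config("Tmegamax", 2000, 2001, seed=1)


class TestClimateCsv:
    def test_round_trip_identity(self, tmp_path):
        s = generate_daily_weather(ScenarioConfig(2000, 2001, seed=3))
        path = tmp_path / "climate.csv"
        write_climate_csv(s, path)
        assert read_climate_csv(path) == s

    def test_round_trip_with_driver_columns(self, tmp_path):
        s = generate_daily_weather(ScenarioConfig(2002, 2002, seed=3,
                                                  et0_mode="drivers"))
        path = tmp_path / "climate.csv"
        write_climate_csv(s, path)
        back = read_climate_csv(path)
        assert "rn_mj" in back.data.columns
        assert back == s

    def test_missing_day_names_the_gap(self, tmp_path):
        s = generate_daily_weather(ScenarioConfig(2001, 2001, seed=1))
        df = s.data[["date", "tmean_c", "precip_mm", "et0_mm"]].copy()
        df = df[df["date"] != "2001-03-05"]
        path = tmp_path / "gap.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="2001-03-05"):
            read_climate_csv(path)

    def test_negative_precip_rejected_with_row(self, tmp_path):
        s = generate_daily_weather(ScenarioConfig(2001, 2001, seed=1))
        df = s.data[["date", "tmean_c", "precip_mm", "et0_mm"]].copy()
        df.loc[9, "precip_mm"] = -1.0
        path = tmp_path / "neg.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="row 11"):
            read_climate_csv(path)

    def test_duplicated_date_rejected(self, tmp_path):
        s = generate_daily_weather(ScenarioConfig(2001, 2001, seed=1))
        df = s.data[["date", "tmean_c", "precip_mm", "et0_mm"]].copy()
        df = pd.concat([df.iloc[:10], df.iloc[9:]], ignore_index=True)
        path = tmp_path / "dup.csv"
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="duplicated date"):
            read_climate_csv(path)


class TestQuantileYears:
    @staticmethod
    def _series_with_totals(build, totals):
        """Uniform daily precip per year so annual totals hit the targets."""
        years = list(range(2000, 2000 + len(totals)))
        frames = []
        for y, tot in zip(years, totals):
            dates = pd.date_range(f"{y}-01-01", f"{y}-12-31", freq="D")
            frames.append(pd.DataFrame({
                "date": dates,
                "tmean_c": 10.0,
                "precip_mm": tot / len(dates),
                "et0_mm": 1.0,
            }))
        return ClimateSeries(pd.concat(frames, ignore_index=True))

    def test_matches_sort_and_interpolate_oracle(self, build_climate):
        totals = [100.0 * k for k in range(1, 11)]
        s = self._series_with_totals(build_climate, totals)
        got = select_quantile_years(s, {0.1, 0.5, 0.9})
        actual = s.annual_precip()
        for p, year in got.items():
            q = np.quantile(np.sort(actual.to_numpy()), p)  # independent oracle
            best = (actual - q).abs()
            expect = best[best == best.min()].index.min()
            assert year == expect

    def test_identical_totals_tie_break_earliest(self, build_climate):
        s = self._series_with_totals(build_climate, [500.0] * 6)
        got = select_quantile_years(s, {0.1, 0.5, 0.9})
        assert set(got.values()) == {2000}

    def test_three_probs_three_keys(self, build_climate):
        s = self._series_with_totals(build_climate, [400.0, 600.0, 800.0])
        got = select_quantile_years(s, {0.1, 0.5, 0.9})
        assert len(got) == 3

    def test_probability_out_of_range(self, build_climate):
        s = self._series_with_totals(build_climate, [400.0, 600.0])
        with pytest.raises(ValueError, match="outside"):
            select_quantile_years(s, {1.5})
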