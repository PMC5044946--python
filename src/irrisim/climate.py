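"""Synthetic daily climate series and the series container.

The generator emulates the driving data of a regional irrigation study:
multi-decade daily series of mean temperature, precipitation and FAO-56
reference evapotranspiration for a single grid cell, with configurable
linear trends that mimic regional climate-scenario runs of a
high-emission pathway (presets ``Tmin``/``Tmed``/``Tmax``) alongside a
trend-free ``observation`` preset.

Structure of the generator:

* temperature: a sinusoidal seasonal cycle plus a linear warming ramp,
  an interannual anomaly and daily noise;
* precipitation: a first-order two-state Markov occurrence chain with
  gamma-distributed wet-day amounts, calibrated so the expected annual
  total equals the configured mean; a deterministic "uniform" mode
  spreads the annual mean evenly over the year;
* reference evapotranspiration: either a direct seasonal cycle with
  trend and noise ("direct" mode, the default), or synthetic radiation /
  wind / humidity drivers passed through the Penman-Monteith equation
  ("drivers" mode).

All randomness flows from a single integer seed; identical configs give
bit-identical series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .et0 import penman_monteith_et0, svp_slope

__all__ = [
    "DailyWeather",
    "ClimateSeries",
    "ScenarioConfig",
    "SCENARIO_PRESETS",
    "scenario_config",
    "generate_daily_weather",
    "compute_reference_et0",
    "read_climate_csv",
    "write_climate_csv",
    "select_quantile_years",
]

#: Required CSV / frame columns.
CORE_COLUMNS = ["date", "tmean_c", "precip_mm", "et0_mm"]
#: Optional raw-driver columns for the Penman-Monteith pathway.
DRIVER_COLUMNS = ["rn_mj", "g_mj", "u2_ms", "es_kpa", "ea_kpa"]

_SEASON_PERIOD = 365.25
_SEASON_PEAK_DOY = 200.0  # mid/late July peak for temperature and ET0


@dataclass(frozen=True)
class DailyWeather:
    """One day of driving weather, optionally with raw ET0 drivers."""

    date: pd.Timestamp
    doy: int
    tmean: float
    precip: float
    et0: float
    net_radiation: float | None = None
    soil_heat_flux: float | None = None
    wind_2m: float | None = None
    vapour_pressure_sat: float | None = None
    vapour_pressure_act: float | None = None

    def __post_init__(self) -> None:
        if self.precip < 0:
            raise ValueError(f"negative precipitation {self.precip}")
        if self.et0 < 0:
            raise ValueError(f"negative et0 {self.et0}")
        if (
            self.vapour_pressure_act is not None
            and self.vapour_pressure_sat is not None
            and self.vapour_pressure_act > self.vapour_pressure_sat + 1e-12
        ):
            raise ValueError("actual vapour pressure exceeds saturation")


class ClimateSeries:
    """A gap-free daily weather series spanning whole calendar years.

    Thin wrapper around a :class:`pandas.DataFrame` with columns
    ``date, tmean_c, precip_mm, et0_mm`` (plus optional driver columns)
    and a scenario label.  Validation enforces strictly increasing
    dates without gaps, complete calendar years and non-negative water
    fluxes.
    """

    def __init__(self, data: pd.DataFrame, scenario_label: str = "custom") -> None:
        df = data.copy()
        missing = [c for c in CORE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        df["date"] = pd.to_datetime(df["date"])
        df = df.reset_index(drop=True)
        self._validate(df)
        df["year"] = df["date"].dt.year
        df["doy"] = df["date"].dt.dayofyear
        self.data = df
        self.scenario_label = scenario_label

    @staticmethod
    def _validate(df: pd.DataFrame) -> None:
        if len(df) == 0:
            raise ValueError("empty climate series")
        dates = df["date"]
        deltas = dates.diff().dropna()
        if (deltas <= pd.Timedelta(0)).any():
            bad = dates[deltas.index[deltas <= pd.Timedelta(0)]].iloc[0]
            raise ValueError(f"dates not strictly increasing at {bad.date()}")
        gaps = deltas[deltas > pd.Timedelta(days=1)]
        if len(gaps) > 0:
            i = gaps.index[0]
            raise ValueError(
                f"gap in dates: missing day(s) after {dates.iloc[i - 1].date()}"
            )
        first, last = dates.iloc[0], dates.iloc[-1]
        if not (first.month == 1 and first.day == 1):
            raise ValueError(f"series must start on 1 January, got {first.date()}")
        if not (last.month == 12 and last.day == 31):
            raise ValueError(f"series must end on 31 December, got {last.date()}")
        for col in ("precip_mm", "et0_mm"):
            neg = df.index[df[col] < 0]
            if len(neg) > 0:
                raise ValueError(f"negative {col} at row {int(neg[0])}")

    @property
    def years(self) -> list[int]:
        return sorted(self.data["year"].unique().tolist())

    def annual_precip(self) -> pd.Series:
        """Annual precipitation totals (mm/yr) indexed by year."""
        return self.data.groupby("year")["precip_mm"].sum()

    def year_frame(self, year: int) -> pd.DataFrame:
        sub = self.data[self.data["year"] == year]
        if len(sub) == 0:
            raise KeyError(f"year {year} not covered by the climate series")
        return sub

    def day(self, year: int, doy: int) -> DailyWeather:
        """Return one day as a :class:`DailyWeather` record."""
        sub = self.data[(self.data["year"] == year) & (self.data["doy"] == doy)]
        if len(sub) == 0:
            raise KeyError(f"no climate day for year {year}, doy {doy}")
        row = sub.iloc[0]
        return DailyWeather(
            date=row["date"],
            doy=int(row["doy"]),
            tmean=float(row["tmean_c"]),
            precip=float(row["precip_mm"]),
            et0=float(row["et0_mm"]),
            net_radiation=float(row["rn_mj"]) if "rn_mj" in row else None,
            soil_heat_flux=float(row["g_mj"]) if "g_mj" in row else None,
            wind_2m=float(row["u2_ms"]) if "u2_ms" in row else None,
            vapour_pressure_sat=float(row["es_kpa"]) if "es_kpa" in row else None,
            vapour_pressure_act=float(row["ea_kpa"]) if "ea_kpa" in row else None,
        )

    def __len__(self) -> int:
        return len(self.data)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ClimateSeries):
            return NotImplemented
        cols = [c for c in CORE_COLUMNS + DRIVER_COLUMNS if c in self.data.columns]
        ocols = [c for c in CORE_COLUMNS + DRIVER_COLUMNS if c in other.data.columns]
        if cols != ocols:
            return False
        return self.data[cols].equals(other.data[cols])


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of the synthetic climate generator.

    Trends are expressed as the change reached at the end of the period
    (a linear ramp from zero): ``temp_trend`` in degC, ``et_trend`` and
    ``precip_delta`` in mm/yr of the respective annual totals.
    """

    start_year: int
    end_year: int
    seed: int
    annual_precip_mean: float = 654.4
    temp_baseline: float = 8.7
    temp_seasonal_amplitude: float = 8.5
    temp_trend: float = 0.0
    et_trend: float = 0.0
    precip_delta: float = 0.0
    annual_et0_mean: float = 600.0
    et0_seasonal_amplitude_frac: float = 0.93
    wet_day_prob: float = 0.32
    wet_wet_persistence: float = 0.55
    amount_shape: float = 0.75
    temp_noise_sd: float = 3.0
    temp_annual_sd: float = 0.4
    et0_noise_sd: float = 0.45
    precip_mode: str = "markov"
    et0_mode: str = "direct"
    scenario_label: str = "custom"

    def __post_init__(self) -> None:
        if self.end_year < self.start_year:
            raise ValueError("empty year range")
        if self.annual_precip_mean <= 0:
            raise ValueError("annual_precip_mean must be positive")
        for name in ("wet_day_prob", "wet_wet_persistence"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name}={p} outside [0, 1]")
        if self.precip_mode not in ("markov", "uniform"):
            raise ValueError(f"unknown precip_mode {self.precip_mode!r}")
        if self.et0_mode not in ("direct", "drivers"):
            raise ValueError(f"unknown et0_mode {self.et0_mode!r}")

    @property
    def n_years(self) -> int:
        return self.end_year - self.start_year + 1


#: Scenario presets: (temp_trend degC, et_trend mm/yr, precip_delta mm/yr)
#: reached at the end of the period, mirroring the contrast between a
#: low, median and high warming run of a high-emission pathway.
SCENARIO_PRESETS: Mapping[str, tuple[float, float, float]] = {
    "observation": (0.0, 0.0, 0.0),
    "Tmin": (0.9, -8.7, 44.7),
    "Tmed": (1.3, 5.6, 45.0),
    "Tmax": (1.7, 28.4, 14.1),
}


def scenario_config(
    preset: str,
    start_year: int,
    end_year: int,
    seed: int,
    **overrides: object,
) -> ScenarioConfig:
    """Build a :class:`ScenarioConfig` from a named preset."""
    if preset not in SCENARIO_PRESETS:
        raise ValueError(
            f"unknown preset {preset!r}; expected one of {sorted(SCENARIO_PRESETS)}"
        )
    temp_trend, et_trend, precip_delta = SCENARIO_PRESETS[preset]
    kwargs: dict = dict(
        start_year=start_year,
        end_year=end_year,
        seed=seed,
        temp_trend=temp_trend,
        et_trend=et_trend,
        precip_delta=precip_delta,
        scenario_label=preset,
    )
    kwargs.update(overrides)
    return ScenarioConfig(**kwargs)


def _seasonal_wave(doy: np.ndarray) -> np.ndarray:
    """Cosine seasonal cycle in [-1, 1], peaking in mid summer."""
    return np.cos(2.0 * np.pi * (doy - _SEASON_PEAK_DOY) / _SEASON_PERIOD)


def generate_daily_weather(config: ScenarioConfig) -> ClimateSeries:
    """Generate a complete multi-year daily weather series.

    The expected annual precipitation equals ``config.annual_precip_mean``
    (ramping to ``+ precip_delta`` at the period end), temperature and
    ET0 follow seasonal cycles plus their configured linear trends, and
    the whole series is reproducible from the seed.
    """
    rng = np.random.default_rng(config.seed)
    dates = pd.date_range(
        f"{config.start_year}-01-01", f"{config.end_year}-12-31", freq="D"
    )
    n = len(dates)
    doy = dates.dayofyear.to_numpy(dtype=float)
    years = dates.year.to_numpy()
    if config.n_years > 1:
        year_frac = (years - config.start_year) / (config.n_years - 1)
    else:
        year_frac = np.zeros(n)

    wave = _seasonal_wave(doy)

    # --- temperature -----------------------------------------------------
    annual_anom = rng.normal(0.0, config.temp_annual_sd, size=config.n_years)
    tmean = (
        config.temp_baseline
        + config.temp_seasonal_amplitude * wave
        + config.temp_trend * year_frac
        + annual_anom[years - config.start_year]
        + rng.normal(0.0, config.temp_noise_sd, size=n)
    )

    # --- precipitation ---------------------------------------------------
    daily_mean = config.annual_precip_mean / _SEASON_PERIOD
    precip_scale = 1.0 + config.precip_delta * year_frac / config.annual_precip_mean
    if config.precip_mode == "uniform":
        precip = np.full(n, daily_mean) * precip_scale
    else:
        p01 = config.wet_day_prob
        p11 = config.wet_wet_persistence
        # stationary wet-day probability of the two-state chain
        denom = 1.0 + p01 - p11
        pi_wet = p01 / denom if denom > 0 else 1.0
        u = rng.random(n)
        wet = np.empty(n, dtype=bool)
        state = u[0] < pi_wet
        wet[0] = state
        for i in range(1, n):
            state = u[i] < (p11 if state else p01)
            wet[i] = state
        mean_amount = daily_mean / pi_wet if pi_wet > 0 else 0.0
        shape = config.amount_shape
        amounts = rng.gamma(shape, mean_amount / shape, size=n)
        precip = np.where(wet, amounts, 0.0) * precip_scale
    precip = np.maximum(precip, 0.0)

    # --- reference evapotranspiration ------------------------------------
    et_scale = 1.0 + config.et_trend * year_frac / config.annual_et0_mean
    if config.et0_mode == "direct":
        et0_daily_mean = config.annual_et0_mean / _SEASON_PERIOD
        et0_season = et0_daily_mean * (
            1.0 + config.et0_seasonal_amplitude_frac * wave
        )
        et0 = et0_season * et_scale + rng.normal(0.0, config.et0_noise_sd, size=n)
        et0 = np.maximum(et0, 0.0)
        frame = pd.DataFrame(
            {"date": dates, "tmean_c": tmean, "precip_mm": precip, "et0_mm": et0}
        )
    else:
        rn, g, u2, es, ea = _synthetic_drivers(rng, tmean, wave, precip, et_scale)
        et0 = np.array(
            [
                penman_monteith_et0(t, r, gg, w, s, a)
                for t, r, gg, w, s, a in zip(tmean, rn, g, u2, es, ea)
            ]
        )
        frame = pd.DataFrame(
            {
                "date": dates,
                "tmean_c": tmean,
                "precip_mm": precip,
                "et0_mm": et0,
                "rn_mj": rn,
                "g_mj": g,
                "u2_ms": u2,
                "es_kpa": es,
                "ea_kpa": ea,
            }
        )
    return ClimateSeries(frame, scenario_label=config.scenario_label)


def _synthetic_drivers(
    rng: np.random.Generator,
    tmean: np.ndarray,
    wave: np.ndarray,
    precip: np.ndarray,
    et_scale: np.ndarray,
) -> tuple[np.ndarray, ...]:
    """Plausible daily radiation / wind / humidity drivers for mid-latitudes.

    Net radiation follows the seasonal cycle (scaled by the ET trend so
    scenario contrasts propagate through the Penman-Monteith pathway),
    reduced on wet (cloudy) days; wind is lognormal around 2 m/s;
    saturation vapour pressure derives from temperature and actual
    vapour pressure from a relative humidity that is higher on wet days.
    """
    n = len(tmean)
    wet = precip > 0
    rn = (7.0 + 6.5 * wave) * et_scale
    rn = rn * np.where(wet, 0.75, 1.0) + rng.normal(0.0, 0.8, size=n)
    rn = np.clip(rn, -1.0, None)
    g = np.zeros(n)  # negligible at the daily time step
    u2 = np.exp(rng.normal(np.log(2.0), 0.3, size=n))
    es = 0.6108 * np.exp(17.27 * tmean / (tmean + 237.3))
    rh = np.clip(np.where(wet, 0.85, 0.68) + rng.normal(0.0, 0.05, size=n), 0.3, 1.0)
    ea = rh * es
    return rn, g, u2, es, ea


def compute_reference_et0(day: DailyWeather) -> float:
    """FAO-56 Penman-Monteith ET0 (mm/day) from a day's raw drivers.

    Raises :class:`ValueError` when any driver is absent.
    """
    return penman_monteith_et0(
        tmean_c=day.tmean,
        net_radiation_mj=day.net_radiation,
        soil_heat_flux_mj=day.soil_heat_flux,
        wind_2m_ms=day.wind_2m,
        vp_sat_kpa=day.vapour_pressure_sat,
        vp_act_kpa=day.vapour_pressure_act,
    )


def write_climate_csv(series: ClimateSeries, path) -> None:
    """Write the series to CSV (ISO dates, decimal point)."""
    cols = [c for c in CORE_COLUMNS + DRIVER_COLUMNS if c in series.data.columns]
    out = series.data[cols].copy()
    out["date"] = out["date"].dt.strftime("%Y-%m-%d")
    # %.17g round-trips IEEE doubles exactly
    out.to_csv(path, index=False, float_format="%.17g")


def read_climate_csv(path, scenario_label: str = "custom") -> ClimateSeries:
    """Read a daily climate CSV, rejecting malformed rows with their row number.

    Expects columns ``date,tmean_c,precip_mm,et0_mm``; the row number in
    error messages is 1-based counting the header as row 1.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in CORE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in CORE_COLUMNS[1:]:
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad) > 0:
            raise ValueError(f"{path}: non-numeric {col} at data row {int(bad[0]) + 2}")
        df[col] = pd.to_numeric(df[col])
    for col in ("precip_mm", "et0_mm"):
        neg = df.index[df[col] < 0]
        if len(neg) > 0:
            raise ValueError(f"{path}: negative {col} at data row {int(neg[0]) + 2}")
    for col in DRIVER_COLUMNS:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col]).astype(float)
    dates = pd.to_datetime(df["date"], errors="coerce")
    bad = df.index[dates.isna()]
    if len(bad) > 0:
        raise ValueError(f"{path}: unparseable date at data row {int(bad[0]) + 2}")
    dup = dates[dates.duplicated()]
    if len(dup) > 0:
        raise ValueError(f"{path}: duplicated date {dup.iloc[0].date()}")
    deltas = dates.diff().dropna()
    gaps = deltas[deltas > pd.Timedelta(days=1)]
    if len(gaps) > 0:
        i = gaps.index[0]
        missing_day = (dates.iloc[i - 1] + pd.Timedelta(days=1)).date()
        raise ValueError(f"{path}: gap in dates, missing {missing_day}")
    df["date"] = dates
    return ClimateSeries(df, scenario_label=scenario_label)


def select_quantile_years(
    series: ClimateSeries, probs: Iterable[float]
) -> dict[float, int]:
    """Map each probability to the year whose annual rainfall is nearest
    that empirical quantile of the annual-rainfall distribution.

    Ties break to the earliest year.  Used to pick representative wet /
    average / dry years (e.g. probabilities 0.9, 0.5, 0.1).
    """
    totals = series.annual_precip()
    if len(totals) < 2:
        raise ValueError("need at least two complete years")
    out: dict[float, int] = {}
    for p in probs:
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"probability {p} outside [0, 1]")
        q = float(np.quantile(totals.to_numpy(), p))
        dist = (totals - q).abs()
        best = dist[dist == dist.min()].index.min()
        out[float(p)] = int(best)
    return out
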