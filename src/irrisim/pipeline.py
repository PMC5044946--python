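"""Season and multi-year simulation, annual accounting and the cap check.

A season is simulated independently per year: the bucket is
re-initialised at the common window start (no carry-over of soil water
between years, since one start day and start value are applied to every
year, scenario and crop), the daily update runs through the last day
before maturation, and events are recorded.  Annual totals for a crop
rotation are then aggregated into a trailing moving average and
compared against the regulatory groundwater cap (strictly greater than
the cap counts as exceedance; the cap itself is permitted).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .climate import ClimateSeries
from .crops import (
    DEFAULT_CROPS,
    CropSpec,
    IrrigationWindow,
    RotationPlan,
    irrigation_window,
    rotation_crop_for_year,
)
from .soil import (
    IrrigationPolicy,
    SoilWaterState,
    StorageParams,
    daily_update,
)

__all__ = [
    "SeasonResult",
    "AnnualSeries",
    "WindowStart",
    "simulate_season",
    "annual_irrigation_series",
    "moving_average",
    "cap_exceedance",
    "determine_window_start",
]


@dataclass(frozen=True)
class SeasonResult:
    """Daily trace and irrigation bookkeeping of one crop season."""

    year: int
    crop: str
    window: IrrigationWindow
    doys: tuple[int, ...]
    swc_trace: tuple[float, ...]
    event_doys: tuple[int, ...]

    @property
    def n_events(self) -> int:
        return len(self.event_doys)

    def total_irrigation_mm(self, policy: IrrigationPolicy) -> float:
        return self.n_events * policy.event_amount_mm

    def to_frame(self) -> pd.DataFrame:
        events = set(self.event_doys)
        return pd.DataFrame(
            {
                "doy": self.doys,
                "swc_l_per_m3": self.swc_trace,
                "event": [d in events for d in self.doys],
            }
        )


def simulate_season(
    climate: ClimateSeries,
    year: int,
    crop: str,
    storages: StorageParams,
    policy: IrrigationPolicy,
    window: Optional[IrrigationWindow] = None,
    table: Mapping[str, CropSpec] = DEFAULT_CROPS,
) -> SeasonResult:
    """Simulate one irrigation season for ``crop`` in ``year``.

    The state starts at the window's start day and start value; the
    daily update is applied for every day from ``start_doy`` through
    ``end_doy - 1`` with irrigation allowed.  The returned trace holds
    the content *after* each day's update (the first trace entry is the
    start value itself, indexed at the start day).
    """
    if window is None:
        window = irrigation_window(crop, table)
    yf = climate.year_frame(year)
    doys_present = set(yf["doy"].tolist())
    needed = range(window.start_doy, window.end_doy)
    missing = [d for d in needed if d not in doys_present]
    if missing:
        raise ValueError(
            f"climate for year {year} missing day(s) {missing[:3]} in the window"
        )
    sub = yf[(yf["doy"] >= window.start_doy) & (yf["doy"] < window.end_doy)]
    precip = sub["precip_mm"].to_numpy()
    et0 = sub["et0_mm"].to_numpy()

    state = SoilWaterState(doy=window.start_doy, swc_l_per_m3=window.start_swc_l_per_m3)
    doys = [window.start_doy]
    trace = [window.start_swc_l_per_m3]
    events: list[int] = []
    for i, d in enumerate(range(window.start_doy, window.end_doy)):
        state, event = daily_update(
            state, precip[i], et0[i], storages, policy, irrigation_allowed=True
        )
        doys.append(d + 1)
        trace.append(state.swc_l_per_m3)
        if event is not None:
            events.append(event.doy)
    return SeasonResult(
        year=year,
        crop=crop,
        window=window,
        doys=tuple(doys),
        swc_trace=tuple(trace),
        event_doys=tuple(events),
    )


@dataclass
class AnnualSeries:
    """Per-year irrigation totals with optional moving average and flags."""

    totals_mm: dict[int, float]
    crops: dict[int, str] = field(default_factory=dict)
    moving_avg_mm: dict[int, float] = field(default_factory=dict)
    cap_flags: dict[int, bool] = field(default_factory=dict)
    event_counts: dict[int, int] = field(default_factory=dict)

    @property
    def years(self) -> list[int]:
        return sorted(self.totals_mm)

    def to_frame(self) -> pd.DataFrame:
        years = self.years
        return pd.DataFrame(
            {
                "year": years,
                "crop": [self.crops.get(y, "") for y in years],
                "total_mm": [self.totals_mm[y] for y in years],
                "n_events": [self.event_counts.get(y, 0) for y in years],
                "ma_mm": [self.moving_avg_mm.get(y, np.nan) for y in years],
                "cap_flag": [self.cap_flags.get(y, False) for y in years],
            }
        )


def annual_irrigation_series(
    climate: ClimateSeries,
    plan: RotationPlan,
    storages: StorageParams,
    policy: IrrigationPolicy,
    table: Mapping[str, CropSpec] = DEFAULT_CROPS,
    years: Optional[Sequence[int]] = None,
) -> AnnualSeries:
    """Simulate the rotation over ``years`` (default: all climate years)."""
    plan.validate(table)
    if years is None:
        years = climate.years
    totals: dict[int, float] = {}
    crops: dict[int, str] = {}
    counts: dict[int, int] = {}
    for y in years:
        crop = rotation_crop_for_year(plan, y)
        season = simulate_season(climate, y, crop, storages, policy, table=table)
        totals[y] = season.total_irrigation_mm(policy)
        counts[y] = season.n_events
        crops[y] = crop
    return AnnualSeries(totals_mm=totals, crops=crops, event_counts=counts)


def moving_average(series: AnnualSeries, window_years: int = 7) -> AnnualSeries:
    """Trailing moving average of annual totals over ``window_years``.

    A year is reported only when the current year and all
    ``window_years - 1`` predecessors have totals (warm-up years are
    omitted, never zero-filled).
    """
    if window_years < 1:
        raise ValueError("window_years must be >= 1")
    ma: dict[int, float] = {}
    for y in series.years:
        needed = [y - k for k in range(window_years)]
        if all(n in series.totals_mm for n in needed):
            ma[y] = sum(series.totals_mm[n] for n in needed) / window_years
    series.moving_avg_mm = ma
    return series


def cap_exceedance(series: AnnualSeries, cap_mm: float = 79.0) -> AnnualSeries:
    """Flag years whose moving average strictly exceeds the cap."""
    series.cap_flags = {
        y: ma > cap_mm for y, ma in series.moving_avg_mm.items()
    }
    return series


@dataclass(frozen=True)
class WindowStart:
    """Result of the average-year irrigation-season start determination."""

    start_doy: Optional[int]
    start_swc_l_per_m3: Optional[float]
    mean_swc_by_doy: Mapping[int, float]
    mean_balance_by_doy: Mapping[int, float]

    @property
    def found(self) -> bool:
        return self.start_doy is not None


def determine_window_start(
    long_climate: ClimateSeries,
    storages: StorageParams,
    policy: IrrigationPolicy,
    confirm_days: int = 14,
) -> WindowStart:
    """Find the average-year irrigation-season start day.

    Runs the bucket continuously (no irrigation, clamps active) from
    full saturation on the first day of the series, averages the daily
    soil water content by day-of-year across all years, and averages the
    climatic water balance (precip - et0) the same way.  The start day
    is the first DOY from which the DOY-averaged balance stays negative
    for ``confirm_days`` consecutive days; the returned start value is
    the DOY-averaged soil water content at that day.  If the balance
    never stays negative, the result reports no irrigation season
    (``found`` is False) instead of raising.
    """
    df = long_climate.data
    precip = df["precip_mm"].to_numpy()
    et0 = df["et0_mm"].to_numpy()
    doy = df["doy"].to_numpy()
    k = policy.mm_factor(storages.depth_cm)
    lo, hi = storages.wp_l_per_m3, storages.fc_l_per_m3

    swc = np.empty(len(df))
    s = hi  # fully saturated on day one
    for i in range(len(df)):
        s = min(max(s + k * (precip[i] - et0[i]), lo), hi)
        swc[i] = s

    mean_swc = pd.Series(swc).groupby(doy).mean()
    mean_bal = pd.Series(precip - et0).groupby(doy).mean()
    # DOY 366 has few samples; restrict the search to DOY 1..365.
    bal = mean_bal.reindex(range(1, 366)).to_numpy()
    neg = bal < 0
    start: Optional[int] = None
    for d0 in range(len(neg) - confirm_days + 1):
        if np.all(neg[d0 : d0 + confirm_days]):
            start = d0 + 1
            break
    if start is None:
        return WindowStart(None, None, mean_swc.to_dict(), mean_bal.to_dict())
    return WindowStart(
        start_doy=start,
        start_swc_l_per_m3=float(mean_swc.loc[start]),
        mean_swc_by_doy=mean_swc.to_dict(),
        mean_balance_by_doy=mean_bal.to_dict(),
    )
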