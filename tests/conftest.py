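"""Shared fixtures: default soil/policy and programmatic climate builders."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from irrisim import (
    SOIL_TYPE_31,
    ClimateSeries,
    IrrigationPolicy,
    derive_storages,
)


@pytest.fixture()
def policy() -> IrrigationPolicy:
    return IrrigationPolicy()


@pytest.fixture()
def storages(policy):
    return derive_storages(SOIL_TYPE_31, policy)


def build_series(
    start_year: int,
    end_year: int,
    precip,
    et0,
    tmean=10.0,
    label: str = "custom",
) -> ClimateSeries:
    """Build a ClimateSeries from scalars, arrays or callables of DOY.

    ``precip``/``et0``/``tmean`` may be a scalar, a callable mapping a
    DOY array to values, or an array of the full series length.
    """
    dates = pd.date_range(f"{start_year}-01-01", f"{end_year}-12-31", freq="D")
    doy = dates.dayofyear.to_numpy(dtype=float)

    def resolve(x):
        if callable(x):
            return np.asarray(x(doy), dtype=float)
        arr = np.asarray(x, dtype=float)
        if arr.ndim == 0:
            return np.full(len(dates), float(arr))
        if len(arr) != len(dates):
            raise ValueError("array length mismatch")
        return arr

    frame = pd.DataFrame(
        {
            "date": dates,
            "tmean_c": resolve(tmean),
            "precip_mm": resolve(precip),
            "et0_mm": resolve(et0),
        }
    )
    return ClimateSeries(frame, scenario_label=label)


@pytest.fixture()
def build_climate():
    return build_series
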