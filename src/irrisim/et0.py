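"""FAO-56 Penman-Monteith reference (grass) evapotranspiration.

Implements the standard daily formulation::

    ET0 = [0.408 * delta * (Rn - G) + gamma * (900 / (T + 273)) * u2 * (es - ea)]
          / [delta + gamma * (1 + 0.34 * u2)]

with ``delta`` the slope of the saturation vapour-pressure curve
(kPa/degC), ``gamma`` the psychrometric constant (kPa/degC), ``Rn`` and
``G`` net radiation and soil heat flux (MJ m^-2 d^-1), ``u2`` wind speed
at 2 m (m/s), ``es``/``ea`` saturation/actual vapour pressure (kPa) and
``T`` the mean daily air temperature (degC).  Negative results (strong
advection or negative net radiation) are floored at zero because the
bucket model treats evapotranspiration strictly as a loss.
"""

from __future__ import annotations

import math

__all__ = [
    "svp_slope",
    "psychrometric_constant",
    "penman_monteith_et0",
]

#: Standard atmospheric pressure at sea level, kPa.
STANDARD_PRESSURE_KPA = 101.3


def svp_slope(tmean_c: float) -> float:
    """Slope of the saturation vapour-pressure curve at ``tmean_c``, kPa/degC."""
    es = 0.6108 * math.exp(17.27 * tmean_c / (tmean_c + 237.3))
    return 4098.0 * es / (tmean_c + 237.3) ** 2


def psychrometric_constant(pressure_kpa: float = STANDARD_PRESSURE_KPA) -> float:
    """Psychrometric constant gamma = 0.665e-3 * P, kPa/degC."""
    return 0.665e-3 * pressure_kpa


def penman_monteith_et0(
    tmean_c: float,
    net_radiation_mj: float,
    soil_heat_flux_mj: float,
    wind_2m_ms: float,
    vp_sat_kpa: float,
    vp_act_kpa: float,
    pressure_kpa: float = STANDARD_PRESSURE_KPA,
) -> float:
    """Daily reference evapotranspiration in mm/day, floored at zero.

    Raises
    ------
    ValueError
        If any driver is missing (``None``), the temperature is below
        absolute zero, or the actual vapour pressure exceeds saturation.
    """
    drivers = {
        "tmean_c": tmean_c,
        "net_radiation_mj": net_radiation_mj,
        "soil_heat_flux_mj": soil_heat_flux_mj,
        "wind_2m_ms": wind_2m_ms,
        "vp_sat_kpa": vp_sat_kpa,
        "vp_act_kpa": vp_act_kpa,
    }
    missing = [k for k, v in drivers.items() if v is None or not math.isfinite(v)]
    if missing:
        raise ValueError(f"missing Penman-Monteith drivers: {', '.join(missing)}")
    if tmean_c <= -273.0:
        raise ValueError(f"temperature {tmean_c} degC below absolute zero")
    if vp_act_kpa > vp_sat_kpa + 1e-12:
        raise ValueError(
            f"actual vapour pressure {vp_act_kpa} kPa exceeds saturation {vp_sat_kpa} kPa"
        )
    delta = svp_slope(tmean_c)
    gamma = psychrometric_constant(pressure_kpa)
    num = 0.408 * delta * (net_radiation_mj - soil_heat_flux_mj)
    num += gamma * (900.0 / (tmean_c + 273.0)) * wind_2m_ms * (vp_sat_kpa - vp_act_kpa)
    den = delta + gamma * (1.0 + 0.34 * wind_2m_ms)
    return max(num / den, 0.0)
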