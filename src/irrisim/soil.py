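"""Soil hydraulics and the daily soil-water bucket update.

The model is a single-layer bucket over the rooting zone.  Soil water
content (SWC) is bookkept in l/m^3 of soil on a scale where 100 %
volumetric water content corresponds to 1000 l/m^3, so a percentage
``x`` converts to ``10 * x`` l/m^3.  The bucket is bounded below by the
stagnant-water (wilting point) storage and above by the field-capacity
storage.  Each day the water balance ``precip - et0`` is applied; when
the content falls below a trigger threshold - the wilting storage plus
a fixed fraction of the available water capacity (AWC) - a discrete
irrigation event of a fixed depth is added.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

__all__ = [
    "SoilProfile",
    "StorageParams",
    "IrrigationPolicy",
    "SoilWaterState",
    "IrrigationEvent",
    "SOIL_TYPE_31",
    "derive_storages",
    "daily_update",
]

#: l/m^3 per volumetric percentage point (the 1000-l/m^3 percent scale).
PCT_TO_LM3 = 10.0


@dataclass(frozen=True)
class SoilProfile:
    """Volumetric soil hydraulic fractions for one rooting zone.

    Parameters
    ----------
    soil_type_id:
        Soil-map unit label, e.g. ``"31"`` for the brown podzolic sands
        that dominate the study region's crop land.
    field_capacity_pct, awc_pct, wilting_pct:
        Volumetric percentages; field capacity must equal wilting point
        plus available water capacity.
    depth_cm:
        Rooting depth of the bucket in centimetres.
    """

    soil_type_id: str
    field_capacity_pct: float
    awc_pct: float
    wilting_pct: float
    depth_cm: float = 60.0

    def __post_init__(self) -> None:
        for name in ("field_capacity_pct", "awc_pct", "wilting_pct"):
            v = getattr(self, name)
            if not (0.0 <= v < 100.0):
                raise ValueError(f"{name}={v!r} outside [0, 100)")
        if not (0.0 < self.field_capacity_pct):
            raise ValueError("field capacity must be positive")
        if self.depth_cm <= 0:
            raise ValueError("depth_cm must be positive")
        resid = self.wilting_pct + self.awc_pct - self.field_capacity_pct
        if abs(resid) > 1e-9:
            raise ValueError(
                "inconsistent profile: wilting + AWC != field capacity "
                f"({self.wilting_pct} + {self.awc_pct} != {self.field_capacity_pct})"
            )


#: Default parameterization: soil type 31, rooting zone 0-60 cm.
SOIL_TYPE_31 = SoilProfile(
    soil_type_id="31",
    field_capacity_pct=24.0,
    awc_pct=17.0,
    wilting_pct=7.0,
    depth_cm=60.0,
)


@dataclass(frozen=True)
class IrrigationPolicy:
    """Trigger rule, event size and the regulatory accounting constants.

    ``trigger_fraction`` is the depletion threshold as a fraction of AWC:
    an event fires when SWC drops strictly below
    ``wilting + trigger_fraction * awc``.  ``event_amount_mm`` is the
    depth applied per event.  ``annual_cap_mm`` and ``cap_window_years``
    describe the groundwater abstraction limit evaluated as a trailing
    moving average of annual irrigation totals.

    ``unit_convention`` selects how mm of water map onto the l/m^3
    bookkeeping scale: ``"direct"`` adds 1 l/m^3 per mm (the
    conventional bookkeeping, under which one 20 mm event is +2
    percentage points), ``"depth_scaled"`` distributes each mm over
    the rooting depth (1000 / (10 * depth_cm) l/m^3 per mm), which is
    the physically consistent alternative.
    """

    trigger_fraction: float = 0.20
    event_amount_mm: float = 20.0
    annual_cap_mm: float = 79.0
    cap_window_years: int = 7
    unit_convention: str = "direct"

    def __post_init__(self) -> None:
        if not (0.0 < self.trigger_fraction < 1.0):
            raise ValueError("trigger_fraction must lie in (0, 1)")
        if self.event_amount_mm <= 0:
            raise ValueError("event_amount_mm must be positive")
        if self.cap_window_years < 1:
            raise ValueError("cap_window_years must be >= 1")
        if self.unit_convention not in ("direct", "depth_scaled"):
            raise ValueError(
                f"unknown unit_convention {self.unit_convention!r}; "
                "expected 'direct' or 'depth_scaled'"
            )

    def mm_factor(self, depth_cm: float) -> float:
        """l/m^3 of bookkept storage per mm of water depth."""
        if self.unit_convention == "direct":
            return 1.0
        return 1000.0 / (PCT_TO_LM3 * depth_cm)


@dataclass(frozen=True)
class StorageParams:
    """Bucket bounds and trigger on the l/m^3 bookkeeping scale."""

    fc_l_per_m3: float
    wp_l_per_m3: float
    awc_l_per_m3: float
    trigger_l_per_m3: float
    depth_cm: float = 60.0

    def __post_init__(self) -> None:
        if not (self.wp_l_per_m3 <= self.trigger_l_per_m3 <= self.fc_l_per_m3):
            raise ValueError("required ordering wp <= trigger <= fc violated")
        if abs(self.awc_l_per_m3 - (self.fc_l_per_m3 - self.wp_l_per_m3)) > 1e-9:
            raise ValueError("awc != fc - wp")


def derive_storages(profile: SoilProfile, policy: IrrigationPolicy) -> StorageParams:
    """Convert a soil profile to volumetric storages and the trigger level.

    Uses the 10x percent-to-l/m^3 rule; the trigger threshold is the
    stagnant-water storage plus ``policy.trigger_fraction`` of the AWC
    storage.  For soil type 31 with the default 20 % fraction this gives
    fc = 240, wp = 70, awc = 170 and trigger = 104 l/m^3.
    """
    fc = PCT_TO_LM3 * profile.field_capacity_pct
    wp = PCT_TO_LM3 * profile.wilting_pct
    awc = PCT_TO_LM3 * profile.awc_pct
    trigger = wp + policy.trigger_fraction * awc
    return StorageParams(
        fc_l_per_m3=fc,
        wp_l_per_m3=wp,
        awc_l_per_m3=awc,
        trigger_l_per_m3=trigger,
        depth_cm=profile.depth_cm,
    )


@dataclass(frozen=True)
class SoilWaterState:
    """Running state of one simulated season."""

    doy: int
    swc_l_per_m3: float
    events_so_far: int = 0
    irrigation_mm_so_far: float = 0.0


@dataclass(frozen=True)
class IrrigationEvent:
    """One discrete irrigation application."""

    doy: int
    amount_mm: float
    swc_before: float
    swc_after: float


def _clamp(x: float, lo: float, hi: float) -> float:
    return lo if x < lo else hi if x > hi else x


def daily_update(
    state: SoilWaterState,
    precip_mm: float,
    et0_mm: float,
    storages: StorageParams,
    policy: IrrigationPolicy,
    irrigation_allowed: bool = True,
) -> tuple[SoilWaterState, Optional[IrrigationEvent]]:
    """Advance the bucket by one day and possibly fire one irrigation event.

    The order of operations is: (1) add ``k * (precip - et0)`` where
    ``k`` is the unit-convention factor; (2) clamp to
    ``[wp, fc]``; (3) if irrigation is allowed and the clamped value is
    strictly below the trigger, add one event of ``k * event_amount_mm``
    and re-clamp to the field-capacity ceiling.  At most one event can
    fire per day; the totals count the event depth in mm.

    Returns the new state (with ``doy`` advanced by one) and the event
    record, or ``None`` when no event fired.
    """
    swc = state.swc_l_per_m3
    if not (storages.wp_l_per_m3 - 1e-9 <= swc <= storages.fc_l_per_m3 + 1e-9):
        raise ValueError(
            f"state swc {swc} outside bucket bounds "
            f"[{storages.wp_l_per_m3}, {storages.fc_l_per_m3}]"
        )
    k = policy.mm_factor(storages.depth_cm)
    swc = _clamp(
        swc + k * (precip_mm - et0_mm),
        storages.wp_l_per_m3,
        storages.fc_l_per_m3,
    )
    event: Optional[IrrigationEvent] = None
    events = state.events_so_far
    total = state.irrigation_mm_so_far
    if irrigation_allowed and swc < storages.trigger_l_per_m3:
        before = swc
        swc = min(swc + k * policy.event_amount_mm, storages.fc_l_per_m3)
        event = IrrigationEvent(
            doy=state.doy,
            amount_mm=policy.event_amount_mm,
            swc_before=before,
            swc_after=swc,
        )
        events += 1
        total += policy.event_amount_mm
    new_state = SoilWaterState(
        doy=state.doy + 1,
        swc_l_per_m3=swc,
        events_so_far=events,
        irrigation_mm_so_far=total,
    )
    return new_state, event
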