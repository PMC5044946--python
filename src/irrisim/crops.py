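"""Crop calendar, irrigation windows and rotation scheduling.

Each crop is described by its harvest day-of-year and the start of its
maturation phase, assumed to begin exactly three weeks (21 days) before
harvest.  Irrigation is only considered between a common season start
day (default DOY 107, when the climatic water balance of an average
year turns negative) and the start of maturation, exclusive: no
irrigation on the maturation start day itself.  DOY constants apply
unchanged in leap years.

A rotation plan cycles an ordered list of crops, anchored so that a
configurable anchor year grows the first crop of the list.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

__all__ = [
    "CropSpec",
    "IrrigationWindow",
    "RotationPlan",
    "DEFAULT_CROPS",
    "DEFAULT_ROTATION",
    "MATURATION_DAYS",
    "DEFAULT_WINDOW_START_DOY",
    "DEFAULT_WINDOW_START_SWC",
    "maturity_start",
    "irrigation_window",
    "rotation_crop_for_year",
]

#: Maturation is assumed to start this many days before harvest.
MATURATION_DAYS = 21
#: Common irrigation-season start (day-of-year) for all crops.
DEFAULT_WINDOW_START_DOY = 107
#: Soil water content (l/m^3) assumed at the season start day.
DEFAULT_WINDOW_START_SWC = 224.9


@dataclass(frozen=True)
class CropSpec:
    """One crop's calendar entry.

    ``maturity_start_doy`` must equal ``harvest_doy - 21``; passing an
    inconsistent explicit value is a validation error rather than a
    silent override.
    """

    name: str
    share_pct: float
    harvest_doy: int
    maturity_start_doy: int | None = None

    def __post_init__(self) -> None:
        derived = self.harvest_doy - MATURATION_DAYS
        if self.maturity_start_doy is None:
            object.__setattr__(self, "maturity_start_doy", derived)
        elif self.maturity_start_doy != derived:
            raise ValueError(
                f"{self.name}: maturity start {self.maturity_start_doy} "
                f"inconsistent with harvest {self.harvest_doy} "
                f"(must be harvest - {MATURATION_DAYS})"
            )
        if not (1 < self.maturity_start_doy < self.harvest_doy <= 366):
            raise ValueError(
                f"{self.name}: harvest day {self.harvest_doy} leaves no valid "
                f"maturation start (derived day {derived})"
            )
        if self.share_pct < 0:
            raise ValueError(f"{self.name}: negative area share")


def _crop_table(rows: Sequence[tuple[str, float, int, int]]) -> dict[str, CropSpec]:
    table: dict[str, CropSpec] = {}
    for name, share, harvest, maturity in rows:
        table[name] = CropSpec(name, share, harvest, maturity)
    return table


#: Default crop table for the study region (shares in % of agricultural
#: area; the organically fertilised winter-rapeseed variant is listed
#: without a separately reported share).
DEFAULT_CROPS: Mapping[str, CropSpec] = _crop_table(
    [
        ("Spring barley", 9.0, 219, 198),
        ("Triticale", 4.0, 219, 198),
        ("Winter barley", 12.0, 198, 177),
        ("Winter rye", 5.0, 219, 198),
        ("Winter wheat", 14.0, 219, 198),
        ("Winter rapeseed", 4.0, 183, 162),
        ("Winter rapeseed with organic fertilisation", 0.0, 208, 187),
        ("Silage maize", 5.0, 261, 240),
        ("Potato", 22.0, 265, 244),
        ("Sugar beet", 15.0, 290, 269),
    ]
)


def maturity_start(
    crop_name: str, table: Mapping[str, CropSpec] = DEFAULT_CROPS
) -> int:
    """Maturation start day-of-year for ``crop_name`` (harvest minus 21)."""
    if crop_name not in table:
        raise KeyError(f"unknown crop {crop_name!r}")
    return table[crop_name].maturity_start_doy


@dataclass(frozen=True)
class IrrigationWindow:
    """Half-open irrigation window ``[start_doy, end_doy)`` for one crop.

    ``start_swc_l_per_m3`` is the soil water content assumed on the
    start day.  A window with ``end_doy <= start_doy`` is zero-length:
    the crop matures before the irrigation season begins and is never
    irrigated (``irrigable`` is False).
    """

    start_doy: int = DEFAULT_WINDOW_START_DOY
    end_doy: int = DEFAULT_WINDOW_START_DOY
    start_swc_l_per_m3: float = DEFAULT_WINDOW_START_SWC

    @property
    def n_days(self) -> int:
        return max(self.end_doy - self.start_doy, 0)

    @property
    def irrigable(self) -> bool:
        return self.n_days > 0

    def contains(self, doy: int) -> bool:
        return self.start_doy <= doy < self.end_doy


def irrigation_window(
    crop_name: str,
    table: Mapping[str, CropSpec] = DEFAULT_CROPS,
    start_doy: int = DEFAULT_WINDOW_START_DOY,
    start_swc: float = DEFAULT_WINDOW_START_SWC,
) -> IrrigationWindow:
    """Irrigation window for a crop: season start to maturation start.

    For the default sugar-beet calendar this is [107, 269).  Crops whose
    maturation starts on or before the season start get a zero-length,
    flagged window rather than an exception.
    """
    end = maturity_start(crop_name, table)
    if end <= start_doy:
        return IrrigationWindow(start_doy=start_doy, end_doy=start_doy,
                                start_swc_l_per_m3=start_swc)
    return IrrigationWindow(start_doy=start_doy, end_doy=end,
                            start_swc_l_per_m3=start_swc)


@dataclass(frozen=True)
class RotationPlan:
    """Ordered crop cycle anchored so ``anchor_year`` grows ``crops[0]``."""

    crops: tuple[str, ...] = ("Sugar beet", "Potato", "Winter rye", "Winter barley")
    anchor_year: int = 1991

    def __post_init__(self) -> None:
        if len(self.crops) == 0:
            raise ValueError("rotation plan must contain at least one crop")

    def validate(self, table: Mapping[str, CropSpec] = DEFAULT_CROPS) -> None:
        unknown = [c for c in self.crops if c not in table]
        if unknown:
            raise KeyError(f"rotation references unknown crops: {unknown}")


#: The region's most common rotation, anchored to sugar beet in 1991.
DEFAULT_ROTATION = RotationPlan()


def rotation_crop_for_year(plan: RotationPlan, year: int) -> str:
    """Crop grown in ``year`` under ``plan`` (periodic, works before the anchor)."""
    return plan.crops[(year - plan.anchor_year) % len(plan.crops)]
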