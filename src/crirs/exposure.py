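"""Exposure banding and scoring for the five workplace exposure indicators.

E1 handling volume (circulation substitutes when missing), E2 worker count,
E3 workplace count, E4 volatility/dustiness, E5 measured exposure. Each
continuous determinant is banded into classes by fixed cut-points (control
banding) and each (indicator, class) cell carries a point value; the five
maxima partition as 30 + 10 + 10 + 10 + 40 = 100.

Band convention: bands are left-closed/right-open except at the Class 2 /
Class 1 boundary, where the Class 1 criterion is a strict inequality as
printed (">1000", ">300", ">500") so Class 2 is closed above. The liquid/gas
volatility band 50-150 °C is closed at both ends (its neighbours are strict).
Missing fields band as Not Classified and score 0.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Literal, Mapping, Optional

__all__ = [
    "ExposureClass",
    "ExposureIndicator",
    "DustForm",
    "PhysicalForm",
    "ExposureProfile",
    "ExposureScoringTable",
    "classify_volume",
    "classify_count",
    "classify_volatility_dustiness",
    "classify_measured_exposure",
    "classify_profile",
    "raw_exposure_score",
    "handling_subscore",
    "distribution_subscore",
    "measured_subscore",
]


class ExposureClass(enum.Enum):
    C1 = "Class1"
    C2 = "Class2"
    C3 = "Class3"
    C4 = "Class4"
    C5 = "Class5"
    NOT_CLASSIFIED = "NotClassified"

    @property
    def severity(self) -> int:
        """Higher = more severe; NotClassified is least severe."""
        order = {
            ExposureClass.NOT_CLASSIFIED: 0,
            ExposureClass.C5: 1,
            ExposureClass.C4: 2,
            ExposureClass.C3: 3,
            ExposureClass.C2: 4,
            ExposureClass.C1: 5,
        }
        return order[self]


class ExposureIndicator(enum.Enum):
    E1 = "handling volume"
    E2 = "worker numbers"
    E3 = "workplace numbers"
    E4 = "volatility/dustiness"
    E5 = "measured exposure"


class DustForm(enum.Enum):
    """ACGIH-style dustiness category for solids.

    TLV_NOTATION covers substances whose TLV carries a V, IFV, H or R
    particle/vapor notation (most readily airborne → highest class).
    """

    TLV_NOTATION = "TLV"
    POWDER_CRYSTALLINE = "POWDER"
    PELLET_NONFRIABLE = "PELLET"


@dataclass(frozen=True)
class PhysicalForm:
    """Physical state plus the attribute that determines its E4 band.

    Liquids/gases carry a boiling point (°C); solids carry a dustiness
    category. Exactly one of the two must be present, matching the state.
    """

    state: Literal["liquid_gas", "solid"]
    boiling_point_C: Optional[float] = None
    dust_form: Optional[DustForm] = None

    def __post_init__(self) -> None:
        if self.state == "liquid_gas":
            if self.boiling_point_C is None or self.dust_form is not None:
                raise ValueError(
                    "liquid/gas form requires boiling_point_C and no dust_form"
                )
        elif self.state == "solid":
            if self.dust_form is None or self.boiling_point_C is not None:
                raise ValueError(
                    "solid form requires dust_form and no boiling_point_C"
                )
        else:
            raise ValueError(f"unknown physical state {self.state!r}")


@dataclass(frozen=True)
class ExposureProfile:
    """Raw exposure determinants for one chemical; any field may be missing.

    ``measured_exposure`` is in ppm for liquids/gases and mg/m³ for solids;
    the unit is implied by ``form.state`` and must agree when both are given.
    """

    handling_volume_tpy: Optional[float] = None
    circulation_tpy: Optional[float] = None
    worker_count: Optional[int] = None
    workplace_count: Optional[int] = None
    form: Optional[PhysicalForm] = None
    measured_exposure: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("handling_volume_tpy", "circulation_tpy", "measured_exposure"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        for name in ("worker_count", "workplace_count"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        if self.measured_exposure is not None and self.form is None:
            raise ValueError(
                "measured_exposure requires a physical form to fix its unit"
            )

    @property
    def effective_volume_tpy(self) -> Optional[float]:
        """Handling volume, with circulation as the fallback source."""
        if self.handling_volume_tpy is not None:
            return self.handling_volume_tpy
        return self.circulation_tpy


def _default_exposure_points() -> dict[ExposureIndicator, dict[ExposureClass, int]]:
    E = ExposureIndicator
    C = ExposureClass
    five = lambda a, b, c, d, e: {C.C1: a, C.C2: b, C.C3: c, C.C4: d, C.C5: e, C.NOT_CLASSIFIED: 0}
    return {
        E.E1: five(30, 24, 18, 12, 6),
        E.E2: five(10, 8, 6, 4, 2),
        E.E3: five(10, 8, 6, 4, 2),
        E.E4: {C.C1: 10, C.C2: 8, C.C3: 6, C.NOT_CLASSIFIED: 0},
        E.E5: five(40, 32, 24, 16, 8),
    }


@dataclass(frozen=True)
class ExposureScoringTable:
    points: Mapping[ExposureIndicator, Mapping[ExposureClass, int]] = field(
        default_factory=_default_exposure_points
    )

    def __post_init__(self) -> None:
        for ind in ExposureIndicator:
            if ind not in self.points:
                raise ValueError(f"exposure table missing indicator {ind.name}")
            for cls, pts in self.points[ind].items():
                if pts < 0:
                    raise ValueError(f"negative points for ({ind.name}, {cls.value})")
                if ind is ExposureIndicator.E4 and cls in (
                    ExposureClass.C4,
                    ExposureClass.C5,
                ):
                    raise ValueError("volatility/dustiness has only three classes")

    def lookup(self, indicator: ExposureIndicator, cls: ExposureClass) -> int:
        if cls not in self.points[indicator]:
            raise ValueError(
                f"exposure class {cls.value} invalid for {indicator.name}"
            )
        return int(self.points[indicator][cls])

    def max_points(self, indicator: ExposureIndicator) -> int:
        return max(self.points[indicator].values())


DEFAULT_EXPOSURE_TABLE = ExposureScoringTable()


def classify_volume(tons_per_year: Optional[float]) -> ExposureClass:
    """Band an annual handling/circulation volume (tons/year)."""
    if tons_per_year is None:
        return ExposureClass.NOT_CLASSIFIED
    v = float(tons_per_year)
    if v < 0:
        raise ValueError(f"volume must be non-negative, got {v}")
    if v > 1000:
        return ExposureClass.C1
    if v >= 10:
        return ExposureClass.C2
    if v >= 1:
        return ExposureClass.C3
    if v >= 0.1:
        return ExposureClass.C4
    return ExposureClass.C5


def classify_count(n: Optional[int], kind: str = "workers") -> ExposureClass:
    """Band an exposed-worker or workplace count (same cut-points)."""
    if kind not in ("workers", "workplaces"):
        raise ValueError(f"kind must be 'workers' or 'workplaces', got {kind!r}")
    if n is None:
        return ExposureClass.NOT_CLASSIFIED
    n = int(n)
    if n < 0:
        raise ValueError(f"{kind} count must be non-negative, got {n}")
    if n > 300:
        return ExposureClass.C1
    if n >= 100:
        return ExposureClass.C2
    if n >= 50:
        return ExposureClass.C3
    if n >= 5:
        return ExposureClass.C4
    return ExposureClass.C5


def classify_volatility_dustiness(form: Optional[PhysicalForm]) -> ExposureClass:
    """Band volatility (boiling point) or dustiness (solid category)."""
    if form is None:
        return ExposureClass.NOT_CLASSIFIED
    if form.state == "liquid_gas":
        bp = form.boiling_point_C
        if bp < 50:
            return ExposureClass.C1
        if bp <= 150:
            return ExposureClass.C2
        return ExposureClass.C3
    return {
        DustForm.TLV_NOTATION: ExposureClass.C1,
        DustForm.POWDER_CRYSTALLINE: ExposureClass.C2,
        DustForm.PELLET_NONFRIABLE: ExposureClass.C3,
    }[form.dust_form]


def classify_measured_exposure(
    value: Optional[float], form: Optional[PhysicalForm]
) -> ExposureClass:
    """Band a measured workplace concentration.

    ppm bands for liquids/gases, mg/m³ bands for solids; which applies is
    decided by ``form.state``.
    """
    if value is None or form is None:
        return ExposureClass.NOT_CLASSIFIED
    v = float(value)
    if v < 0:
        raise ValueError(f"measured exposure must be non-negative, got {v}")
    if form.state == "liquid_gas":
        cuts = (500.0, 50.0, 5.0, 0.5)
    else:
        cuts = (10.0, 1.0, 0.1, 0.01)
    if v > cuts[0]:
        return ExposureClass.C1
    if v >= cuts[1]:
        return ExposureClass.C2
    if v >= cuts[2]:
        return ExposureClass.C3
    if v >= cuts[3]:
        return ExposureClass.C4
    return ExposureClass.C5


def classify_profile(
    profile: ExposureProfile,
) -> dict[ExposureIndicator, ExposureClass]:
    """Band all five indicators of a profile."""
    return {
        ExposureIndicator.E1: classify_volume(profile.effective_volume_tpy),
        ExposureIndicator.E2: classify_count(profile.worker_count, "workers"),
        ExposureIndicator.E3: classify_count(profile.workplace_count, "workplaces"),
        ExposureIndicator.E4: classify_volatility_dustiness(profile.form),
        ExposureIndicator.E5: classify_measured_exposure(
            profile.measured_exposure, profile.form
        ),
    }


def raw_exposure_score(
    profile: ExposureProfile, table: ExposureScoringTable = DEFAULT_EXPOSURE_TABLE
) -> int:
    """Sum of the five indicator points; 0–100 under the default table."""
    bands = classify_profile(profile)
    return sum(table.lookup(ind, cls) for ind, cls in bands.items())


def handling_subscore(
    profile: ExposureProfile, table: ExposureScoringTable = DEFAULT_EXPOSURE_TABLE
) -> int:
    """E1 points only (≤ 30 by default)."""
    return table.lookup(
        ExposureIndicator.E1, classify_volume(profile.effective_volume_tpy)
    )


def distribution_subscore(
    profile: ExposureProfile, table: ExposureScoringTable = DEFAULT_EXPOSURE_TABLE
) -> int:
    """E2 + E3 + E4 points: workers, workplaces, volatility/dustiness (≤ 30)."""
    bands = classify_profile(profile)
    return sum(
        table.lookup(ind, bands[ind])
        for ind in (ExposureIndicator.E2, ExposureIndicator.E3, ExposureIndicator.E4)
    )


def measured_subscore(
    profile: ExposureProfile, table: ExposureScoringTable = DEFAULT_EXPOSURE_TABLE
) -> int:
    """E5 points only (≤ 40 by default)."""
    return table.lookup(
        ExposureIndicator.E5,
        classify_measured_exposure(profile.measured_exposure, profile.form),
    )
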