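"""Domain types shared across the pipeline.

Conventions: coordinates are geographic lon/lat (WGS84, degrees);
incidence ("need") is cumulative 5-year HIV incidence per 100 000 persons;
a PFNR is a facility count divided by that incidence, so lower values mean
poorer geographic availability relative to need. Suppressed need (small-count
privacy suppression, as in the Kentucky county data) is always carried as an
explicit state, never conflated with zero incidence.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Optional

from shapely.geometry.base import BaseGeometry


class ValidationError(ValueError):
    """Raised for malformed or inconsistent input data."""


class FacilityKind(str, enum.Enum):
    """Facility class: a PrEP-prescribing location or a pharmacy."""

    PREP_PRESCRIBER = "prep_prescriber"
    PHARMACY = "pharmacy"


class UnitLevel(str, enum.Enum):
    """Spatial resolution of an analysis unit."""

    ZCTA = "zcta"
    COUNTY = "county"


class ExclusionReason(str, enum.Enum):
    """Why a unit contributes no PFNR to summaries."""

    SUPPRESSED_NEED = "suppressed_need"
    ZERO_NEED = "zero_need"


@dataclass(frozen=True)
class SpatialUnit:
    """A polygonal analysis unit (ZCTA or county) with region membership."""

    unit_id: str
    level: UnitLevel
    region_id: str
    geometry: BaseGeometry

    def __post_init__(self) -> None:
        if self.geometry is None or self.geometry.is_empty:
            raise ValidationError(f"unit {self.unit_id!r}: empty geometry")
        minx, miny, maxx, maxy = self.geometry.bounds
        if not all(math.isfinite(v) for v in (minx, miny, maxx, maxy)):
            raise ValidationError(f"unit {self.unit_id!r}: non-finite coordinates")


@dataclass(frozen=True)
class FacilityRecord:
    """A classed facility point; carries either coordinates or an address key
    awaiting gazetteer resolution (exactly one of the two on ingest)."""

    facility_id: str
    kind: FacilityKind
    lon: Optional[float] = None
    lat: Optional[float] = None
    address_key: Optional[str] = None

    @property
    def has_coords(self) -> bool:
        return self.lon is not None and self.lat is not None

    def __post_init__(self) -> None:
        if self.has_coords:
            if not (-180.0 <= self.lon <= 180.0 and -90.0 <= self.lat <= 90.0):
                raise ValidationError(
                    f"facility {self.facility_id!r}: coordinates "
                    f"({self.lon}, {self.lat}) outside lon/lat range"
                )
        elif self.address_key is None:
            raise ValidationError(
                f"facility {self.facility_id!r}: neither coordinates nor address key"
            )


@dataclass(frozen=True)
class NeedRecord:
    """A unit's 5-year HIV incidence per 100 000, or an explicit suppression."""

    unit_id: str
    incidence_per_100k: Optional[float]  # None means suppressed

    @property
    def suppressed(self) -> bool:
        return self.incidence_per_100k is None

    def __post_init__(self) -> None:
        v = self.incidence_per_100k
        if v is not None and (not math.isfinite(v) or v < 0):
            raise ValidationError(
                f"need for unit {self.unit_id!r}: incidence must be finite and >= 0, got {v}"
            )


@dataclass(frozen=True)
class UnitCounts:
    """Per-unit facility counts by class (zero-filled over all units)."""

    unit_id: str
    n_prescribers: int = 0
    n_pharmacies: int = 0

    def count(self, kind: FacilityKind) -> int:
        return self.n_prescribers if kind is FacilityKind.PREP_PRESCRIBER else self.n_pharmacies

    def __post_init__(self) -> None:
        if self.n_prescribers < 0 or self.n_pharmacies < 0:
            raise ValidationError(f"unit {self.unit_id!r}: negative facility count")


@dataclass(frozen=True)
class UnitMetrics:
    """Per-unit facility counts and PFNRs; a PFNR is defined iff the unit's
    incidence is present and positive, otherwise `excluded_reason` is set."""

    unit_id: str
    n_prescribers: int
    n_pharmacies: int
    incidence_per_100k: Optional[float]
    pfnr_prescribers: Optional[float]
    pfnr_pharmacies: Optional[float]
    excluded_reason: Optional[ExclusionReason] = None

    @property
    def defined(self) -> bool:
        return self.excluded_reason is None

    def pfnr(self, kind: FacilityKind) -> Optional[float]:
        return (
            self.pfnr_prescribers
            if kind is FacilityKind.PREP_PRESCRIBER
            else self.pfnr_pharmacies
        )


@dataclass(frozen=True)
class ClassSummary:
    """Distribution summary of defined unit PFNRs for one facility class."""

    mean: Optional[float]
    median: Optional[float]
    q1: Optional[float]
    q3: Optional[float]
    n_used: int

    @property
    def defined(self) -> bool:
        return self.n_used > 0


@dataclass(frozen=True)
class RegionReport:
    """Per-region PFNR summaries, pharmacy-expansion fold increase and
    facility-desert counts.

    `fold_increase` is the ratio of full-precision mean PFNRs
    (pharmacies over prescribers); it is None with `fold_reason` set when a
    mean is degenerate (no current prescriber access, or no pharmacies).
    """

    region_id: str
    prescriber_summary: ClassSummary
    pharmacy_summary: ClassSummary
    fold_increase: Optional[float]
    fold_reason: Optional[str]
    n_prescriber_deserts: int
    n_pharmacy_deserts: int
    n_units_total: int
    n_units_used: int
    n_units_excluded: int
    excluded_by_reason: dict[str, int] = field(default_factory=dict)
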