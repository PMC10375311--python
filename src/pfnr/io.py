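"""Reading and validation of facility tables, boundary GeoJSON and need
tables; offline address resolution; table writers.

File formats: boundaries are GeoJSON FeatureCollections (RFC 7946, lon-lat
axis order) whose features carry ``unit_id``, ``level`` and ``region_id``
properties; facility and need tables are delimited text with a header row
(comma by default, configurable). Suppressed incidence is encoded by a
designated token (default ``"NA"``) and is preserved as an explicit state.

Geocoding is offline by design: a :class:`Gazetteer` maps address keys to
coordinates deterministically, and unknown keys are an explicit miss that is
tallied and reported — never a silent default location.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Optional, Sequence, Union

import pandas as pd
from shapely.geometry import shape
from shapely.geometry.base import BaseGeometry

from pfnr.types import (
    FacilityKind,
    FacilityRecord,
    NeedRecord,
    SpatialUnit,
    UnitLevel,
    ValidationError,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

#: Default column names for facility tables.
FACILITY_COLUMNS = ("facility_id", "kind", "lon", "lat", "address_key")
#: Default column names for need tables.
NEED_COLUMNS = ("unit_id", "incidence_per_100k")
#: Default token marking suppressed (not released) incidence.
DEFAULT_SUPPRESSION_TOKEN = "NA"


class Gazetteer:
    """Deterministic offline address-key -> (lon, lat) lookup.

    A stand-in for an online geocoding service: resolution is a plain
    dictionary lookup, and unknown keys return ``None`` (an explicit miss).
    """

    def __init__(self, mapping: Mapping[str, tuple[float, float]]):
        self._mapping = dict(mapping)

    def resolve(self, address_key: str) -> Optional[tuple[float, float]]:
        """Return (lon, lat) for a known key, None for a miss."""
        return self._mapping.get(address_key)

    def __len__(self) -> int:
        return len(self._mapping)

    def __contains__(self, key: str) -> bool:
        return key in self._mapping

    @classmethod
    def from_csv(cls, path: PathLike, delimiter: str = ",") -> "Gazetteer":
        """Load from a table with columns address_key, lon, lat."""
        df = pd.read_csv(path, sep=delimiter, dtype={"address_key": str})
        for col in ("address_key", "lon", "lat"):
            if col not in df.columns:
                raise ValidationError(f"gazetteer {path}: missing column {col!r}")
        return cls(
            {
                str(r.address_key): (float(r.lon), float(r.lat))
                for r in df.itertuples(index=False)
            }
        )


@dataclass
class FacilityReadResult:
    """Resolved facility records plus the gazetteer misses excluded from
    downstream counts. ``len(records) + len(misses)`` equals the input row
    count."""

    records: list[FacilityRecord]
    misses: list[str] = field(default_factory=list)  # facility_ids left unresolved

    def __iter__(self) -> Iterator[FacilityRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def read_boundaries(path: PathLike) -> list[SpatialUnit]:
    """Read spatial units from a GeoJSON FeatureCollection.

    Each feature must carry ``unit_id``, ``level`` (``zcta`` | ``county``)
    and ``region_id`` properties and a non-empty polygon or multipolygon
    geometry. Errors name the offending feature index. All units within one
    region must share a level, and unit ids must be unique.
    """
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise ValidationError(f"{path}: expected a GeoJSON FeatureCollection")

    units: list[SpatialUnit] = []
    seen_ids: set[str] = set()
    region_levels: dict[str, UnitLevel] = {}
    for i, feature in enumerate(doc.get("features", [])):
        props = feature.get("properties") or {}
        for key in ("unit_id", "level", "region_id"):
            if key not in props or props[key] in (None, ""):
                raise ValidationError(f"{path}: feature {i} missing property {key!r}")
        unit_id = str(props["unit_id"])
        if unit_id in seen_ids:
            raise ValidationError(f"{path}: feature {i}: duplicate unit_id {unit_id!r}")
        seen_ids.add(unit_id)
        try:
            level = UnitLevel(props["level"])
        except ValueError:
            raise ValidationError(
                f"{path}: feature {i}: unknown level {props['level']!r}"
            ) from None
        region_id = str(props["region_id"])
        if region_id in region_levels and region_levels[region_id] is not level:
            raise ValidationError(
                f"{path}: feature {i}: mixed unit levels within region {region_id!r}"
            )
        region_levels[region_id] = level
        geom_doc = feature.get("geometry")
        if geom_doc is None:
            raise ValidationError(f"{path}: feature {i}: missing geometry")
        geom: BaseGeometry = shape(geom_doc)
        if geom.is_empty:
            raise ValidationError(f"{path}: feature {i}: empty geometry")
        if geom.geom_type not in ("Polygon", "MultiPolygon"):
            raise ValidationError(
                f"{path}: feature {i}: geometry must be Polygon or MultiPolygon, "
                f"got {geom.geom_type}"
            )
        units.append(SpatialUnit(unit_id=unit_id, level=level, region_id=region_id, geometry=geom))
    return units


def write_boundaries(units: Sequence[SpatialUnit], path: PathLike) -> None:
    """Write spatial units as a GeoJSON FeatureCollection (lon-lat order)."""
    features = [
        {
            "type": "Feature",
            "properties": {
                "unit_id": u.unit_id,
                "level": u.level.value,
                "region_id": u.region_id,
            },
            "geometry": u.geometry.__geo_interface__,
        }
        for u in units
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_facilities(
    path: PathLike,
    gazetteer: Optional[Gazetteer] = None,
    delimiter: str = ",",
) -> FacilityReadResult:
    """Read a facility table, resolving address keys through a gazetteer.

    Rows with coordinates pass through unchanged; rows with only an address
    key are resolved via `gazetteer`. Unresolvable rows (no gazetteer, or a
    gazetteer miss) are collected in ``misses`` and excluded from the
    returned records, with a logged tally. Unknown facility kinds and rows
    with neither coordinates nor address key are hard errors.
    """
    df = pd.read_csv(
        path, sep=delimiter, dtype={"facility_id": str, "kind": str, "address_key": str}
    )
    for col in ("facility_id", "kind"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")

    records: list[FacilityRecord] = []
    misses: list[str] = []
    for i, row in enumerate(df.itertuples(index=False)):
        fid = str(row.facility_id)
        try:
            kind = FacilityKind(row.kind)
        except ValueError:
            raise ValidationError(
                f"{path}: row {i}: unknown facility kind {row.kind!r} "
                f"(expected one of {[k.value for k in FacilityKind]})"
            ) from None
        lon = getattr(row, "lon", None)
        lat = getattr(row, "lat", None)
        lon = None if lon is None or pd.isna(lon) else float(lon)
        lat = None if lat is None or pd.isna(lat) else float(lat)
        addr = getattr(row, "address_key", None)
        addr = None if addr is None or pd.isna(addr) else str(addr)
        if lon is not None and lat is not None:
            records.append(FacilityRecord(fid, kind, lon=lon, lat=lat, address_key=addr))
            continue
        if addr is None:
            raise ValidationError(
                f"{path}: row {i} (facility {fid!r}): neither coordinates nor address_key"
            )
        hit = gazetteer.resolve(addr) if gazetteer is not None else None
        if hit is None:
            misses.append(fid)
        else:
            records.append(FacilityRecord(fid, kind, lon=hit[0], lat=hit[1], address_key=addr))
    if misses:
        logger.warning(
            "%s: %d of %d facility rows unresolved by gazetteer (excluded): %s",
            path, len(misses), len(df), ", ".join(misses[:10]),
        )
    return FacilityReadResult(records=records, misses=misses)


def write_facilities(
    records: Iterable[FacilityRecord], path: PathLike, delimiter: str = ","
) -> None:
    """Write facility records as a delimited table (round-trips with
    :func:`read_facilities`)."""
    rows = [
        {
            "facility_id": r.facility_id,
            "kind": r.kind.value,
            "lon": r.lon,
            "lat": r.lat,
            "address_key": r.address_key,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(FACILITY_COLUMNS)).to_csv(path, sep=delimiter, index=False)


def read_need_table(
    path: PathLike,
    suppression_token: str = DEFAULT_SUPPRESSION_TOKEN,
    delimiter: str = ",",
) -> list[NeedRecord]:
    """Read a per-unit need table (5-year HIV incidence per 100 000).

    Entries equal to `suppression_token` become explicitly suppressed
    records, never zero. Negative incidence and duplicated unit ids are
    errors.
    """
    df = pd.read_csv(
        path, sep=delimiter, dtype=str, keep_default_na=False, na_values=[]
    )
    for col in NEED_COLUMNS:
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r}")
    records: list[NeedRecord] = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False)):
        unit_id = str(row.unit_id)
        if unit_id in seen:
            raise ValidationError(f"{path}: row {i}: duplicate unit_id {unit_id!r}")
        seen.add(unit_id)
        raw = str(row.incidence_per_100k).strip()
        if raw == suppression_token:
            records.append(NeedRecord(unit_id, None))
            continue
        try:
            value = float(raw)
        except ValueError:
            raise ValidationError(
                f"{path}: row {i}: incidence {raw!r} is neither numeric nor the "
                f"suppression token {suppression_token!r}"
            ) from None
        if value < 0:
            raise ValidationError(f"{path}: row {i}: negative incidence {value}")
        records.append(NeedRecord(unit_id, value))
    return records


def write_need_table(
    records: Iterable[NeedRecord],
    path: PathLike,
    suppression_token: str = DEFAULT_SUPPRESSION_TOKEN,
    delimiter: str = ",",
) -> None:
    """Write need records, encoding suppression with `suppression_token`."""
    rows = [
        {
            "unit_id": r.unit_id,
            "incidence_per_100k": suppression_token
            if r.suppressed
            else repr(r.incidence_per_100k),
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=list(NEED_COLUMNS)).to_csv(path, sep=delimiter, index=False)
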