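"""Point-in-polygon assignment of facilities to spatial units.

Containment is planar in raw lon/lat: at ZCTA/county scales the question
"which polygon holds this point" is topological, so no projection is
applied. Boundary-inclusive containment follows the even-odd rule; a point
lying exactly on a shared boundary (or inside overlapping slivers) is
assigned deterministically to the unit with the lexicographically smallest
unit_id. Facilities falling outside every unit — e.g. chain pharmacies
registered at out-of-region headquarters addresses — are not errors; they
accumulate in a per-class unassigned tally.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from shapely import STRtree
from shapely.geometry import Point

from pfnr.types import (
    FacilityKind,
    FacilityRecord,
    SpatialUnit,
    UnitCounts,
    ValidationError,
)

logger = logging.getLogger(__name__)


@dataclass
class AssignmentResult:
    """Per-unit facility counts plus per-class unassigned tallies.

    Conservation holds per class: assigned + unassigned = number of input
    facilities of that class.
    """

    counts: list[UnitCounts]
    unassigned: dict[FacilityKind, int] = field(default_factory=dict)

    def by_unit(self) -> dict[str, UnitCounts]:
        return {c.unit_id: c for c in self.counts}


def _check_overlaps(units: Sequence[SpatialUnit], tree: STRtree) -> None:
    """Warn on pairwise interior overlaps (real ZCTA products contain
    slivers; the tie-break makes assignment deterministic regardless)."""
    geoms = [u.geometry for u in units]
    left, right = tree.query(geoms, predicate="intersects")
    overlapping: list[tuple[str, str]] = []
    for i, j in zip(left, right):
        if i >= j:
            continue
        inter = geoms[i].intersection(geoms[j])
        if inter.area > 0:
            overlapping.append((units[i].unit_id, units[j].unit_id))
    if overlapping:
        warnings.warn(
            f"{len(overlapping)} pair(s) of units have interior overlaps "
            f"(e.g. {overlapping[0]}); points in overlaps go to the "
            "lexicographically smallest unit_id",
            stacklevel=3,
        )


def assign_facilities(
    facilities: Sequence[FacilityRecord],
    units: Sequence[SpatialUnit],
    check_overlaps: bool = True,
) -> AssignmentResult:
    """Assign each facility point to at most one containing unit.

    Returns zero-filled counts for every unit plus per-class unassigned
    tallies. Facilities still lacking coordinates are rejected.
    """
    if not units:
        raise ValidationError("assign_facilities: empty unit collection")
    for f in facilities:
        if not f.has_coords:
            raise ValidationError(
                f"facility {f.facility_id!r} has no coordinates (unresolved address?)"
            )

    order = sorted(range(len(units)), key=lambda i: units[i].unit_id)
    sorted_units = [units[i] for i in order]
    tree = STRtree([u.geometry for u in sorted_units])
    if check_overlaps:
        _check_overlaps(sorted_units, tree)

    prescribers = {u.unit_id: 0 for u in sorted_units}
    pharmacies = {u.unit_id: 0 for u in sorted_units}
    unassigned = {FacilityKind.PREP_PRESCRIBER: 0, FacilityKind.PHARMACY: 0}

    if facilities:
        points = [Point(f.lon, f.lat) for f in facilities]
        # covered_by is boundary-inclusive (even-odd interior + boundary)
        fac_idx, unit_idx = tree.query(points, predicate="covered_by")
        # tree geometries are in unit_id order, so the minimum index per
        # facility is the lexicographic tie-break
        best = np.full(len(facilities), -1, dtype=np.int64)
        for fi, ui in zip(fac_idx, unit_idx):
            if best[fi] == -1 or ui < best[fi]:
                best[fi] = ui
        for fi, f in enumerate(facilities):
            if best[fi] == -1:
                unassigned[f.kind] += 1
            else:
                uid = sorted_units[best[fi]].unit_id
                if f.kind is FacilityKind.PREP_PRESCRIBER:
                    prescribers[uid] += 1
                else:
                    pharmacies[uid] += 1

    counts = [
        UnitCounts(u.unit_id, n_prescribers=prescribers[u.unit_id], n_pharmacies=pharmacies[u.unit_id])
        for u in sorted_units
    ]
    n_un = sum(unassigned.values())
    if n_un:
        logger.info("assign_facilities: %d facility point(s) outside all units", n_un)
    return AssignmentResult(counts=counts, unassigned=unassigned)


def desert_summary(
    counts: Sequence[UnitCounts], kind: FacilityKind
) -> tuple[int, int]:
    """Count facility deserts: units with zero facilities of `kind`.

    `counts` must be zero-filled over all units of the region. Returns
    (n_units_without, n_units_total).
    """
    n_without = sum(1 for c in counts if c.count(kind) == 0)
    return n_without, len(counts)
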