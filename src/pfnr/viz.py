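"""Choropleth rendering and report-table output.

Maps show binned 5-year HIV incidence per unit with two facility point
overlays (prescribers, pharmacies). Suppressed units get a dedicated
hatched "no data" fill — conflating suppression with zero incidence would
misstate need. Pharmacy markers may be decimated for legibility (one marker
standing for k pharmacies, declared in the legend); decimation is display
only and never alters any count or ratio.

SVG output carries stable element ids (``unit-<id>``, ``nodata-<id>``,
``prescriber-layer``, ``pharmacy-layer``) so figures can be checked
structurally.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from matplotlib.collections import LineCollection
from matplotlib.lines import Line2D
from matplotlib.patches import PathPatch, Patch
from matplotlib.path import Path as MplPath

import pandas as pd

from pfnr.types import (
    FacilityKind,
    FacilityRecord,
    NeedRecord,
    RegionReport,
    SpatialUnit,
    ValidationError,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

#: Fixed default incidence bin edges (cases per 100 000 over 5 years); the
#: last bin is open ("400+"), matching common disease-mapping scales.
DEFAULT_BIN_EDGES = (0.0, 100.0, 200.0, 300.0, 400.0)


@dataclass
class MapSpec:
    """Rendering options for incidence choropleths."""

    bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES
    quantile_bins: bool = False  # derive edges from data quantiles instead
    n_quantile_bins: int = 5
    cmap: str = "YlOrRd"
    nodata_color: str = "0.85"
    nodata_hatch: str = "///"
    prescriber_marker: str = "^"
    prescriber_color: str = "tab:blue"
    pharmacy_marker: str = "o"
    pharmacy_color: str = "tab:green"
    pharmacy_decimation: int = 1  # one plotted marker represents k pharmacies

    def __post_init__(self) -> None:
        edges = tuple(float(e) for e in self.bin_edges)
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValidationError("bin edges must be strictly increasing")
        if self.pharmacy_decimation < 1:
            raise ValidationError("pharmacy decimation factor must be >= 1")
        self.bin_edges = edges


def _resolve_edges(spec: MapSpec, values: np.ndarray) -> tuple[float, ...]:
    if not spec.quantile_bins or values.size == 0:
        return spec.bin_edges
    qs = np.linspace(0, 1, spec.n_quantile_bins + 1)[:-1]
    edges = np.unique(np.quantile(values, qs))
    return tuple(float(e) for e in edges)


def _bin_labels(edges: Sequence[float]) -> list[str]:
    labels = [f"{lo:g}–{hi:g}" for lo, hi in zip(edges, edges[1:])]
    labels.append(f"{edges[-1]:g}+")
    return labels


def _polygon_path(geom) -> MplPath:
    """Compound matplotlib path for a shapely Polygon/MultiPolygon
    (exterior plus holes, even-odd fill)."""
    polys = geom.geoms if geom.geom_type == "MultiPolygon" else [geom]
    vertices: list[tuple[float, float]] = []
    codes: list[int] = []
    for poly in polys:
        for ring in [poly.exterior, *poly.interiors]:
            coords = list(ring.coords)
            vertices.extend(coords)
            codes.extend([MplPath.MOVETO] + [MplPath.LINETO] * (len(coords) - 2) + [MplPath.CLOSEPOLY])
    return MplPath(vertices, codes)


def render_map(
    units: Sequence[SpatialUnit],
    need: Sequence[NeedRecord],
    facilities: Sequence[FacilityRecord],
    spec: Optional[MapSpec] = None,
    out: PathLike = "map.svg",
    title: Optional[str] = None,
) -> Path:
    """Render the incidence choropleth with facility overlays to SVG or PNG
    (chosen by the output extension).

    Need records for units absent from the boundaries are warned about and
    skipped. Empty facility layers render without error.
    """
    spec = spec or MapSpec()
    unit_ids = {u.unit_id for u in units}
    need_by_unit: dict[str, NeedRecord] = {}
    for r in need:
        if r.unit_id not in unit_ids:
            warnings.warn(f"need record for unknown unit {r.unit_id!r} skipped", stacklevel=2)
            continue
        need_by_unit[r.unit_id] = r

    released = np.asarray(
        [r.incidence_per_100k for r in need_by_unit.values() if not r.suppressed],
        dtype=float,
    )
    edges = _resolve_edges(spec, released)
    labels = _bin_labels(edges)
    cmap = plt.get_cmap(spec.cmap, len(labels))

    fig, ax = plt.subplots(figsize=(8, 8))
    for u in sorted(units, key=lambda u: u.unit_id):
        rec = need_by_unit.get(u.unit_id)
        path = _polygon_path(u.geometry)
        if rec is None or rec.suppressed:
            patch = PathPatch(
                path, facecolor=spec.nodata_color, hatch=spec.nodata_hatch,
                edgecolor="white", linewidth=0.6,
            )
            patch.set_gid(f"nodata-{u.unit_id}")
        else:
            idx = int(np.searchsorted(edges, rec.incidence_per_100k, side="right") - 1)
            idx = max(0, min(idx, len(labels) - 1))
            patch = PathPatch(
                path, facecolor=cmap(idx), edgecolor="white", linewidth=0.6
            )
            patch.set_gid(f"unit-{u.unit_id}")
        ax.add_patch(patch)

    prescribers = [f for f in facilities if f.kind is FacilityKind.PREP_PRESCRIBER]
    pharmacies = [f for f in facilities if f.kind is FacilityKind.PHARMACY]
    plotted_pharm = _decimate_pharmacies(pharmacies, units, spec.pharmacy_decimation)

    sc_pr = ax.scatter(
        [f.lon for f in prescribers], [f.lat for f in prescribers],
        marker=spec.prescriber_marker, c=spec.prescriber_color,
        s=30, zorder=3, edgecolors="black", linewidths=0.4,
    )
    sc_pr.set_gid("prescriber-layer")
    sc_ph = ax.scatter(
        [f.lon for f in plotted_pharm], [f.lat for f in plotted_pharm],
        marker=spec.pharmacy_marker, c=spec.pharmacy_color,
        s=14, zorder=2, edgecolors="none", alpha=0.8,
    )
    sc_ph.set_gid("pharmacy-layer")

    handles = [
        Patch(facecolor=cmap(i), label=lab) for i, lab in enumerate(labels)
    ]
    handles.append(
        Patch(facecolor=spec.nodata_color, hatch=spec.nodata_hatch, label="No data (suppressed)")
    )
    handles.append(
        Line2D([], [], marker=spec.prescriber_marker, color=spec.prescriber_color,
               linestyle="", markeredgecolor="black", label="PrEP-prescribing location")
    )
    k = spec.pharmacy_decimation
    pharm_label = "Pharmacy" if k == 1 else f"Pharmacy (1 marker = {k} pharmacies)"
    handles.append(
        Line2D([], [], marker=spec.pharmacy_marker, color=spec.pharmacy_color,
               linestyle="", label=pharm_label)
    )
    ax.legend(handles=handles, loc="center left", bbox_to_anchor=(1.01, 0.5),
              title="5-year HIV incidence per 100 000", fontsize=8, title_fontsize=8)
    if title:
        ax.set_title(title)
    ax.set_xlabel("Longitude")
    ax.set_ylabel("Latitude")
    ax.autoscale_view()
    ax.set_aspect("equal")
    out = Path(out)
    fig.savefig(out, bbox_inches="tight")
    plt.close(fig)
    return out


def _decimate_pharmacies(
    pharmacies: Sequence[FacilityRecord],
    units: Sequence[SpatialUnit],
    k: int,
) -> list[FacilityRecord]:
    """Display-only thinning: within each unit, ceil(n/k) markers, so one
    marker stands for up to k pharmacies and no served unit renders empty.
    Unassigned pharmacies are thinned as one extra group."""
    if k == 1:
        return list(pharmacies)
    from shapely import STRtree
    from shapely.geometry import Point

    sorted_units = sorted(units, key=lambda u: u.unit_id)
    tree = STRtree([u.geometry for u in sorted_units])
    groups: dict[Optional[str], list[FacilityRecord]] = {}
    if pharmacies:
        fac_idx, unit_idx = tree.query(
            [Point(f.lon, f.lat) for f in pharmacies], predicate="covered_by"
        )
        best: dict[int, int] = {}
        for fi, ui in zip(fac_idx, unit_idx):
            if fi not in best or ui < best[fi]:
                best[fi] = int(ui)
        for fi, f in enumerate(pharmacies):
            uid = sorted_units[best[fi]].unit_id if fi in best else None
            groups.setdefault(uid, []).append(f)
    plotted: list[FacilityRecord] = []
    for uid in sorted(groups, key=lambda x: (x is None, x)):
        members = sorted(groups[uid], key=lambda f: f.facility_id)
        n_keep = math.ceil(len(members) / k)
        plotted.extend(members[:n_keep])
    return plotted


def _fmt(v: Optional[float], nd: int = 3) -> str:
    return "NA" if v is None else f"{v:.{nd}f}"


def _summary_display(s) -> str:
    """Table-style cell: mean (median [Q1-Q3])."""
    if not s.defined:
        return "NA"
    return f"{s.mean:.3f} ({s.median:.3f} [{s.q1:.3f}-{s.q3:.3f}])"


def report_frame(reports: Sequence[RegionReport]) -> pd.DataFrame:
    """Tabular form of region reports: one row per region, full-precision
    statistics plus display-rounded companion columns."""
    rows = []
    for r in reports:
        rows.append(
            {
                "region": r.region_id,
                "n_units": r.n_units_total,
                "n_units_used": r.n_units_used,
                "n_units_excluded": r.n_units_excluded,
                "n_suppressed_need": r.excluded_by_reason.get("suppressed_need", 0),
                "n_zero_need": r.excluded_by_reason.get("zero_need", 0),
                "prescriber_mean": r.prescriber_summary.mean,
                "prescriber_median": r.prescriber_summary.median,
                "prescriber_q1": r.prescriber_summary.q1,
                "prescriber_q3": r.prescriber_summary.q3,
                "prescriber_pfnr_display": _summary_display(r.prescriber_summary),
                "prescriber_deserts": r.n_prescriber_deserts,
                "pharmacy_mean": r.pharmacy_summary.mean,
                "pharmacy_median": r.pharmacy_summary.median,
                "pharmacy_q1": r.pharmacy_summary.q1,
                "pharmacy_q3": r.pharmacy_summary.q3,
                "pharmacy_pfnr_display": _summary_display(r.pharmacy_summary),
                "pharmacy_deserts": r.n_pharmacy_deserts,
                "fold_increase_raw": r.fold_increase,
                "fold_increase": "NA" if r.fold_increase is None else f"{r.fold_increase:.1f}",
                "fold_reason": r.fold_reason or "",
            }
        )
    return pd.DataFrame(rows)


def write_report(reports: Sequence[RegionReport], out: PathLike) -> Path:
    """Write the per-region report CSV (the pooled row, if supplied, is just
    another report, conventionally last)."""
    if not reports:
        raise ValidationError("write_report: no reports")
    out = Path(out)
    report_frame(reports).to_csv(out, index=False)
    return out
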