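"""Independent brute-force oracles, deliberately simple and free of any
dependence on the implementation paths they check."""

from __future__ import annotations

from typing import Sequence


def ray_cast_contains(x: float, y: float, rings: Sequence[Sequence[tuple[float, float]]]) -> bool:
    """Even-odd containment of (x, y) in a polygon given as rings
    (exterior + holes, or all rings of a multipolygon). Classic crossing
    count of a horizontal ray to +infinity."""
    inside = False
    for ring in rings:
        n = len(ring)
        # tolerate closed rings (first == last)
        pts = ring[:-1] if n > 1 and ring[0] == ring[-1] else ring
        m = len(pts)
        for i in range(m):
            x1, y1 = pts[i]
            x2, y2 = pts[(i + 1) % m]
            if (y1 > y) != (y2 > y):
                x_cross = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
                if x_cross > x:
                    inside = not inside
    return inside


def geom_rings(geom) -> list[list[tuple[float, float]]]:
    """All rings of a shapely Polygon/MultiPolygon as coordinate lists."""
    polys = geom.geoms if geom.geom_type == "MultiPolygon" else [geom]
    rings = []
    for poly in polys:
        for ring in [poly.exterior, *poly.interiors]:
            rings.append([(float(x), float(y)) for x, y in ring.coords])
    return rings


def shoelace_area(ring: Sequence[tuple[float, float]]) -> float:
    """Absolute polygon area of one ring by the shoelace formula."""
    pts = ring[:-1] if len(ring) > 1 and ring[0] == ring[-1] else list(ring)
    s = 0.0
    for i in range(len(pts)):
        x1, y1 = pts[i]
        x2, y2 = pts[(i + 1) % len(pts)]
        s += x1 * y2 - x2 * y1
    return abs(s) / 2.0


def quantile_sorted(values: Sequence[float], q: float) -> float:
    """Quantile by sorting and linear interpolation at position q*(n-1)."""
    v = sorted(values)
    pos = q * (len(v) - 1)
    lo = int(pos)
    hi = min(lo + 1, len(v) - 1)
    frac = pos - lo
    return v[lo] * (1 - frac) + v[hi] * frac


def mean_plain(values: Sequence[float]) -> float:
    return sum(values) / len(values)
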