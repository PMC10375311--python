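from __future__ import annotations

import json
from pathlib import Path

import pytest

from pfnr import ScenarioConfig, gen_units


def make_feature(unit_id: str, coords, level="zcta", region_id="R1", geom_type="Polygon"):
    return {
        "type": "Feature",
        "properties": {"unit_id": unit_id, "level": level, "region_id": region_id},
        "geometry": {"type": geom_type, "coordinates": coords},
    }


def square_coords(x0: float, y0: float, size: float = 1.0):
    return [[[x0, y0], [x0 + size, y0], [x0 + size, y0 + size], [x0, y0 + size], [x0, y0]]]


@pytest.fixture
def write_geojson(tmp_path):
    def _write(features, name="boundaries.geojson") -> Path:
        path = tmp_path / name
        path.write_text(json.dumps({"type": "FeatureCollection", "features": features}))
        return path

    return _write


@pytest.fixture
def grid3x3_units():
    """3x3 grid of unit squares anchored at the origin."""
    cfg = ScenarioConfig(grid_rows=3, grid_cols=3, cell_size_deg=1.0,
                         origin_lon=0.0, origin_lat=0.0)
    return gen_units(cfg)
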