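"""Seeded synthetic scenarios with known ground truth.

Emulates the structure of the study inputs without any licensed data: a
rectangular grid of spatial units standing in for ZCTAs; a strictly
positive, right-skewed (lognormal) incidence surface with optional
small-count suppression and occasional exact zeros; sparse PrEP-prescriber
points clustered around "downtown" kernel centers; and dense, spatially
homogeneous pharmacy points. Counts per unit are Poisson; placements are
uniform within the generating unit, so spatial assignment can recover the
generated counts exactly.

All randomness flows from one seed through named substreams (incidence,
pharmacies, prescribers), so adding a generator does not perturb existing
draws and identical configs produce byte-identical files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from shapely.geometry import box

from pfnr.io import write_boundaries, write_facilities, write_need_table
from pfnr.types import (
    FacilityKind,
    FacilityRecord,
    NeedRecord,
    SpatialUnit,
    UnitLevel,
    ValidationError,
)

PathLike = Union[str, Path]

# substream keys: adding a stream appends a key, never renumbers
_STREAM_INCIDENCE = 0
_STREAM_PHARMACY = 1
_STREAM_PRESCRIBER = 2


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of a synthetic scenario.

    Defaults sketch a metro-area ZCTA grid: 100 units of ~0.1° (~10 km),
    prescribers sparse (~0.5 expected per unit overall) and pulled toward a
    single central urban cluster, pharmacies dense (8 per unit) and
    homogeneous, incidence lognormal with median 150 per 100 000 over five
    years and a long upper tail, no suppression, and a 2% chance of an
    exactly-zero incidence estimate.
    """

    grid_rows: int = 10
    grid_cols: int = 10
    cell_size_deg: float = 0.1
    origin_lon: float = -84.9
    origin_lat: float = 33.4
    region_id: str = "R1"
    level: UnitLevel = UnitLevel.ZCTA
    unit_id_prefix: str = ""  # disambiguates unit ids when scenarios are merged
    # prescriber intensity = base + Gaussian kernel mixture at unit centroid
    prescriber_base_intensity: float = 0.1
    prescriber_clusters: tuple[tuple[float, float, float, float], ...] = (
        # (lon, lat, weight, bandwidth_deg): one downtown cluster at the grid center
        (-84.4, 33.9, 4.0, 0.15),
    )
    pharmacy_intensity: float = 8.0
    incidence_log_mean: float = 5.0  # exp(5.0) ≈ 148 per 100 000
    incidence_log_sd: float = 0.8
    suppression_prob: float = 0.0
    zero_incidence_prob: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValidationError("grid must have at least one cell")
        if self.cell_size_deg <= 0:
            raise ValidationError("cell_size_deg must be positive")
        if self.pharmacy_intensity < 0 or self.prescriber_base_intensity < 0:
            raise ValidationError("intensities must be non-negative")
        if any(w < 0 or bw <= 0 for (_, _, w, bw) in self.prescriber_clusters):
            raise ValidationError("cluster weights must be >= 0 and bandwidths > 0")
        for p, name in (
            (self.suppression_prob, "suppression_prob"),
            (self.zero_incidence_prob, "zero_incidence_prob"),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")

    def rng(self, stream: int) -> np.random.Generator:
        """Named substream of the scenario's seed."""
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(stream,)))


def gen_units(config: ScenarioConfig) -> list[SpatialUnit]:
    """Deterministic grid of axis-aligned rectangular units.

    Unit ids are "r{i}c{j}" (row-major, zero-padded so lexicographic order
    equals grid order); all units share one region."""
    pad_r = len(str(config.grid_rows - 1))
    pad_c = len(str(config.grid_cols - 1))
    # shared edge arrays so adjacent cells meet exactly (no sliver overlaps)
    xs = [config.origin_lon + j * config.cell_size_deg for j in range(config.grid_cols + 1)]
    ys = [config.origin_lat + i * config.cell_size_deg for i in range(config.grid_rows + 1)]
    units = []
    for i in range(config.grid_rows):
        for j in range(config.grid_cols):
            units.append(
                SpatialUnit(
                    unit_id=f"{config.unit_id_prefix}r{i:0{pad_r}d}c{j:0{pad_c}d}",
                    level=config.level,
                    region_id=config.region_id,
                    geometry=box(xs[j], ys[i], xs[j + 1], ys[i + 1]),
                )
            )
    return units


def gen_incidence(units: Sequence[SpatialUnit], config: ScenarioConfig) -> list[NeedRecord]:
    """Per-unit incidence: lognormal draws, zero-inflated, independently
    suppressed with `suppression_prob`. Fully determined by the seed."""
    rng = config.rng(_STREAM_INCIDENCE)
    records = []
    for u in units:
        value = float(rng.lognormal(config.incidence_log_mean, config.incidence_log_sd))
        if rng.random() < config.zero_incidence_prob:
            value = 0.0
        suppressed = rng.random() < config.suppression_prob
        records.append(NeedRecord(u.unit_id, None if suppressed else value))
    return records


def prescriber_intensity_at(config: ScenarioConfig, lon: float, lat: float) -> float:
    """Expected prescribers per unit at a location: base intensity plus a
    Gaussian kernel mixture over the configured cluster centers."""
    lam = config.prescriber_base_intensity
    for clon, clat, weight, bw in config.prescriber_clusters:
        d2 = (lon - clon) ** 2 + (lat - clat) ** 2
        lam += weight * math.exp(-d2 / (2.0 * bw * bw))
    return lam


def _scatter_in(unit: SpatialUnit, n: int, rng: np.random.Generator) -> np.ndarray:
    minx, miny, maxx, maxy = unit.geometry.bounds
    xs = rng.uniform(minx, maxx, size=n)
    ys = rng.uniform(miny, maxy, size=n)
    return np.column_stack([xs, ys])


@dataclass
class GeneratedFacilities:
    """Facilities plus the generator's own per-unit counts (ground truth for
    round-trip checks against spatial assignment)."""

    records: list[FacilityRecord]
    true_counts: dict[str, dict[str, int]] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.records)


def gen_facilities(
    units: Sequence[SpatialUnit], config: ScenarioConfig
) -> GeneratedFacilities:
    """Poisson facility counts per unit, placed uniformly inside the unit.

    Pharmacies are homogeneous (one intensity everywhere); prescribers use
    the kernel-mixture intensity evaluated at the unit centroid (a unit-level
    inhomogeneous Poisson process — urban clustering without a continuous
    Cox model). Rectangular units make uniform placement exact.
    """
    records: list[FacilityRecord] = []
    true_counts: dict[str, dict[str, int]] = {}
    rng_ph = config.rng(_STREAM_PHARMACY)
    rng_pr = config.rng(_STREAM_PRESCRIBER)
    for u in units:
        n_ph = int(rng_ph.poisson(config.pharmacy_intensity))
        for k, (x, y) in enumerate(_scatter_in(u, n_ph, rng_ph)):
            records.append(
                FacilityRecord(f"ph-{u.unit_id}-{k}", FacilityKind.PHARMACY, lon=float(x), lat=float(y))
            )
        c = u.geometry.centroid
        lam = prescriber_intensity_at(config, c.x, c.y)
        n_pr = int(rng_pr.poisson(lam))
        for k, (x, y) in enumerate(_scatter_in(u, n_pr, rng_pr)):
            records.append(
                FacilityRecord(
                    f"pr-{u.unit_id}-{k}", FacilityKind.PREP_PRESCRIBER, lon=float(x), lat=float(y)
                )
            )
        true_counts[u.unit_id] = {"n_pharmacies": n_ph, "n_prescribers": n_pr}
    return GeneratedFacilities(records=records, true_counts=true_counts)


@dataclass
class Scenario:
    """A fully generated scenario: inputs plus ground truth."""

    config: ScenarioConfig
    units: list[SpatialUnit]
    need: list[NeedRecord]
    facilities: GeneratedFacilities

    @property
    def expected_fold(self) -> Optional[float]:
        """Ground-truth expected fold increase when incidence is independent
        of facilities: pharmacy intensity over the mean prescriber intensity
        across units."""
        lams = [
            prescriber_intensity_at(self.config, u.geometry.centroid.x, u.geometry.centroid.y)
            for u in self.units
        ]
        mean_lam = float(np.mean(lams))
        if mean_lam == 0:
            return None
        return self.config.pharmacy_intensity / mean_lam


def generate_scenario(config: ScenarioConfig) -> Scenario:
    """Generate units, incidence and facilities for one config."""
    units = gen_units(config)
    return Scenario(
        config=config,
        units=units,
        need=gen_incidence(units, config),
        facilities=gen_facilities(units, config),
    )


def write_scenario(scenario: Scenario, out_dir: PathLike) -> dict[str, Path]:
    """Persist the three standard input files plus a ground-truth JSON.

    Writes boundaries.geojson, facilities.csv, need.csv and
    ground_truth.json (config, per-unit true counts, expected fold)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "boundaries": out / "boundaries.geojson",
        "facilities": out / "facilities.csv",
        "need": out / "need.csv",
        "ground_truth": out / "ground_truth.json",
    }
    write_boundaries(scenario.units, paths["boundaries"])
    write_facilities(scenario.facilities.records, paths["facilities"])
    write_need_table(scenario.need, paths["need"])
    cfg = asdict(scenario.config)
    cfg["level"] = scenario.config.level.value
    cfg["prescriber_clusters"] = [list(c) for c in scenario.config.prescriber_clusters]
    with open(paths["ground_truth"], "w") as fh:
        json.dump(
            {
                "config": cfg,
                "true_counts": scenario.facilities.true_counts,
                "expected_fold": scenario.expected_fold,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
    return paths
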