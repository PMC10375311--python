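"""End-to-end orchestration: ingest -> assign -> PFNR -> report/maps.

A run is driven by a single :class:`RunConfig` (loadable from YAML), so
everything that affects the numbers — suppression token, delimiter,
aggregate mode, map binning — is recorded in one auditable place. Outputs
are deterministic for fixed inputs; the run log records input row counts,
gazetteer misses, unassigned facilities and excluded units.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
import yaml
from shapely import STRtree
from shapely.geometry import Point

from pfnr.assign import assign_facilities
from pfnr.core import aggregate_pfnr, build_unit_metrics, pooled_report, region_report
from pfnr.io import (
    DEFAULT_SUPPRESSION_TOKEN,
    Gazetteer,
    read_boundaries,
    read_facilities,
    read_need_table,
)
from pfnr.synthetic import ScenarioConfig, generate_scenario, write_scenario
from pfnr.types import FacilityKind, FacilityRecord, SpatialUnit, ValidationError
from pfnr.viz import MapSpec, render_map, write_report

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

POOLED_REGION_ID = "all_regions"


@dataclass
class RunConfig:
    """Paths and analysis settings for one pipeline run."""

    out_dir: Path
    boundaries: Optional[Path] = None  # required for analyze; filled in by synth
    facilities: Optional[Path] = None
    need: Optional[Path] = None
    gazetteer: Optional[Path] = None
    suppression_token: str = DEFAULT_SUPPRESSION_TOKEN
    delimiter: str = ","
    aggregate_mode: bool = False
    render_maps: bool = True
    map_spec: MapSpec = field(default_factory=MapSpec)
    map_format: str = "svg"
    seed: int = 0  # used by the synthetic subcommand only

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        for name in ("boundaries", "facilities", "need", "gazetteer"):
            value = getattr(self, name)
            if value is not None:
                setattr(self, name, Path(value))

    @classmethod
    def from_yaml(cls, path: PathLike) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        map_doc = doc.pop("map", {}) or {}
        if "bin_edges" in map_doc:
            map_doc["bin_edges"] = tuple(map_doc["bin_edges"])
        known = {f.name for f in dataclasses.fields(cls)} - {"map_spec"}
        unknown = set(doc) - known
        if unknown:
            raise ValidationError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(map_spec=MapSpec(**map_doc), **doc)

    def validate_inputs(self) -> None:
        for name in ("boundaries", "facilities", "need"):
            p = getattr(self, name)
            if p is None or not p.exists():
                raise ValidationError(f"input path missing or does not exist: {name}={p}")


@dataclass
class RunArtifacts:
    """What a pipeline run produced, with in-memory results attached."""

    report_csv: Path
    maps: dict[str, Path]
    log_file: Path
    reports: list  # RegionReport, per region + pooled last
    metrics_by_region: dict[str, list]
    unassigned: dict[FacilityKind, int]
    aggregate_csv: Optional[Path] = None


def _facilities_in_units(
    facilities: Sequence[FacilityRecord], units: Sequence[SpatialUnit]
) -> list[FacilityRecord]:
    if not facilities:
        return []
    tree = STRtree([u.geometry for u in units])
    idx, _ = tree.query(
        [Point(f.lon, f.lat) for f in facilities], predicate="covered_by"
    )
    keep = set(int(i) for i in idx)
    return [f for i, f in enumerate(facilities) if i in keep]


def _setup_run_logger(log_file: Path) -> logging.Handler:
    handler = logging.FileHandler(log_file, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logging.getLogger("pfnr").addHandler(handler)
    logging.getLogger("pfnr").setLevel(logging.INFO)
    return handler


def run_analysis(config: RunConfig) -> RunArtifacts:
    """Execute the full analysis for one config.

    Stages: read and validate inputs; assign facilities to units; compute
    per-unit PFNRs; summarize per region and pooled; write the report CSV
    and one map per region. Stage failures propagate with the stage name.
    """
    config.validate_inputs()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_file = out / "run.log"
    handler = _setup_run_logger(log_file)
    try:
        logger.info("config: %s", config)
        stage = "read_boundaries"
        units = read_boundaries(config.boundaries)
        stage = "read_facilities"
        gaz = Gazetteer.from_csv(config.gazetteer) if config.gazetteer else None
        fac_result = read_facilities(config.facilities, gazetteer=gaz, delimiter=config.delimiter)
        stage = "read_need_table"
        need = read_need_table(
            config.need, suppression_token=config.suppression_token, delimiter=config.delimiter
        )
        logger.info(
            "inputs: %d units, %d facilities (%d gazetteer misses), %d need rows",
            len(units), len(fac_result.records), len(fac_result.misses), len(need),
        )

        stage = "assign_facilities"
        assignment = assign_facilities(fac_result.records, units)
        logger.info("unassigned facilities by class: %s",
                    {k.value: v for k, v in assignment.unassigned.items()})

        stage = "pfnr"
        metrics = build_unit_metrics(assignment.counts, need)
        region_of = {u.unit_id: u.region_id for u in units}
        metrics_by_region: dict[str, list] = {}
        for m in metrics:
            metrics_by_region.setdefault(region_of[m.unit_id], []).append(m)
        reports = [
            region_report(rid, ms) for rid, ms in sorted(metrics_by_region.items())
        ]
        reports.append(pooled_report(metrics_by_region, pooled_id=POOLED_REGION_ID))
        for r in reports:
            logger.info(
                "region %s: n_units=%d used=%d excluded=%d fold=%s",
                r.region_id, r.n_units_total, r.n_units_used, r.n_units_excluded,
                r.fold_increase if r.fold_increase is not None else f"NA ({r.fold_reason})",
            )

        stage = "write_report"
        report_csv = write_report(reports, out / "report.csv")

        aggregate_csv = None
        if config.aggregate_mode:
            stage = "aggregate_report"
            rows = []
            for rid, ms in sorted(metrics_by_region.items()):
                rows.append({
                    "region": rid,
                    "aggregate_pfnr_prescribers": aggregate_pfnr(ms, FacilityKind.PREP_PRESCRIBER),
                    "aggregate_pfnr_pharmacies": aggregate_pfnr(ms, FacilityKind.PHARMACY),
                })
            aggregate_csv = out / "aggregate_report.csv"
            pd.DataFrame(rows).to_csv(aggregate_csv, index=False)

        maps: dict[str, Path] = {}
        if config.render_maps:
            stage = "render_maps"
            units_by_region: dict[str, list[SpatialUnit]] = {}
            for u in units:
                units_by_region.setdefault(u.region_id, []).append(u)
            need_by_unit = {r.unit_id: r for r in need}
            for rid, runits in sorted(units_by_region.items()):
                rneed = [need_by_unit[u.unit_id] for u in runits if u.unit_id in need_by_unit]
                rfac = _facilities_in_units(fac_result.records, runits)
                maps[rid] = render_map(
                    runits, rneed, rfac, spec=config.map_spec,
                    out=out / f"map_{rid}.{config.map_format}",
                    title=f"5-year HIV incidence and facility locations — {rid}",
                )

        return RunArtifacts(
            report_csv=report_csv,
            maps=maps,
            log_file=log_file,
            reports=reports,
            metrics_by_region=metrics_by_region,
            unassigned=assignment.unassigned,
            aggregate_csv=aggregate_csv,
        )
    except Exception as exc:
        logger.error("stage %s failed: %s", stage, exc)
        raise type(exc)(f"[stage {stage}] {exc}") from exc
    finally:
        logging.getLogger("pfnr").removeHandler(handler)
        handler.close()


def run_synthetic(config: RunConfig, scenario: ScenarioConfig) -> RunArtifacts:
    """Generate a synthetic scenario, persist its input files (plus
    ground-truth JSON) under ``out_dir/inputs``, then analyze them."""
    out = Path(config.out_dir)
    scn = generate_scenario(scenario)
    paths = write_scenario(scn, out / "inputs")
    cfg = dataclasses.replace(
        config,
        boundaries=paths["boundaries"],
        facilities=paths["facilities"],
        need=paths["need"],
    )
    return run_analysis(cfg)
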