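"""PFNR computation: per-unit ratios, regional summaries, fold increase.

The PrEP facility-to-need ratio (PFNR) of a unit is its facility count
divided by its 5-year HIV incidence per 100 000 persons; lower values mean
lower geographic availability relative to need. Units whose incidence is
suppressed or zero have no defined ratio: they are excluded from summaries
and counted, never imputed or treated as zero need.

Summaries report mean, median and quartiles of the defined per-unit PFNRs.
Quartiles use linear interpolation between order statistics at positions
0.25·(n−1) and 0.75·(n−1) — pinned explicitly because quantile conventions
differ across software. The pharmacy-expansion fold increase is the ratio of
the full-precision class means (medians are frequently zero, which would
leave the ratio undefined).

An aggregate mode (region-total facilities over region-total incidence) is
available via :func:`aggregate_pfnr` for sensitivity analysis; the default
per-unit-then-summarize mode is what produces median/IQR columns.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from pfnr.types import (
    ClassSummary,
    ExclusionReason,
    FacilityKind,
    NeedRecord,
    RegionReport,
    SpatialUnit,
    UnitCounts,
    UnitMetrics,
    ValidationError,
)
from pfnr.assign import desert_summary


def compute_unit_pfnr(
    facility_count: int, incidence_per_100k: Optional[float]
) -> tuple[Optional[float], Optional[ExclusionReason]]:
    """Facility count divided by incidence; undefined on suppressed or zero
    incidence.

    Returns (pfnr, None) when incidence is present and positive, otherwise
    (None, reason). Zero facilities over positive incidence is a defined
    PFNR of 0.0.
    """
    if facility_count < 0:
        raise ValidationError(f"negative facility count {facility_count}")
    if incidence_per_100k is None:
        return None, ExclusionReason.SUPPRESSED_NEED
    if incidence_per_100k == 0:
        return None, ExclusionReason.ZERO_NEED
    return facility_count / incidence_per_100k, None


def build_unit_metrics(
    counts: Sequence[UnitCounts],
    need: Sequence[NeedRecord],
) -> list[UnitMetrics]:
    """Join zero-filled facility counts with the need table into per-unit
    metrics. Units absent from the need table are treated as suppressed."""
    need_by_unit = {r.unit_id: r for r in need}
    metrics: list[UnitMetrics] = []
    for c in counts:
        rec = need_by_unit.get(c.unit_id)
        incidence = None if rec is None else rec.incidence_per_100k
        pfnr_prep, reason = compute_unit_pfnr(c.n_prescribers, incidence)
        pfnr_pharm, _ = compute_unit_pfnr(c.n_pharmacies, incidence)
        metrics.append(
            UnitMetrics(
                unit_id=c.unit_id,
                n_prescribers=c.n_prescribers,
                n_pharmacies=c.n_pharmacies,
                incidence_per_100k=incidence,
                pfnr_prescribers=pfnr_prep,
                pfnr_pharmacies=pfnr_pharm,
                excluded_reason=reason,
            )
        )
    return metrics


def _summarize(values: np.ndarray) -> ClassSummary:
    if values.size == 0:
        return ClassSummary(mean=None, median=None, q1=None, q3=None, n_used=0)
    q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75], method="linear")
    return ClassSummary(
        mean=float(np.mean(values)),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        n_used=int(values.size),
    )


def summarize_region(
    metrics: Sequence[UnitMetrics], kind: FacilityKind
) -> ClassSummary:
    """Mean/median/Q1/Q3 over the defined unit PFNRs of one facility class.

    Excluded units (suppressed or zero need) contribute nothing; an
    all-excluded input yields an undefined summary (n_used == 0).
    """
    values = np.asarray(
        [m.pfnr(kind) for m in metrics if m.defined], dtype=float
    )
    return _summarize(values)


def fold_increase(mean_pharm: float, mean_prep: float) -> Optional[float]:
    """Pharmacy-expansion fold increase: mean pharmacy PFNR over mean
    prescriber PFNR, at full precision.

    Returns None ("no current access") when the prescriber mean is zero.
    A non-positive pharmacy mean is an upstream reporting condition, not a
    valid input here.
    """
    if mean_pharm <= 0:
        raise ValidationError(
            f"fold_increase: mean pharmacy PFNR must be positive, got {mean_pharm}"
        )
    if mean_prep < 0:
        raise ValidationError(f"fold_increase: negative prescriber mean {mean_prep}")
    if mean_prep == 0:
        return None
    return mean_pharm / mean_prep


def _fold_from_summaries(
    prep: ClassSummary, pharm: ClassSummary
) -> tuple[Optional[float], Optional[str]]:
    if not prep.defined or not pharm.defined:
        return None, "no_defined_units"
    if pharm.mean <= 0:
        return None, "no_pharmacy_access"
    fold = fold_increase(pharm.mean, prep.mean)
    if fold is None:
        return None, "no_current_access"
    return fold, None


def region_report(
    region_id: str,
    metrics: Sequence[UnitMetrics],
) -> RegionReport:
    """Assemble the per-region report: class summaries, fold increase and
    desert counts. Desert counts run over ALL units of the region (they do
    not depend on incidence); PFNR summaries run over defined units only."""
    counts = [
        UnitCounts(m.unit_id, n_prescribers=m.n_prescribers, n_pharmacies=m.n_pharmacies)
        for m in metrics
    ]
    prep = summarize_region(metrics, FacilityKind.PREP_PRESCRIBER)
    pharm = summarize_region(metrics, FacilityKind.PHARMACY)
    fold, reason = _fold_from_summaries(prep, pharm)
    n_prep_des, n_total = desert_summary(counts, FacilityKind.PREP_PRESCRIBER)
    n_pharm_des, _ = desert_summary(counts, FacilityKind.PHARMACY)
    excluded = [m for m in metrics if not m.defined]
    by_reason: dict[str, int] = {}
    for m in excluded:
        key = m.excluded_reason.value
        by_reason[key] = by_reason.get(key, 0) + 1
    return RegionReport(
        region_id=region_id,
        prescriber_summary=prep,
        pharmacy_summary=pharm,
        fold_increase=fold,
        fold_reason=reason,
        n_prescriber_deserts=n_prep_des,
        n_pharmacy_deserts=n_pharm_des,
        n_units_total=n_total,
        n_units_used=prep.n_used,
        n_units_excluded=len(excluded),
        excluded_by_reason=by_reason,
    )


def pooled_report(
    metrics_by_region: dict[str, Sequence[UnitMetrics]],
    pooled_id: str = "all_regions",
) -> RegionReport:
    """Pooled report over the union of all regions' units.

    The identical per-unit algorithm is applied to the pooled unit set —
    NOT the mean of region means (the pooled mean is the count-weighted
    combination of region means).
    """
    if not metrics_by_region:
        raise ValidationError("pooled_report: no regions")
    pooled: list[UnitMetrics] = []
    for ms in metrics_by_region.values():
        pooled.extend(ms)
    return region_report(pooled_id, pooled)


def aggregate_pfnr(
    metrics: Sequence[UnitMetrics], kind: FacilityKind
) -> Optional[float]:
    """Aggregate-mode ratio: region-total facilities over region-total
    incidence, summed over units with a released positive incidence.
    Sensitivity alternative to the per-unit summaries; None when no unit
    has usable incidence."""
    total_fac = 0
    total_inc = 0.0
    for m in metrics:
        if m.defined:
            total_fac += m.n_prescribers if kind is FacilityKind.PREP_PRESCRIBER else m.n_pharmacies
            total_inc += m.incidence_per_100k
    if total_inc == 0:
        return None
    return total_fac / total_inc
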