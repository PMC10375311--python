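"""PFNR arithmetic, regional summaries, fold increase, pooling, and the
scale/monotonicity/direction properties of the ratio."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pfnr import (
    FacilityKind,
    NeedRecord,
    UnitCounts,
    build_unit_metrics,
    compute_unit_pfnr,
    fold_increase,
    pooled_report,
    region_report,
    summarize_region,
)
from pfnr.core import _summarize, aggregate_pfnr
from pfnr.types import ExclusionReason, UnitMetrics, ValidationError

from _oracles import mean_plain, quantile_sorted


def _metrics_from(counts_and_incidence):
    counts = [UnitCounts(f"u{i}", p, ph) for i, (p, ph, _) in enumerate(counts_and_incidence)]
    need = [NeedRecord(f"u{i}", inc) for i, (_, _, inc) in enumerate(counts_and_incidence)]
    return build_unit_metrics(counts, need)


class TestComputeUnitPfnr:
    @pytest.mark.parametrize(
        "count,incidence,expected",
        [(0, 150.0, 0.0), (12, 300.0, 0.04), (3, 150.0, 0.02)],
    )
    def test_defined_ratio(self, count, incidence, expected):
        value, reason = compute_unit_pfnr(count, incidence)
        assert value == pytest.approx(expected, rel=1e-15)
        assert reason is None

    def test_suppressed_need_undefined_with_reason(self):
        value, reason = compute_unit_pfnr(5, None)
        assert value is None and reason is ExclusionReason.SUPPRESSED_NEED

    def test_zero_need_undefined_with_reason(self):
        value, reason = compute_unit_pfnr(5, 0.0)
        assert value is None and reason is ExclusionReason.ZERO_NEED

    def test_negative_count_rejected(self):
        with pytest.raises(ValidationError):
            compute_unit_pfnr(-1, 100.0)

    def test_zero_iff_no_facilities(self):
        assert compute_unit_pfnr(0, 50.0)[0] == 0.0
        assert compute_unit_pfnr(1, 1e9)[0] > 0.0


class TestSummarizeRegion:
    def test_singleton(self):
        metrics = _metrics_from([(1, 1, 10.0)])  # pfnr 0.1 both classes
        s = summarize_region(metrics, FacilityKind.PHARMACY)
        assert s.mean == s.median == s.q1 == s.q3 == pytest.approx(0.1)
        assert s.n_used == 1

    def test_majority_zero_median(self):
        # unit pfnrs {0, 0, 0, 0.004, 0.012}
        rows = [(0, 0, 100.0), (0, 0, 100.0), (0, 0, 100.0), (2, 2, 500.0), (6, 6, 500.0)]
        s = summarize_region(_metrics_from(rows), FacilityKind.PREP_PRESCRIBER)
        assert s.median == 0.0
        assert s.mean == pytest.approx((0.004 + 0.012) / 5, rel=1e-12)

    def test_matches_sort_and_interpolate_oracle_on_200_values(self):
        rng = np.random.default_rng(202)
        values = rng.lognormal(-3.0, 1.2, size=200)
        s = _summarize(values)
        assert s.mean == pytest.approx(mean_plain(values.tolist()), rel=1e-12)
        for got, q in ((s.q1, 0.25), (s.median, 0.5), (s.q3, 0.75)):
            assert got == pytest.approx(quantile_sorted(values.tolist(), q), rel=1e-12)

    def test_all_excluded_gives_undefined_summary(self):
        metrics = _metrics_from([(1, 1, None), (2, 2, 0.0)])
        s = summarize_region(metrics, FacilityKind.PHARMACY)
        assert not s.defined and s.mean is None and s.n_used == 0

    def test_excluded_units_not_imputed(self):
        with_suppressed = _metrics_from([(1, 1, 100.0), (5, 5, None)])
        without = _metrics_from([(1, 1, 100.0)])
        assert summarize_region(with_suppressed, FacilityKind.PHARMACY) == summarize_region(
            without, FacilityKind.PHARMACY
        )


class TestFoldIncrease:
    def test_direct_arithmetic(self):
        # note: ratios of display-rounded means differ from full-precision folds
        assert fold_increase(0.7, 0.008) == pytest.approx(87.5)

    @given(st.floats(min_value=1e-6, max_value=1e6, allow_nan=False))
    @settings(max_examples=30, deadline=None)
    def test_identity(self, x):
        assert fold_increase(x, x) == pytest.approx(1.0)

    def test_zero_prescriber_mean_is_undefined_not_error(self):
        assert fold_increase(0.5, 0.0) is None

    def test_nonpositive_pharmacy_mean_rejected(self):
        with pytest.raises(ValidationError):
            fold_increase(0.0, 0.1)


class TestRegionReport:
    def test_exclusion_accounting(self):
        rows = [(1, 4, 100.0), (0, 2, None), (2, 3, 0.0), (1, 1, 250.0)]
        report = region_report("R1", _metrics_from(rows))
        assert report.n_units_used + report.n_units_excluded == report.n_units_total == 4
        assert report.excluded_by_reason == {"suppressed_need": 1, "zero_need": 1}

    def test_desert_counts_cover_all_units_regardless_of_need(self):
        rows = [(0, 0, None), (0, 1, 100.0), (1, 2, 0.0)]
        report = region_report("R1", _metrics_from(rows))
        assert report.n_prescriber_deserts == 2
        assert report.n_pharmacy_deserts == 1

    def test_no_current_access_reported(self):
        rows = [(0, 2, 100.0), (0, 3, 50.0)]
        report = region_report("R1", _metrics_from(rows))
        assert report.fold_increase is None
        assert report.fold_reason == "no_current_access"

    def test_quartile_ordering_invariant(self):
        rng = np.random.default_rng(5)
        rows = [(int(rng.poisson(0.5)), int(rng.poisson(8)), float(rng.lognormal(5, 1)))
                for _ in range(50)]
        report = region_report("R1", _metrics_from(rows))
        for s in (report.prescriber_summary, report.pharmacy_summary):
            assert s.q1 <= s.median <= s.q3


class TestPooledReport:
    def test_single_region_identity(self):
        rows = [(1, 4, 100.0), (0, 2, 250.0), (2, 9, 400.0)]
        metrics = _metrics_from(rows)
        single = region_report("R1", metrics)
        pooled = pooled_report({"R1": metrics})
        assert pooled.prescriber_summary == single.prescriber_summary
        assert pooled.pharmacy_summary == single.pharmacy_summary
        assert pooled.fold_increase == single.fold_increase

    def test_pooled_mean_is_count_weighted_combination(self):
        rng = np.random.default_rng(99)
        regions = {}
        for rid, n in (("A", 30), ("B", 70)):
            rows = [(int(rng.poisson(0.6)), int(rng.poisson(7)), float(rng.lognormal(5, 0.9)))
                    for _ in range(n)]
            counts = [UnitCounts(f"{rid}{i}", p, ph) for i, (p, ph, _) in enumerate(rows)]
            need = [NeedRecord(f"{rid}{i}", inc) for i, (_, _, inc) in enumerate(rows)]
            regions[rid] = build_unit_metrics(counts, need)
        pooled = pooled_report(regions)
        parts = [region_report(rid, ms) for rid, ms in regions.items()]
        for kind_attr in ("prescriber_summary", "pharmacy_summary"):
            weighted = sum(
                getattr(p, kind_attr).mean * getattr(p, kind_attr).n_used for p in parts
            ) / sum(getattr(p, kind_attr).n_used for p in parts)
            assert getattr(pooled, kind_attr).mean == pytest.approx(weighted, rel=1e-12)
        assert pooled.n_units_used == sum(p.n_units_used for p in parts)

    def test_pooled_is_not_mean_of_region_means(self):
        # deliberately unbalanced regions: pooling by units must differ
        ra = _metrics_from([(1, 10, 100.0)])
        rb = _metrics_from([(0, 1, 100.0)] * 9)
        pooled = pooled_report({"A": ra, "B": rb})
        naive = (
            summarize_region(ra, FacilityKind.PHARMACY).mean
            + summarize_region(rb, FacilityKind.PHARMACY).mean
        ) / 2
        assert pooled.pharmacy_summary.mean != pytest.approx(naive, rel=1e-6)


class TestRatioProperties:
    @pytest.mark.parametrize("c", [0.1, 2.0, 10.0])
    def test_scaling_incidence_divides_pfnrs_and_preserves_fold(self, c):
        rng = np.random.default_rng(17)
        rows = [(int(rng.poisson(0.5)), int(rng.poisson(8)), float(rng.lognormal(5, 1)))
                for _ in range(60)]
        base = region_report("R1", _metrics_from(rows))
        scaled_rows = [(p, ph, inc * c if inc is not None else None) for p, ph, inc in rows]
        scaled = region_report("R1", _metrics_from(scaled_rows))
        assert scaled.pharmacy_summary.mean == pytest.approx(
            base.pharmacy_summary.mean / c, rel=1e-12
        )
        assert scaled.fold_increase == pytest.approx(base.fold_increase, rel=1e-12)

    def test_adding_a_pharmacy_cannot_decrease_mean_or_fold(self):
        rows = [(1, 2, 100.0), (1, 3, 200.0), (2, 1, 50.0)]
        base = region_report("R1", _metrics_from(rows))
        bumped_rows = [(1, 3, 100.0)] + rows[1:]
        bumped = region_report("R1", _metrics_from(bumped_rows))
        assert bumped.pharmacy_summary.mean >= base.pharmacy_summary.mean
        assert bumped.fold_increase >= base.fold_increase

    @given(
        st.integers(min_value=0, max_value=20),
        st.integers(min_value=1, max_value=20),
        st.floats(min_value=1.0, max_value=1e4, allow_nan=False),
    )
    @settings(max_examples=50, deadline=None)
    def test_fewer_facilities_means_lower_pfnr_pointwise(self, n, extra, incidence):
        lo, _ = compute_unit_pfnr(n, incidence)
        hi, _ = compute_unit_pfnr(n + extra, incidence)
        assert lo < hi


class TestAggregatePfnr:
    def test_totals_over_usable_units(self):
        rows = [(1, 4, 100.0), (2, 6, 100.0), (5, 5, None)]
        metrics = _metrics_from(rows)
        assert aggregate_pfnr(metrics, FacilityKind.PHARMACY) == pytest.approx(10 / 200.0)
        assert aggregate_pfnr(metrics, FacilityKind.PREP_PRESCRIBER) == pytest.approx(3 / 200.0)

    def test_no_usable_incidence_gives_none(self):
        assert aggregate_pfnr(_metrics_from([(1, 1, None)]), FacilityKind.PHARMACY) is None
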