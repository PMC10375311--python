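# Methods

## The measure and its assumptions

The PrEP facility-to-need ratio (PFNR) of a spatial unit is the count of
service locations of one class (PrEP-prescribing locations or pharmacies)
divided by the unit's cumulative 5-year HIV incidence per 100 000 persons.
It is a presence/density measure: it assumes every location has equal and
unbounded service capacity, ignores travel across unit boundaries, and
treats incidence as a proxy for prevention need. It is not a catchment or
gravity model (no distance decay, no two-step floating catchment), and it
provides no inferential uncertainty — the package reports distributional
summaries, not confidence intervals.

Two unit-level degeneracies make the ratio undefined: suppressed incidence
(small-count privacy suppression by the surveillance source) and measured
zero incidence (a ratio "to need" is meaningless at zero measured need).
Both are excluded from summaries and tallied separately
(`n_units_excluded`, split by reason); suppression is carried as an
explicit state end to end and is never conflated with zero — on maps it
gets a dedicated hatched fill.

### Per-unit-then-summarize vs aggregate mode

Regional results are summaries (mean, median, Q1, Q3) of the per-unit PFNR
distribution; only a per-unit distribution admits a median and IQR, and it
is what exposes within-region inequity. An aggregate mode — region-total
facilities over region-total incidence, over units with usable need — is
available behind `aggregate_mode` as a sensitivity analysis; it answers a
slightly different question (region-average availability) and hides
within-region deserts.

### Fold increase

The pharmacy-expansion fold increase is the ratio of the full-precision
class means. Means rather than medians because the median prescriber PFNR
is typically exactly 0 (most units have no prescriber), which would leave
the ratio undefined; full precision because ratios of display-rounded
means can differ noticeably from the true ratio. When the prescriber mean
is 0 the fold is reported as undefined with reason `no_current_access`
(infinite relative improvement is not a meaningful number); a region with
no pharmacies at all reports `no_pharmacy_access`.

As a ratio of means, the estimator carries the usual Jensen-type
finite-sample bias of order CV²/n (the denominator's squared coefficient
of variation over the number of units): simulations at 400 units with
sparse prescribers (intensity 0.5/unit) show an expected estimate of
≈ 30.3 when the true ratio is 30, about +1%. Verification therefore checks
that the truth lies within the estimator's Monte-Carlo 95% sampling
interval across replicates, not that the estimator is exactly unbiased at
finite n.

## Spatial assignment

Facilities are assigned to units by planar point-in-polygon containment in
raw lon/lat (WGS84). No projection is applied: containment is a
topological question and ZCTA/county polygons and their points share one
coordinate system. Containment is boundary-inclusive (shapely
`covered_by`, equivalent to the even-odd rule plus boundary); a point on a
shared boundary — or inside an overlap, since real ZCTA products contain
slivers — is assigned to the unit with the lexicographically smallest
`unit_id`, a deterministic, input-order-independent tie-break. Overlapping
unit interiors raise a data-quality warning, not an error. Points covered
by no unit (e.g. chain pharmacies registered at out-of-state headquarters
addresses) accumulate in a per-class `unassigned` tally; conservation
(assigned + unassigned = input count, per class) is asserted in tests.
Assignment is validated against an independent brute-force ray-casting
oracle on seeded random points.

Geocoding is offline by design: a `Gazetteer` is a deterministic
address-key → (lon, lat) table, and unknown keys are explicit misses that
are tallied, logged and excluded — never silently defaulted. Live
geocoding services are out of scope; the interface is pluggable.

## Quantile convention

Quartiles interpolate linearly between order statistics at positions
0.25·(n−1) and 0.75·(n−1) (numpy's `linear` method). Pinned explicitly
because software disagrees on quantile conventions and the choice moves
IQRs on small regions. The pooled (all-regions) report applies the
identical per-unit algorithm to the union of all units' defined PFNRs —
not the mean of region means — so the pooled mean is the
count-weighted combination of region means (asserted to 12 significant
digits in tests).

## Synthetic scenarios

The generator emulates the structure of the study's inputs so every stage
is testable offline with known ground truth:

| parameter | default | rationale |
|---|---|---|
| grid | 10×10 units of 0.1° (~10 km) | metro-area ZCTA scale and count |
| prescriber intensity | 0.1/unit base + Gaussian kernel (weight 4, bandwidth 0.15°) at the grid center | sparse, urban-clustered prescribing locations (~0.5/unit overall) |
| pharmacy intensity | 8/unit, homogeneous | dense, evenly spread pharmacies (hundreds per ~100 ZCTAs) |
| incidence | lognormal(μ=5.0, σ=0.8) per 100 000 | strictly positive, right-skewed small-area risk with median ≈ 150 and a long upper tail |
| zero-incidence probability | 0.02 | occasional units with measured zero risk, as in low-burden counties |
| suppression probability | 0 (scenario-dependent) | surveillance suppression, state-dependent in reality |

Counts per unit are Poisson; placements are uniform within the generating
(rectangular) unit, so spatial assignment recovers the generated counts
exactly — a round-trip asserted in tests. Prescriber clustering is a
unit-level inhomogeneous Poisson process (kernel mixture evaluated at unit
centroids) rather than a continuous Cox process: simpler, and sufficient
to reproduce qualitative urban clustering. All randomness flows from one
seed through named substreams (incidence, pharmacies, prescribers), so
adding a generator never perturbs existing draws, and identical configs
yield byte-identical files. Grid cell edges are computed from shared edge
arrays so adjacent cells meet exactly (no floating-point slivers).

What the generator does **not** emulate: population size and density
(PFNR uses incidence only, so no denominator model is needed), real street
addresses, spatial autocorrelation of incidence beyond the lognormal
marginal, correlation between facility placement and need, and
multi-level (ZCTA within county) nesting. Passing tests therefore show the
pipeline's arithmetic, accounting and geometry are correct under known
conditions — not that any particular real region looks like a scenario.

Verification problem sizes — 1 000 points for the containment oracle,
100-unit scenarios for accounting, 400 units × 100 replicates for fold
recovery, 500 units for desert closed forms — were chosen so each check
has clear statistical resolution while the whole suite runs in well under
a minute.

## Numerical and rendering choices

- Desert closed form: with Poisson(λ) counts, P(unit is a desert) = e^(−λ);
  observed fractions are checked against 99% binomial bounds (λ=9 for
  pharmacies → almost no deserts; λ=0.3 for prescribers → ~74% deserts,
  reproducing the qualitative prescriber/pharmacy contrast).
- Map bins default to fixed 100-unit steps capped at "400+"; quantile
  binning is available (`MapSpec.quantile_bins`). Suppressed units render
  in a hatched "no data" fill distinct from the 0–100 bin.
- Pharmacy markers can be decimated k:1 for legibility (legend declares
  the factor). Per unit, ⌈n/k⌉ markers are drawn so a served unit never
  renders empty. Decimation is display-only; tests assert report output is
  unchanged by it.
- Report CSV: one row per region plus a pooled `all_regions` row;
  full-precision statistics plus display columns (`mean (median [Q1-Q3])`
  at 3 decimals, fold at 1 decimal, undefined folds as `NA` with a reason
  column).
- Units present in boundaries but missing from the need table are treated
  as suppressed (excluded and counted) with a warning.

## Known limitations

Planar containment mishandles polygons spanning the antimeridian (not a
concern for the intended geography). The gazetteer is exact-key only — no
fuzzy address matching. Boundary-point assignment depends on exact
coordinate equality and is therefore sensitive to upstream coordinate
rounding. The fold increase inherits every limitation of the PFNR itself:
equal-capacity facilities, no travel model, incidence as the sole need
proxy.
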