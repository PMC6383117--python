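# Methods

## Scope and model

`cropshift` implements suitability-driven projection of crop
production areas in three stages: (1) fuzzy-logic land suitability on
a regular lat/lon grid, (2) a scenario rule engine classifying each
cell into one of four transition categories, (3) spherical-Earth area
accounting. A seeded synthetic geodata generator supplies inputs with
the statistical structure the method assumes, so the whole chain is
testable without global datasets.

### Suitability

Each environmental parameter is mapped to [0, 1] by a membership
function and the cell's suitability is the minimum over parameters
(law of the minimum). Design choices:

- **Membership shape.** Trapezoid with breakpoints x1 ≤ x2 ≤ x3 ≤ x4
  for continuous parameters: 0 outside [x1, x4], 1 on [x2, x3],
  linear ramps `(x−x1)/(x2−x1)` and `(x4−x)/(x4−x3)`. A degenerate
  ramp (x1 = x2 or x3 = x4) is a step. Texture class uses a
  class→score lookup. The trapezoid is the standard form in land
  evaluation and is exactly testable; no other shapes are offered.
- **Aggregation across parameters** is the strict minimum. Weighted
  or mean variants were deliberately rejected: they change the
  semantics from "most limiting factor" to a compensatory score.
- **Daily data.** The engine evaluates memberships on growing-season
  aggregates. When inputs arrive as daily series,
  `aggregate_season` reduces them over the crop's day-of-year window
  first (mean/sum/min/max per parameter, set in the requirement
  file), then membership is evaluated once. Evaluating per day and
  averaging afterwards is a defensible alternative; aggregate-first
  was chosen because it matches how the requirement breakpoints are
  expressed (seasonal means and sums) and keeps the pipeline
  deterministic in the number of membership evaluations.
- **Missing data.** A cell missing in *any* parameter has missing
  suitability and is excluded from percentile pools and category
  totals. Taking a minimum over the observed subset would be silently
  optimistic.
- The bundled maize/soybean requirement files are **illustrative**:
  plausible agronomic ranges chosen so that, on the synthetic fields,
  suitability spans [0, 1] with a meaningful fraction of zero cells.
  They are not a published crop parameterization and must not be used
  for real assessments.

### Transition rules

Cells are used (harvested-area fraction ≥ 1% of cell area) or not.
Per scenario, used cells are retained iff `LSf > f·LSt` (f = 0.9 for
`no_change`, 1.1 for `major_change`), else abandoned; not-used cells
are added iff `LSf > PERC_p(LSt over used cells)` (p = 33 / 67), else
unaltered. All inequalities are strict, with "≤" as the complement,
exactly as the rule table defines — including two literal
consequences that are asserted in tests rather than smoothed over:

- a used cell with `LSt = 0` is always abandoned under `no_change`
  (0 > 0.9·0 fails);
- with unchanged suitability, `major_change` abandons *every* used
  cell. A relative-change reading of the 10%-increase rule would
  behave differently at LSt = 0 only; the printed rule is
  implemented as-is and this edge is documented rather than
  reinterpreted.

Percentiles use linear interpolation between order statistics (the
"type 7" convention, numpy's default); the test-suite oracle encodes
the same convention independently (floor/ceil on `h = p(n−1)/100`).
The percentile pool is per-cell and unweighted by area, and is
computed per crop. Thresholds depend only on baseline data, so a
cell's classification is independent of other cells' futures.

### Area accounting

Cell area is `R²·Δλ·(sin φ_top − sin φ_bot)` on a sphere of
R = 6371.0 km (ellipsoidal corrections are < 0.3%, not worth a
geodesy dependency). Summed over a full global grid the band areas
telescope to 4πR² exactly (verified to 1e−6 relative in tests).
Category totals count whole cell areas, not harvested fractions: the
summaries measure the footprint of the production map. Conservation
(Σ categories + missing = grid total) holds to 1e−9 relative on every
run.

## Synthetic generator

The generator emulates three features of the real inputs: spatial
autocorrelation, a meridional temperature structure, and a land-use
mask concentrated on good land.

- **Fields** are Gaussian white noise smoothed with a Gaussian kernel
  of width `correlation_cells` (default 3 cells) and rescaled to the
  requested marginal sd, then clipped to physical bounds (pH ∈
  [3, 10], precipitation ≥ 0, …). Kernel smoothing was chosen over a
  geostatistical simulator because it is seedable, dependency-free
  and sufficient for the invariants under test.
- **Temperature** declines with |latitude| at 0.6 °C/deg (referenced
  to the grid's mean |latitude|), giving ≈ 50 °C equator-to-pole
  contrast so that a warming delta moves the suitable band poleward.
- **Climate delta**: warming `dT + g·|lat|` (a polar-amplification
  stand-in) and multiplicative precipitation scaling. Defaults used
  in examples and the acceptance run: dT = 3.5 °C, g = 0.08 °C/deg,
  precipitation ×1.05, late-century-like magnitudes.
- **Land use**: P(used) = expit(a + 6·LS), with the intercept solved
  by Brent's method so the expected used fraction equals the target
  (default 0.15); zero-suitability cells are never used. Used cells
  draw a harvested fraction uniformly on [0.01, 1] — exercising the
  1% used-cell rule exactly at its boundary — and all others get 0.
  The logistic link guarantees the property the percentile thresholds
  rely on: mean baseline suitability on used cells strictly exceeds
  that on not-used cells.
- Categorical texture is a smoothed latent field cut at equiprobable
  normal quantiles, keeping classes spatially coherent.

What the generator does **not** emulate: daily weather sequences,
covariance between parameters (fields are independent), realistic
marginal distributions, coastlines/land masks, and observed land-use
geography. Passing tests therefore demonstrate the correctness of the
rule engine and accounting, and qualitative behaviors (poleward
shift, scenario nesting) — not magnitudes for any real crop or region.

## Numerical choices and problem sizes

- All randomness flows through `numpy.random.default_rng(seed)`;
  fields are drawn in sorted parameter-name order, so output is
  independent of dict ordering and bit-reproducible per seed.
- Suitability grids, masks and rasters are float64 throughout; NetCDF
  round-trips are bit-identical, the text grid dialect prints 10
  significant digits.
- Examples and the acceptance run use a 60×120 (3°) global grid —
  large enough for ≈ 1000 used cells and stable percentile pools
  while keeping any run under a few seconds. Oracle cross-checks use
  100 random grids up to 50×50 (rule engine), 10⁴ twelve-parameter
  cells (min rule) and pools up to 10⁴ (percentiles), all exact.
- Degenerate inputs: an empty used-cell pool makes the percentile
  threshold (and hence the addition rule) undefined and raises; a
  single-cell pool returns that value for every percentile;
  infeasible land-use targets (more cells requested than have
  positive suitability) raise rather than silently saturate.

## Known limitations

- Crops are processed independently; there is no competition for
  cells or demand-side allocation.
- One working resolution per run; no resampling between suitability
  and production-map resolutions.
- The four-way classification ignores harvested-fraction magnitude
  beyond the 1% cutoff; area totals are whole-cell.
- The rule engine's thresholds (0.9/1.1, P33/P67) are fixed named
  scenarios; they parameterize demand narratives, not biophysics.
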