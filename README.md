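# cropshift

Projecting where crop production areas move under climate change.

`cropshift` is a small, fully tested pipeline for scenario-based
land-use-change projection on regular latitude/longitude grids. It is
aimed at land-systems and agro-climate researchers who want the
mechanics of suitability-driven land-use projection — fuzzy crop
suitability, percentile-threshold transition rules, latitude-aware
area accounting — as an importable, deterministic library, with a
seeded synthetic geodata generator standing in for the heavyweight
global climate/soil/land-use datasets such studies normally require.

## The model

**Land suitability.** For a crop *c* and grid cell *x*, each
environmental parameter *i* (growing-season mean temperature,
seasonal precipitation sum, solar radiation, soil pH, organic carbon,
salinity, sodicity, slope, elevation, available water capacity,
texture class) is scored by a fuzzy membership function
μᵢ(x) ∈ [0, 1] — trapezoidal for continuous parameters, a lookup
table for texture. Overall suitability follows the law of the
minimum:

    LS(x) = min_i μ_i(x)

so the most limiting factor alone governs. `LSt` denotes the baseline
surface, `LSf` the future one after a climate delta.

**Transition rules.** A cell is *used* when the crop's harvested-area
fraction is at least 1% of the cell. With `PERC_p(LSt)` the p-th
percentile of baseline suitability over used cells, two named
scenarios classify every cell:

| scenario | used cell stays used iff | not-used cell is added iff |
|---|---|---|
| `no_change` (rising demand) | LSf > 0.9 · LSt | LSf > PERC33(LSt) |
| `major_change` (falling demand) | LSf > 1.1 · LSt | LSf > PERC67(LSt) |

Inequalities are strict; the complement branches give *abandoned* and
*unaltered not-used*. Note the literal consequence: under
`major_change` with unchanged suitability every used cell is
abandoned, since LSf > 1.1·LSt can never hold when LSf = LSt.

**Area accounting.** Category maps become km² totals using spherical
cell areas `R²·Δλ·(sin φ_top − sin φ_bot)` with R = 6371 km, summed
per category (whole-cell areas, not harvested fractions).

## Worked example

`examples/03_project_transitions.py` generates a 60×120 synthetic
global grid, warms it by 3.5 °C plus 0.08 °C per degree of latitude,
and classifies maize cells under both scenarios:

```
used cells at baseline: 1027 (14.3% of the grid)

no_change: addition threshold = 0.620 (P33 of baseline suitability on used cells)
  unaltered_used       696 cells
  abandoned            331 cells
  added                789 cells
  unaltered_notused   5384 cells

major_change: addition threshold = 0.800 (P67 of baseline suitability on used cells)
  unaltered_used        86 cells
  abandoned            941 cells
  added                150 cells
  unaltered_notused   6023 cells
```

The higher retention bar (1.1 vs 0.9) and addition threshold (P67 vs
P33) make `major_change` abandon roughly three times as many cells
and add roughly five times fewer — the nesting direction the rule
algebra guarantees. Because warming is polar-amplified, the added
cells sit systematically poleward of the abandoned ones.

Other examples: `01_synthetic_fields.py` (generator and climate
delta), `02_suitability.py` (membership functions and the min rule),
`04_area_summary.py` (km² tables for both crops × both scenarios).

A thin CLI mirrors the stages:

```bash
cropshift simulate-data --n-lat 60 --n-lon 120 --seed 7 --dt 3.5 --out run/
cropshift suitability run/env_baseline.nc --crop maize --out run/lst.nc
cropshift run-all --seed 1 --out run/
```

Rasters travel as NetCDF (CF-style lat/lon, scipy backend) or a
plain-text grid dialect; crop requirements are YAML (the bundled
maize/soybean sets are illustrative, not a published
parameterization); summaries are CSV.

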