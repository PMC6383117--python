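"""Scenario rule engine: classify cells under both rule sets.

Shows the percentile thresholds over currently used cells and the
four-way cell classification under the no-change (retention factor
0.9, 33rd percentile) and major-change (1.1, 67th) scenarios.
"""

import numpy as np

from cropshift import (
    ClimateDelta,
    GridSpec,
    SCENARIOS,
    apply_climate_delta,
    bundled_requirements,
    classify_transitions,
    compute_suitability,
    generate_environment,
    generate_landuse,
)

spec = GridSpec(60, 120)
base = generate_environment(spec, seed=7)
fut = apply_climate_delta(base, ClimateDelta(dT=3.5, gradient_per_degree_lat=0.08))
reqs = bundled_requirements("maize")
lst = compute_suitability(base, reqs)
lsf = compute_suitability(fut, reqs)
mask = generate_landuse(lst, target_used_fraction=0.15, seed=8)
print(f"used cells at baseline: {mask.used.sum()} "
      f"({100 * mask.used.mean():.1f}% of the grid)")

for name, rules in SCENARIOS.items():
    tmap = classify_transitions(lst, lsf, mask, rules)
    counts = {c: int(tmap.category_mask(c).sum())
              for c in ("unaltered_used", "abandoned", "added", "unaltered_notused")}
    print(f"\n{name}: addition threshold = {tmap.threshold_used:.3f} "
          f"(P{rules.addition_percentile:.0f} of baseline suitability on used cells)")
    for c, n in counts.items():
        print(f"  {c:18s} {n:5d} cells")
# Under major change the retention bar is higher (LSf must exceed
# 1.1 x LSt), so more cells are abandoned and fewer are added.
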