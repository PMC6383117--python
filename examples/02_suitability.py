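"""Fuzzy membership functions and min-rule suitability.

Evaluates one trapezoidal membership function by hand, then computes
the full maize suitability surface on a synthetic grid and shows that
every cell's score equals its most limiting factor.
"""

import numpy as np

from cropshift import (
    GridSpec,
    MembershipFunction,
    bundled_requirements,
    compute_suitability,
    evaluate_membership,
    generate_environment,
)

mf = MembershipFunction(kind="trapezoid", breakpoints=(8, 16, 30, 40))
for t in (5, 12, 20, 35, 45):
    print(f"membership(T={t:2d} C) = {evaluate_membership(mf, float(t)):.2f}")
# 0 outside 8-40 C, 1 on the 16-30 C plateau, linear ramps between.

spec = GridSpec(40, 80)
env = generate_environment(spec, seed=7)
reqs = bundled_requirements("maize")  # illustrative requirement set
suit = compute_suitability(env, reqs)

vals = suit.values[~np.isnan(suit.values)]
print(f"\nmaize suitability: mean {vals.mean():.3f}, "
      f"{100 * (vals > 0).mean():.0f}% of cells above zero, "
      f"{100 * (vals > 0.8).mean():.0f}% above 0.8")

# law of the minimum: the score never exceeds any single component
comp = evaluate_membership(reqs.memberships["temperature"], env["temperature"])
ok = ~np.isnan(suit.values)
assert np.all(suit.values[ok] <= comp[ok] + 1e-12)
print("every cell is bounded by its temperature membership: the most "
      "limiting factor governs")
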