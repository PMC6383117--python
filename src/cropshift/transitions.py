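"""Scenario rule engine: four-way land-use transition classification.

Two named scenarios project each grid cell's land use forward:

* ``no_change`` — demand keeps rising; a used cell is retained if its
  future suitability exceeds 0.9 x its baseline suitability, and a
  not-used cell is added once future suitability exceeds the 33rd
  percentile of baseline suitability over currently used cells.
* ``major_change`` — demand falls; retention requires future
  suitability to exceed 1.1 x baseline (an increase of at least 10%),
  and addition requires exceeding the 67th percentile.

All comparisons are strict, with "<=" as the complement, exactly as
the rule table defines.  A literal consequence worth knowing: under
``major_change`` with unchanged suitability every used cell is
abandoned, because LSf > 1.1 * LSt can never hold when LSf == LSt
(except at LSt = 0, where 0 > 0 also fails).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import (
    CATEGORY_CODES,
    GridSpec,
    LandUseMask,
    SuitabilityGrid,
    TransitionMap,
)

__all__ = [
    "ScenarioRuleSet",
    "NO_CHANGE",
    "MAJOR_CHANGE",
    "SCENARIOS",
    "percentile_threshold",
    "classify_transitions",
]


@dataclass(frozen=True)
class ScenarioRuleSet:
    """Retention factor and addition percentile for one scenario.

    A used cell stays used iff ``LSf > retention_factor * LSt``; a
    not-used cell is added iff ``LSf > P_addition_percentile(LSt over
    used cells)``.
    """

    scenario: str
    retention_factor: float
    addition_percentile: float

    def __post_init__(self) -> None:
        if self.retention_factor <= 0:
            raise ValueError("retention_factor must be > 0")
        if not 0.0 <= self.addition_percentile <= 100.0:
            raise ValueError("addition_percentile must lie in [0, 100]")


NO_CHANGE = ScenarioRuleSet("no_change", retention_factor=0.9, addition_percentile=33.0)
MAJOR_CHANGE = ScenarioRuleSet("major_change", retention_factor=1.1, addition_percentile=67.0)
SCENARIOS: dict[str, ScenarioRuleSet] = {
    "no_change": NO_CHANGE,
    "major_change": MAJOR_CHANGE,
}


def percentile_threshold(lst: SuitabilityGrid, mask: LandUseMask, p: float) -> float:
    """p-th percentile of baseline suitability over used, non-missing cells.

    The pool is per-cell and unweighted by cell area; linear
    interpolation between order statistics (the "type 7" convention).
    """
    if lst.grid != mask.grid:
        raise ValueError("suitability and land-use mask are on different grids")
    pool = lst.values[mask.used & ~np.isnan(lst.values)]
    if pool.size == 0:
        raise ValueError(
            "no used, non-missing cells: the percentile threshold — and hence "
            "the addition rule for not-used cells — is undefined"
        )
    return float(np.percentile(pool, p, method="linear"))


def classify_transitions(
    lst: SuitabilityGrid,
    lsf: SuitabilityGrid,
    mask: LandUseMask,
    rules: ScenarioRuleSet,
) -> TransitionMap:
    """Classify every cell as unaltered-used / abandoned / added / unaltered-not-used.

    Used cells: ``unaltered_used`` iff LSf > f * LSt, else ``abandoned``.
    Not-used cells: ``added`` iff LSf > PERC_p(LSt over used cells),
    else ``unaltered_notused``.  Inequalities are strict.  Cells
    missing in LSt, LSf or the mask are coded missing.  The realized
    percentile threshold is recorded on the output.
    """
    if not (lst.grid == lsf.grid == mask.grid):
        raise ValueError(
            f"grid mismatch: LSt {lst.grid.shape}, LSf {lsf.grid.shape}, "
            f"mask {mask.grid.shape}"
        )
    if lst.period != "baseline" or lsf.period != "future":
        raise ValueError(
            f"expected baseline LSt and future LSf, got {lst.period!r} / {lsf.period!r}"
        )

    threshold = percentile_threshold(lst, mask, rules.addition_percentile)

    a, b = lst.values, lsf.values
    missing = np.isnan(a) | np.isnan(b) | mask.missing_mask()
    used = mask.used & ~missing

    codes = np.full(lst.grid.shape, CATEGORY_CODES["missing"], dtype=np.uint8)
    with np.errstate(invalid="ignore"):
        retained = b > rules.retention_factor * a
        added = b > threshold
    codes[used & retained] = CATEGORY_CODES["unaltered_used"]
    codes[used & ~retained] = CATEGORY_CODES["abandoned"]
    notused = ~used & ~missing
    codes[notused & added] = CATEGORY_CODES["added"]
    codes[notused & ~added] = CATEGORY_CODES["unaltered_notused"]

    return TransitionMap(
        grid=lst.grid,
        codes=codes,
        scenario=rules.scenario,
        crop=lst.crop,
        threshold_used=threshold,
        attrs={
            "retention_factor": rules.retention_factor,
            "addition_percentile": rules.addition_percentile,
            "threshold_used": threshold,
        },
    )
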