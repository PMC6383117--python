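"""Fuzzy-logic crop suitability: membership functions and min-aggregation.

A crop's requirements are a set of per-parameter membership functions,
each mapping one environmental value to a score in [0, 1].  Overall
suitability at a cell is the *minimum* of the component scores — the
law of the minimum: the most limiting factor alone determines how
suitable a location is.  Continuous parameters use trapezoidal
membership (zero outside [x1, x4], one on the plateau [x2, x3],
linear ramps between); categorical parameters use a class-score
lookup table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import EnvironmentalGrid, SuitabilityGrid

__all__ = [
    "MembershipFunction",
    "CropRequirementSet",
    "evaluate_membership",
    "aggregate_season",
    "compute_suitability",
]


@dataclass(frozen=True)
class MembershipFunction:
    """One fuzzy membership function, trapezoidal or categorical.

    Trapezoid: breakpoints ``x1 <= x2 <= x3 <= x4``; value 0 outside
    [x1, x4], 1 on [x2, x3], linear on the ramps.  A degenerate ramp
    (``x1 == x2`` or ``x3 == x4``) is a step.  Categorical: ``classes``
    maps integer class code to a score in [0, 1].
    """

    kind: str  # "trapezoid" | "categorical"
    breakpoints: tuple[float, float, float, float] | None = None
    classes: dict[int, float] | None = None

    def __post_init__(self) -> None:
        if self.kind == "trapezoid":
            if self.breakpoints is None or len(self.breakpoints) != 4:
                raise ValueError("trapezoid requires exactly 4 breakpoints")
            x1, x2, x3, x4 = self.breakpoints
            if not (x1 <= x2 <= x3 <= x4):
                raise ValueError(
                    f"breakpoints must be sorted x1 <= x2 <= x3 <= x4, got {self.breakpoints}"
                )
        elif self.kind == "categorical":
            if not self.classes:
                raise ValueError("categorical membership requires a non-empty class map")
            for cls, score in self.classes.items():
                if not 0.0 <= score <= 1.0:
                    raise ValueError(f"score for class {cls} outside [0, 1]: {score}")
        else:
            raise ValueError(f"unknown membership kind {self.kind!r}")


def evaluate_membership(mf: MembershipFunction, x) -> np.ndarray | float:
    """Evaluate a membership function at scalar or array ``x``.

    NaN inputs give NaN scores.  Unknown categorical classes raise a
    ``ValueError`` naming the class.
    """
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0

    if mf.kind == "categorical":
        out = np.full(x.shape, np.nan)
        mask = ~np.isnan(x)
        codes = x[mask]
        known = np.array(sorted(mf.classes))
        scores = np.array([mf.classes[int(c)] for c in known])
        idx = np.searchsorted(known, codes)
        bad = (idx >= known.size) | (known[np.clip(idx, 0, known.size - 1)] != codes)
        if bad.any():
            raise ValueError(
                f"unknown categorical class {codes[bad].flat[0]:g}; "
                f"known classes: {known.tolist()}"
            )
        vals = np.full(x.shape, np.nan)
        vals[mask] = scores[idx]
        out = vals
        return float(out) if scalar else out

    x1, x2, x3, x4 = mf.breakpoints
    out = np.zeros(x.shape, dtype=float)
    # plateau
    out[(x >= x2) & (x <= x3)] = 1.0
    # rising ramp (only reachable when x2 > x1)
    if x2 > x1:
        m = (x > x1) & (x < x2)
        out[m] = (x[m] - x1) / (x2 - x1)
    # falling ramp
    if x4 > x3:
        m = (x > x3) & (x < x4)
        out[m] = (x4 - x[m]) / (x4 - x3)
    out[np.isnan(x)] = np.nan
    return float(out) if scalar else out


@dataclass(frozen=True)
class SeasonWindow:
    """Growing-season window as inclusive day-of-year bounds."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"season end {self.end} precedes start {self.start}")


@dataclass
class CropRequirementSet:
    """Named set of membership functions plus a growing-season window.

    ``memberships`` maps environmental parameter name to its
    membership function; ``aggregators`` maps climate parameter names
    to the seasonal aggregator (mean | sum | min | max) used when the
    input arrives as daily series rather than seasonal aggregates.
    """

    crop: str
    memberships: dict[str, MembershipFunction]
    season: SeasonWindow = field(default_factory=lambda: SeasonWindow(1, 365))
    aggregators: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.memberships:
            raise ValueError("requirement set needs at least one parameter")
        for name, agg in self.aggregators.items():
            if agg not in ("mean", "sum", "min", "max"):
                raise ValueError(
                    f"unknown aggregator {agg!r} for parameter {name!r}"
                )


_AGGREGATORS = {"mean": np.mean, "sum": np.sum, "min": np.min, "max": np.max}


def aggregate_season(
    daily: np.ndarray, window: SeasonWindow, aggregator: str, first_doy: int = 1
) -> np.ndarray:
    """Aggregate a daily series over a day-of-year window.

    ``daily`` has the day axis first (shape ``(n_days, ...)``), with
    day ``first_doy`` at index 0.  The window is inclusive on both
    ends.  Missing daily values (NaN) propagate to a missing
    aggregate.  Raises if the window lies outside the series.
    """
    if aggregator not in _AGGREGATORS:
        raise ValueError(f"unknown aggregator {aggregator!r}")
    daily = np.asarray(daily, dtype=float)
    n_days = daily.shape[0]
    i0 = window.start - first_doy
    i1 = window.end - first_doy + 1
    if i0 < 0 or i1 > n_days:
        raise ValueError(
            f"window [{window.start}, {window.end}] outside series coverage "
            f"[{first_doy}, {first_doy + n_days - 1}]"
        )
    return _AGGREGATORS[aggregator](daily[i0:i1], axis=0)


def compute_suitability(
    env: EnvironmentalGrid, reqs: CropRequirementSet, period: str | None = None
) -> SuitabilityGrid:
    """Per-cell suitability = min over parameters of the membership score.

    Every parameter named in ``reqs`` must be a field of ``env``.  A
    cell missing in any parameter gets a missing suitability — a
    minimum over incomplete information would be silently optimistic.
    """
    missing_fields = [p for p in reqs.memberships if p not in env.parameters]
    if missing_fields:
        raise ValueError(
            f"environmental grid lacks parameter field(s) {missing_fields}; "
            f"available: {sorted(env.parameters)}"
        )
    suit = np.ones(env.grid.shape, dtype=float)
    for name, mf in reqs.memberships.items():
        suit = np.fmin(suit, evaluate_membership(mf, env[name]))
    # fmin ignores NaN; reimpose the missing-anywhere-means-missing rule
    suit[env.missing_mask()] = np.nan
    return SuitabilityGrid(
        grid=env.grid,
        values=suit,
        crop=reqs.crop,
        period=period or env.period,
        attrs={"crop": reqs.crop},
    )
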