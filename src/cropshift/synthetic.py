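"""Seeded synthetic geodata: environmental grids, climate deltas, land use.

This module generates environmental fields with the statistical
structure the downstream analysis relies on — spatial autocorrelation,
a poleward temperature decline so that warming shifts suitable zones
toward the poles, and a land-use mask concentrated on high-suitability
cells so that percentile thresholds over used cells are meaningful.
All generators are pure functions of their arguments and a seed.

These are stand-ins for real gridded climate/soil/topography datasets
and a real harvested-area raster; the default parameter statistics are
illustrative, not fitted to any dataset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize, special

from .grids import EnvironmentalGrid, GridSpec, LandUseMask, SuitabilityGrid

__all__ = [
    "ParameterStats",
    "ClimateDelta",
    "DEFAULT_PARAMETER_STATS",
    "generate_environment",
    "apply_climate_delta",
    "generate_landuse",
]


@dataclass(frozen=True)
class ParameterStats:
    """Mean, spatial standard deviation and physical bounds of one field."""

    mean: float
    sd: float
    lower: float = -np.inf
    upper: float = np.inf
    #: number of classes if the field is categorical (class codes 1..n)
    n_classes: int | None = None

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"sd must be >= 0, got {self.sd}")
        if self.lower > self.upper:
            raise ValueError("lower bound exceeds upper bound")


#: Illustrative (synthetic) defaults for the growing-season aggregate
#: fields the suitability engine consumes.  Units: temperature °C,
#: precipitation mm per season, solar radiation MJ m^-2 d^-1, pH
#: unitless, organic carbon %, salinity dS m^-1, sodicity (ESP) %,
#: slope %, elevation m, available water capacity mm, texture class
#: categorical 1..3.
DEFAULT_PARAMETER_STATS: dict[str, ParameterStats] = {
    "temperature": ParameterStats(mean=18.0, sd=3.0, lower=-40.0, upper=45.0),
    "precipitation": ParameterStats(mean=550.0, sd=180.0, lower=0.0, upper=4000.0),
    "solar_radiation": ParameterStats(mean=18.0, sd=3.0, lower=2.0, upper=35.0),
    "ph": ParameterStats(mean=6.5, sd=0.8, lower=3.0, upper=10.0),
    "organic_carbon": ParameterStats(mean=1.5, sd=0.8, lower=0.0, upper=15.0),
    "salinity": ParameterStats(mean=1.0, sd=1.0, lower=0.0, upper=30.0),
    "sodicity": ParameterStats(mean=4.0, sd=3.0, lower=0.0, upper=60.0),
    "slope": ParameterStats(mean=4.0, sd=4.0, lower=0.0, upper=60.0),
    "elevation": ParameterStats(mean=500.0, sd=400.0, lower=-400.0, upper=6000.0),
    "available_water_capacity": ParameterStats(mean=120.0, sd=40.0, lower=10.0, upper=300.0),
    "texture_class": ParameterStats(mean=0.0, sd=1.0, n_classes=3),
}

#: Built-in meridional temperature lapse (°C per degree of |latitude|).
#: 0.6 °C/deg gives roughly a 50 °C equator-to-pole contrast, enough
#: for warming to move the suitable band poleward.
DEFAULT_LATITUDE_LAPSE = 0.6


@dataclass(frozen=True)
class ClimateDelta:
    """Climate change between the baseline and future periods.

    Warming at a cell of latitude phi is ``dT + gradient_per_degree_lat
    * |phi|``; precipitation is scaled by ``precip_factor``.
    """

    dT: float = 0.0
    precip_factor: float = 1.0
    gradient_per_degree_lat: float = 0.0

    def __post_init__(self) -> None:
        if self.precip_factor <= 0:
            raise ValueError(f"precip_factor must be > 0, got {self.precip_factor}")

    def warming_at(self, lat: np.ndarray | float) -> np.ndarray | float:
        return self.dT + self.gradient_per_degree_lat * np.abs(lat)


def _correlated_noise(
    rng: np.random.Generator, shape: tuple[int, int], correlation_cells: float
) -> np.ndarray:
    """Unit-variance Gaussian noise smoothed to the given correlation length.

    White noise is convolved with a Gaussian kernel of width
    ``correlation_cells`` and rescaled back to unit variance, so the
    marginal sd requested in :class:`ParameterStats` is preserved
    regardless of smoothing.
    """
    z = rng.standard_normal(shape)
    if correlation_cells <= 0:
        return z
    sm = ndimage.gaussian_filter(z, sigma=correlation_cells, mode="wrap")
    s = sm.std()
    if s == 0:  # pragma: no cover - only for pathological tiny grids
        return np.zeros(shape)
    return sm / s


def generate_environment(
    spec: GridSpec,
    seed: int,
    correlation_cells: float = 3.0,
    parameter_stats: dict[str, ParameterStats] | None = None,
    latitude_lapse: float = DEFAULT_LATITUDE_LAPSE,
) -> EnvironmentalGrid:
    """Generate a baseline-period environmental grid.

    Each continuous field is spatially correlated Gaussian noise
    (``mean + sd * smoothed_noise``) clipped to its physical bounds.
    The temperature field additionally declines with |latitude| at
    ``latitude_lapse`` °C per degree, referenced so that the stated
    mean is attained at the grid's mean |latitude|; pass
    ``latitude_lapse=0`` to disable.  Categorical fields are produced
    by binning a correlated latent field into equiprobable classes,
    which keeps the classes spatially coherent.

    Identical arguments and seed give bit-identical output.
    """
    if correlation_cells < 0:
        raise ValueError(f"correlation_cells must be >= 0, got {correlation_cells}")
    stats = dict(DEFAULT_PARAMETER_STATS if parameter_stats is None else parameter_stats)
    unknown = set(stats) - set(DEFAULT_PARAMETER_STATS)
    if unknown:
        raise ValueError(
            f"unknown parameter name(s) {sorted(unknown)}; "
            f"valid names: {sorted(DEFAULT_PARAMETER_STATS)}"
        )

    rng = np.random.default_rng(seed)
    lat = spec.lat_grid()
    fields: dict[str, np.ndarray] = {}
    # Draw fields in sorted-name order so output is independent of dict order.
    for name in sorted(stats):
        st = stats[name]
        noise = _correlated_noise(rng, spec.shape, correlation_cells)
        if st.n_classes is not None:
            # equiprobable bins of the standard-normal latent field
            edges = special.ndtri(np.arange(1, st.n_classes) / st.n_classes)
            fields[name] = (np.digitize(noise, edges) + 1).astype(float)
            continue
        f = st.mean + st.sd * noise
        if name == "temperature" and latitude_lapse != 0.0:
            f = f - latitude_lapse * (np.abs(lat) - np.abs(lat).mean())
        fields[name] = np.clip(f, st.lower, st.upper)

    return EnvironmentalGrid(
        grid=spec,
        parameters=fields,
        period="baseline",
        attrs={
            "seed": int(seed),
            "correlation_cells": float(correlation_cells),
            "latitude_lapse": float(latitude_lapse),
            "synthetic": True,
        },
    )


def apply_climate_delta(base: EnvironmentalGrid, delta: ClimateDelta) -> EnvironmentalGrid:
    """Produce the future-period grid from a baseline grid.

    Temperature gains ``delta.warming_at(lat)``, precipitation is
    multiplied by ``precip_factor``, every other field is copied
    unchanged.  Missing cells stay missing (NaN arithmetic).
    """
    if base.period != "baseline":
        raise ValueError(f"expected a baseline-period grid, got period={base.period!r}")
    lat = base.grid.lat_grid()
    fields: dict[str, np.ndarray] = {}
    for name, arr in base.parameters.items():
        if name == "temperature":
            fields[name] = arr + delta.warming_at(lat)
        elif name == "precipitation":
            fields[name] = arr * delta.precip_factor
        else:
            fields[name] = arr.copy()
    attrs = dict(base.attrs)
    attrs.update(
        dT=float(delta.dT),
        precip_factor=float(delta.precip_factor),
        gradient_per_degree_lat=float(delta.gradient_per_degree_lat),
    )
    return EnvironmentalGrid(grid=base.grid, parameters=fields, period="future", attrs=attrs)


def _calibrate_intercept(suit: np.ndarray, slope: float, target: float) -> float:
    """Solve for the logistic intercept giving E[P(used)] = target.

    The expectation runs over all non-missing cells, with
    zero-suitability cells contributing probability 0 (they can never
    be used).
    """
    pos = suit[suit > 0]
    n_total = suit.size
    if pos.size == 0:
        raise ValueError("all suitability values are 0; cannot place any used cells")
    # feasible range: target * n_total used cells must fit in the positive pool
    max_frac = pos.size / n_total
    if target >= max_frac:
        raise ValueError(
            f"target_used_fraction={target} infeasible: only {max_frac:.3f} of "
            "cells have positive suitability"
        )

    def mean_p(a: float) -> float:
        return float(special.expit(a + slope * pos).sum()) / n_total

    return optimize.brentq(lambda a: mean_p(a) - target, -500.0, 500.0)


def generate_landuse(
    suitability: SuitabilityGrid,
    target_used_fraction: float,
    seed: int,
    slope: float = 6.0,
) -> LandUseMask:
    """Draw a harvested-area mask concentrated on high-suitability cells.

    P(used) follows a logistic link ``expit(a + slope * LS)`` with the
    intercept ``a`` calibrated so the expected used fraction over
    non-missing cells equals ``target_used_fraction``.  Used cells get
    a harvested fraction drawn uniformly on [0.01, 1] — so the 1%
    used-cell rule is exercised at its boundary — and all other cells
    get fraction 0.  Cells with suitability exactly 0 are never used.
    Missing suitability gives a missing fraction.
    """
    if not 0.0 < target_used_fraction < 1.0:
        raise ValueError(
            f"target_used_fraction must lie in (0, 1), got {target_used_fraction}"
        )
    if suitability.period != "baseline":
        raise ValueError("land use must be generated from baseline suitability")

    vals = suitability.values
    missing = np.isnan(vals)
    finite = vals[~missing]
    a = _calibrate_intercept(finite, slope, target_used_fraction)

    rng = np.random.default_rng(seed)
    p_used = special.expit(a + slope * np.nan_to_num(vals, nan=0.0))
    p_used[np.nan_to_num(vals, nan=0.0) <= 0] = 0.0
    u = rng.random(vals.shape)
    used = u < p_used
    frac = np.where(used, 0.01 + 0.99 * rng.random(vals.shape), 0.0)
    frac[missing] = np.nan

    return LandUseMask(
        grid=suitability.grid,
        fraction=frac,
        attrs={
            "seed": int(seed),
            "target_used_fraction": float(target_used_fraction),
            "logistic_slope": float(slope),
            "logistic_intercept": float(a),
            "synthetic": True,
        },
    )
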