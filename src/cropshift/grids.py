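"""Core gridded data containers.

All fields live on a regular cell-centered lat/lon grid described by
:class:`GridSpec`.  Rows run north to south (row 0 is the northernmost
band), matching the row order of the plain-text grid dialect.  Missing
cells are encoded as NaN in float fields; the rule throughout the
package is that a cell missing in any input is missing in every
derived product.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "GridSpec",
    "EnvironmentalGrid",
    "SuitabilityGrid",
    "LandUseMask",
    "TransitionMap",
    "CATEGORY_CODES",
    "USED_THRESHOLD",
]

#: Harvested-area fraction at or above which a cell counts as "used".
USED_THRESHOLD = 0.01

#: Integer raster codes for transition categories (255 = missing).
CATEGORY_CODES = {
    "unaltered_notused": 0,
    "unaltered_used": 1,
    "abandoned": 2,
    "added": 3,
    "missing": 255,
}


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular cell-centered latitude/longitude grid.

    Parameters
    ----------
    n_lat, n_lon
        Number of rows (latitude bands) and columns.
    lat_min, lat_max, lon_min, lon_max
        Outer edges of the grid in degrees.  Cell centers sit half a
        cell inside the edges.
    """

    n_lat: int
    n_lon: int
    lat_min: float = -90.0
    lat_max: float = 90.0
    lon_min: float = -180.0
    lon_max: float = 180.0

    def __post_init__(self) -> None:
        if self.n_lat < 1 or self.n_lon < 1:
            raise ValueError(
                f"grid counts must be >= 1, got n_lat={self.n_lat}, n_lon={self.n_lon}"
            )
        if not (-90.0 <= self.lat_min < self.lat_max <= 90.0):
            raise ValueError(
                f"latitude bounds must satisfy -90 <= lat_min < lat_max <= 90, "
                f"got [{self.lat_min}, {self.lat_max}]"
            )
        if not (-180.0 <= self.lon_min < self.lon_max <= 180.0):
            raise ValueError(
                f"longitude bounds must satisfy -180 <= lon_min < lon_max <= 180, "
                f"got [{self.lon_min}, {self.lon_max}]"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_lat, self.n_lon)

    @property
    def d_lat(self) -> float:
        return (self.lat_max - self.lat_min) / self.n_lat

    @property
    def d_lon(self) -> float:
        return (self.lon_max - self.lon_min) / self.n_lon

    def lat_centers(self) -> np.ndarray:
        """Cell-center latitudes, north to south (row order)."""
        return self.lat_max - self.d_lat * (np.arange(self.n_lat) + 0.5)

    def lon_centers(self) -> np.ndarray:
        return self.lon_min + self.d_lon * (np.arange(self.n_lon) + 0.5)

    def lat_grid(self) -> np.ndarray:
        """(n_lat, n_lon) array of cell-center latitudes."""
        return np.broadcast_to(
            self.lat_centers()[:, None], (self.n_lat, self.n_lon)
        ).copy()


def _check_shape(spec: GridSpec, arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr, dtype=float)
    if arr.shape != spec.shape:
        raise ValueError(
            f"field {name!r} has shape {arr.shape}, expected {spec.shape}"
        )
    return arr


@dataclass
class EnvironmentalGrid:
    """Named per-cell environmental parameter fields for one period.

    ``parameters`` maps parameter name (e.g. ``"temperature"``,
    ``"precipitation"``, ``"ph"``, ``"texture_class"``) to a float
    array of shape ``grid.shape``.  Categorical fields hold integer
    class codes stored as floats; NaN marks missing cells.  A cell
    that is NaN in any parameter is treated as missing everywhere.
    """

    grid: GridSpec
    parameters: dict[str, np.ndarray]
    period: str = "baseline"
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.period not in ("baseline", "future"):
            raise ValueError(f"period must be 'baseline' or 'future', got {self.period!r}")
        self.parameters = {
            k: _check_shape(self.grid, v, k) for k, v in self.parameters.items()
        }

    def missing_mask(self) -> np.ndarray:
        """True where any parameter is missing."""
        m = np.zeros(self.grid.shape, dtype=bool)
        for v in self.parameters.values():
            m |= np.isnan(v)
        return m

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            return self.parameters[name]
        except KeyError:
            raise KeyError(
                f"parameter {name!r} not in grid; available: {sorted(self.parameters)}"
            ) from None


@dataclass
class SuitabilityGrid:
    """Per-cell crop suitability in [0, 1], NaN = missing.

    Holds the baseline surface (suitability today) or the future one,
    distinguished by ``period``.
    """

    grid: GridSpec
    values: np.ndarray
    crop: str
    period: str = "baseline"
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = _check_shape(self.grid, self.values, "suitability")
        finite = self.values[~np.isnan(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError(
                f"suitability values outside [0, 1]: range "
                f"[{finite.min():.4g}, {finite.max():.4g}]"
            )


@dataclass
class LandUseMask:
    """Per-cell harvested-area fraction and the derived used flag.

    A non-missing cell is *used* when its harvested-area fraction is
    at least 1% of the cell area.
    """

    grid: GridSpec
    fraction: np.ndarray
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.fraction = _check_shape(self.grid, self.fraction, "fraction")
        finite = self.fraction[~np.isnan(self.fraction)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValueError("harvested-area fraction outside [0, 1]")

    @property
    def used(self) -> np.ndarray:
        """Boolean used-cell flag; False on missing cells."""
        with np.errstate(invalid="ignore"):
            return np.nan_to_num(self.fraction, nan=0.0) >= USED_THRESHOLD

    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.fraction)


@dataclass
class TransitionMap:
    """Categorical transition raster for one crop under one scenario.

    ``codes`` is a uint8 array using :data:`CATEGORY_CODES`;
    ``threshold_used`` is the realized percentile threshold applied to
    not-used cells.
    """

    grid: GridSpec
    codes: np.ndarray
    scenario: str
    crop: str
    threshold_used: float
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        codes = np.asarray(self.codes)
        if codes.shape != self.grid.shape:
            raise ValueError(
                f"codes shape {codes.shape} != grid shape {self.grid.shape}"
            )
        valid = set(CATEGORY_CODES.values())
        bad = set(np.unique(codes).tolist()) - valid
        if bad:
            raise ValueError(f"unknown category codes {sorted(bad)}")
        self.codes = codes.astype(np.uint8)

    def category_mask(self, category: str) -> np.ndarray:
        return self.codes == CATEGORY_CODES[category]
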