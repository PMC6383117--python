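"""Latitude-aware area accounting: categorical maps to km² totals.

Cells of a regular lat/lon grid shrink toward the poles; on a
spherical Earth of radius R the area of a cell spanning Δλ in
longitude between latitudes φ_bot and φ_top is

    A = R² · Δλ · (sin φ_top − sin φ_bot)      [Δλ in radians]

Summed over a full global grid this telescopes exactly to 4πR².
Totals count whole cell areas, not harvested fractions: the summary
measures the footprint of the production map, not tonnage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import CATEGORY_CODES, GridSpec, TransitionMap

__all__ = ["EARTH_RADIUS_KM", "AreaSummary", "cell_area_km2", "band_areas_km2", "summarize"]

EARTH_RADIUS_KM = 6371.0

_CATEGORIES = ("unaltered_used", "abandoned", "added", "unaltered_notused")


def cell_area_km2(lat_center: float, d_lat: float, d_lon: float) -> float:
    """Area in km² of one cell centered at ``lat_center`` degrees.

    Raises if the cell would cross a pole.
    """
    top = lat_center + d_lat / 2.0
    bot = lat_center - d_lat / 2.0
    if top > 90.0 + 1e-12 or bot < -90.0 - 1e-12:
        raise ValueError(
            f"cell centered at {lat_center}° with d_lat={d_lat}° crosses a pole"
        )
    dlon_rad = np.deg2rad(d_lon)
    return float(
        EARTH_RADIUS_KM**2 * dlon_rad * (np.sin(np.deg2rad(top)) - np.sin(np.deg2rad(bot)))
    )


def band_areas_km2(spec: GridSpec) -> np.ndarray:
    """Per-row cell areas (km²) for a grid, north to south."""
    lats = spec.lat_centers()
    top = np.deg2rad(lats + spec.d_lat / 2.0)
    bot = np.deg2rad(lats - spec.d_lat / 2.0)
    dlon = np.deg2rad(spec.d_lon)
    return EARTH_RADIUS_KM**2 * dlon * (np.sin(top) - np.sin(bot))


@dataclass
class AreaSummary:
    """km² totals per transition category for one crop and scenario."""

    crop: str
    scenario: str
    area_km2: dict[str, float]
    missing_km2: float
    total_km2: float

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: crop, scenario, category, area_km2."""
        rows = [
            {"crop": self.crop, "scenario": self.scenario, "category": c, "area_km2": self.area_km2[c]}
            for c in _CATEGORIES
        ]
        rows.append(
            {"crop": self.crop, "scenario": self.scenario, "category": "missing", "area_km2": self.missing_km2}
        )
        return pd.DataFrame(rows)


def summarize(tmap: TransitionMap) -> AreaSummary:
    """Accumulate per-category km² totals from a transition map.

    Conservation holds by construction: category areas plus missing
    equal the grid's total area.
    """
    band = band_areas_km2(tmap.grid)
    cell_areas = np.broadcast_to(band[:, None], tmap.grid.shape)
    areas = {
        cat: float(cell_areas[tmap.codes == CATEGORY_CODES[cat]].sum())
        for cat in _CATEGORIES
    }
    missing = float(cell_areas[tmap.codes == CATEGORY_CODES["missing"]].sum())
    total = float(band.sum() * tmap.grid.n_lon)
    return AreaSummary(
        crop=tmap.crop,
        scenario=tmap.scenario,
        area_km2=areas,
        missing_km2=missing,
        total_km2=total,
    )
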