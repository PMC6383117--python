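"""Raster and configuration I/O.

Rasters travel as NetCDF (one variable per field, CF-style ``lat``/
``lon`` coordinate vectors, written through xarray's scipy backend)
or as a plain-text grid dialect for human-readable fixtures:

    ncols <n>
    nrows <n>
    xllcorner <deg>
    yllcorner <deg>
    cellsize <deg>
    NODATA_value <v>
    <row 0 = northernmost band>
    ...

NetCDF round-trips are bit-identical (float64 throughout); the text
dialect prints values with 10 significant digits, so round-trips are
exact to that precision.  Crop requirement sets are read from YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import xarray as xr
import yaml

from .grids import EnvironmentalGrid, GridSpec, LandUseMask, SuitabilityGrid, TransitionMap
from .suitability import CropRequirementSet, MembershipFunction, SeasonWindow

__all__ = [
    "write_netcdf",
    "read_environment",
    "read_suitability",
    "read_landuse",
    "write_transition_map",
    "read_transition_map",
    "write_ascii_grid",
    "read_ascii_grid",
    "read_requirements",
    "write_requirements",
]

_NODATA = -9999.0


def _spec_to_coords(spec: GridSpec) -> dict[str, np.ndarray]:
    return {"lat": spec.lat_centers(), "lon": spec.lon_centers()}


def _spec_attrs(spec: GridSpec) -> dict:
    return {
        "lat_min": spec.lat_min,
        "lat_max": spec.lat_max,
        "lon_min": spec.lon_min,
        "lon_max": spec.lon_max,
    }


def _spec_from_dataset(ds: xr.Dataset) -> GridSpec:
    return GridSpec(
        n_lat=ds.sizes["lat"],
        n_lon=ds.sizes["lon"],
        lat_min=float(ds.attrs["lat_min"]),
        lat_max=float(ds.attrs["lat_max"]),
        lon_min=float(ds.attrs["lon_min"]),
        lon_max=float(ds.attrs["lon_max"]),
    )


def _sanitize_attrs(attrs: dict) -> dict:
    out = {}
    for k, v in attrs.items():
        if isinstance(v, bool):
            v = int(v)
        if isinstance(v, (int, float, str)):
            out[k] = v
    return out


def to_dataset(obj) -> xr.Dataset:
    """Convert any grid container to an xarray Dataset."""
    if isinstance(obj, EnvironmentalGrid):
        data = {k: (("lat", "lon"), v) for k, v in obj.parameters.items()}
        attrs = {"kind": "environment", "period": obj.period}
    elif isinstance(obj, SuitabilityGrid):
        data = {"suitability": (("lat", "lon"), obj.values)}
        attrs = {"kind": "suitability", "period": obj.period, "crop": obj.crop}
    elif isinstance(obj, LandUseMask):
        data = {"fraction": (("lat", "lon"), obj.fraction)}
        attrs = {"kind": "landuse"}
    elif isinstance(obj, TransitionMap):
        data = {"category": (("lat", "lon"), obj.codes.astype(np.int32))}
        attrs = {
            "kind": "transition",
            "scenario": obj.scenario,
            "crop": obj.crop,
            "threshold_used": obj.threshold_used,
        }
    else:
        raise TypeError(f"cannot serialise object of type {type(obj).__name__}")
    attrs.update(_spec_attrs(obj.grid))
    attrs.update(_sanitize_attrs(obj.attrs))
    return xr.Dataset(data, coords=_spec_to_coords(obj.grid), attrs=attrs)


def write_netcdf(obj, path) -> None:
    to_dataset(obj).to_netcdf(path, engine="scipy")


def _open(path) -> xr.Dataset:
    with xr.open_dataset(path, engine="scipy") as ds:
        return ds.load()


def read_environment(path) -> EnvironmentalGrid:
    ds = _open(path)
    spec = _spec_from_dataset(ds)
    params = {name: ds[name].values.astype(float) for name in ds.data_vars}
    return EnvironmentalGrid(
        grid=spec, parameters=params, period=ds.attrs.get("period", "baseline"),
        attrs=dict(ds.attrs),
    )


def read_suitability(path) -> SuitabilityGrid:
    ds = _open(path)
    return SuitabilityGrid(
        grid=_spec_from_dataset(ds),
        values=ds["suitability"].values.astype(float),
        crop=ds.attrs.get("crop", "unknown"),
        period=ds.attrs.get("period", "baseline"),
        attrs=dict(ds.attrs),
    )


def read_landuse(path) -> LandUseMask:
    ds = _open(path)
    return LandUseMask(
        grid=_spec_from_dataset(ds),
        fraction=ds["fraction"].values.astype(float),
        attrs=dict(ds.attrs),
    )


def write_transition_map(tmap: TransitionMap, path, sidecar: bool = True) -> None:
    """Write a categorical raster plus a JSON sidecar with the rule metadata."""
    write_netcdf(tmap, path)
    if sidecar:
        meta = {
            "scenario": tmap.scenario,
            "crop": tmap.crop,
            "retention_factor": tmap.attrs.get("retention_factor"),
            "addition_percentile": tmap.attrs.get("addition_percentile"),
            "threshold_used": tmap.threshold_used,
            "category_codes": {
                "unaltered_notused": 0, "unaltered_used": 1,
                "abandoned": 2, "added": 3, "missing": 255,
            },
        }
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))


def read_transition_map(path) -> TransitionMap:
    ds = _open(path)
    return TransitionMap(
        grid=_spec_from_dataset(ds),
        codes=ds["category"].values.astype(np.uint8),
        scenario=ds.attrs.get("scenario", "unknown"),
        crop=ds.attrs.get("crop", "unknown"),
        threshold_used=float(ds.attrs.get("threshold_used", np.nan)),
        attrs=dict(ds.attrs),
    )


def write_ascii_grid(field: np.ndarray, spec: GridSpec, path, nodata: float = _NODATA) -> None:
    """Write one field in the plain-text grid dialect (rows north→south)."""
    if abs(spec.d_lat - spec.d_lon) > 1e-9:
        raise ValueError(
            f"text dialect requires square cells; d_lat={spec.d_lat}, d_lon={spec.d_lon}"
        )
    field = np.asarray(field, dtype=float)
    if field.shape != spec.shape:
        raise ValueError(f"field shape {field.shape} != grid shape {spec.shape}")
    out = np.where(np.isnan(field), nodata, field)
    lines = [
        f"ncols {spec.n_lon}",
        f"nrows {spec.n_lat}",
        f"xllcorner {spec.lon_min:.10g}",
        f"yllcorner {spec.lat_min:.10g}",
        f"cellsize {spec.d_lat:.10g}",
        f"NODATA_value {nodata:.10g}",
    ]
    for row in out:
        lines.append(" ".join(f"{v:.10g}" for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_ascii_grid(path) -> tuple[np.ndarray, GridSpec]:
    """Read the plain-text grid dialect; returns (field, spec), NaN for NODATA."""
    lines = Path(path).read_text().splitlines()
    header: dict[str, float] = {}
    expected = ["ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "NODATA_value"]
    for i, key in enumerate(expected):
        try:
            k, v = lines[i].split()
        except (IndexError, ValueError):
            raise ValueError(f"{path}: malformed header at line {i + 1} (expected {key})")
        if k.lower() != key.lower():
            raise ValueError(f"{path}: expected header key {key!r}, found {k!r}")
        header[key] = float(v)
    n_lon, n_lat = int(header["ncols"]), int(header["nrows"])
    cell = header["cellsize"]
    spec = GridSpec(
        n_lat=n_lat,
        n_lon=n_lon,
        lat_min=header["yllcorner"],
        lat_max=header["yllcorner"] + cell * n_lat,
        lon_min=header["xllcorner"],
        lon_max=header["xllcorner"] + cell * n_lon,
    )
    rows = [
        np.array(line.split(), dtype=float) for line in lines[6:] if line.strip()
    ]
    field = np.vstack(rows)
    if field.shape != (n_lat, n_lon):
        raise ValueError(
            f"{path}: data block shape {field.shape} does not match header "
            f"({n_lat}, {n_lon})"
        )
    field[field == header["NODATA_value"]] = np.nan
    return field, spec


def _parse_membership(entry: dict, path) -> MembershipFunction:
    name = entry.get("name", "<unnamed>")
    kind = entry.get("kind")
    if kind == "trapezoid":
        bp = entry.get("breakpoints")
        if bp is None or len(bp) != 4:
            raise ValueError(f"{path}: parameter {name!r} needs 4 breakpoints")
        bp = tuple(float(b) for b in bp)
        if sorted(bp) != list(bp):
            raise ValueError(
                f"{path}: parameter {name!r} has unsorted breakpoints {list(bp)}"
            )
        return MembershipFunction(kind="trapezoid", breakpoints=bp)
    if kind == "categorical":
        classes = entry.get("classes")
        if not classes:
            raise ValueError(f"{path}: parameter {name!r} needs a class map")
        return MembershipFunction(
            kind="categorical", classes={int(k): float(v) for k, v in classes.items()}
        )
    raise ValueError(f"{path}: parameter {name!r} has unknown kind {kind!r}")


def read_requirements(path) -> CropRequirementSet:
    """Read a crop requirement set from YAML.

    Schema: ``crop``, ``season.start``/``season.end`` (day of year),
    ``parameters`` — a list of ``{name, kind, breakpoints|classes,
    aggregator?}`` entries.  Validation errors name the offending
    parameter.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict) or "crop" not in raw or "parameters" not in raw:
        raise ValueError(f"{path}: requirement file must define 'crop' and 'parameters'")
    memberships: dict[str, MembershipFunction] = {}
    aggregators: dict[str, str] = {}
    for entry in raw["parameters"]:
        name = entry.get("name")
        if not name:
            raise ValueError(f"{path}: every parameter entry needs a 'name'")
        memberships[name] = _parse_membership(entry, path)
        if "aggregator" in entry:
            aggregators[name] = entry["aggregator"]
    season_raw = raw.get("season", {"start": 1, "end": 365})
    season = SeasonWindow(int(season_raw["start"]), int(season_raw["end"]))
    return CropRequirementSet(
        crop=raw["crop"], memberships=memberships, season=season, aggregators=aggregators
    )


def write_requirements(reqs: CropRequirementSet, path) -> None:
    entries = []
    for name, mf in reqs.memberships.items():
        e: dict = {"name": name, "kind": mf.kind}
        if mf.kind == "trapezoid":
            e["breakpoints"] = list(mf.breakpoints)
        else:
            e["classes"] = {int(k): float(v) for k, v in mf.classes.items()}
        if name in reqs.aggregators:
            e["aggregator"] = reqs.aggregators[name]
        entries.append(e)
    doc = {
        "crop": reqs.crop,
        "season": {"start": reqs.season.start, "end": reqs.season.end},
        "parameters": entries,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
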