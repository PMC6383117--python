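"""End-to-end orchestration: generate/load → suitability → classify → account.

A :class:`RunConfig` describes one run — either fully synthetic
(generator parameters) or file-driven (paths to rasters) — and
:func:`run_pipeline` executes the stages, writing every artifact with
provenance metadata (config hash, seed, package version) so a rerun
with the same config is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as cio
from .areas import AreaSummary, summarize
from .grids import EnvironmentalGrid, GridSpec, LandUseMask, SuitabilityGrid, TransitionMap
from .suitability import CropRequirementSet, compute_suitability
from .synthetic import ClimateDelta, apply_climate_delta, generate_environment, generate_landuse
from .transitions import SCENARIOS, classify_transitions

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "bundled_requirements", "load_config"]

log = logging.getLogger("cropshift")


def bundled_requirements(crop: str) -> CropRequirementSet:
    """Load one of the illustrative requirement sets shipped with the package."""
    ref = resources.files("cropshift.data") / f"{crop}.yaml"
    if not ref.is_file():
        available = [p.name[:-5] for p in resources.files("cropshift.data").iterdir()
                     if p.name.endswith(".yaml")]
        raise ValueError(f"no bundled requirements for {crop!r}; available: {available}")
    with resources.as_file(ref) as p:
        return cio.read_requirements(p)


@dataclass
class RunConfig:
    """Configuration of one projection run.

    Synthetic mode (default): the environmental grids and land-use
    mask are generated from ``seed`` with the stated grid, climate
    delta and target used fraction.  File mode: set ``baseline_env`` /
    ``future_env`` / ``landuse`` to NetCDF paths instead.
    """

    crop: str = "maize"
    requirements_file: str | None = None  # None -> bundled illustrative set
    scenario: str = "both"  # no_change | major_change | both
    seed: int = 0
    output_dir: str | None = None
    # synthetic-mode knobs
    n_lat: int = 60
    n_lon: int = 120
    lat_min: float = -90.0
    lat_max: float = 90.0
    lon_min: float = -180.0
    lon_max: float = 180.0
    correlation_cells: float = 3.0
    dT: float = 3.5
    precip_factor: float = 1.05
    gradient_per_degree_lat: float = 0.0
    target_used_fraction: float = 0.15
    # file-mode inputs
    baseline_env: str | None = None
    future_env: str | None = None
    landuse: str | None = None

    def __post_init__(self) -> None:
        if self.scenario not in ("no_change", "major_change", "both"):
            raise ValueError(
                f"scenario must be no_change, major_change or both, got {self.scenario!r}"
            )

    def scenarios(self) -> list[str]:
        return ["no_change", "major_change"] if self.scenario == "both" else [self.scenario]

    def grid_spec(self) -> GridSpec:
        return GridSpec(self.n_lat, self.n_lon, self.lat_min, self.lat_max,
                        self.lon_min, self.lon_max)

    def config_hash(self) -> str:
        doc = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(doc.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Read a RunConfig from a YAML mapping of field names."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    valid = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"{path}: unknown config key(s) {sorted(unknown)}")
    return RunConfig(**raw)


@dataclass
class PipelineResult:
    """Everything one run produces, in memory."""

    config: RunConfig
    baseline_env: EnvironmentalGrid
    future_env: EnvironmentalGrid
    lst: SuitabilityGrid
    lsf: SuitabilityGrid
    landuse: LandUseMask
    transitions: dict[str, TransitionMap]
    summaries: dict[str, AreaSummary]

    def summary_frame(self) -> pd.DataFrame:
        return pd.concat([s.to_frame() for s in self.summaries.values()], ignore_index=True)


def _stage(name: str):
    """Decorator prefixing stage name to any error raised inside."""
    def wrap(fn):
        def inner(*args, **kw):
            try:
                return fn(*args, **kw)
            except Exception as e:
                raise type(e)(f"[stage {name}] {e}") from e
        return inner
    return wrap


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    """Execute the full projection pipeline for one crop.

    Stages: obtain baseline/future environments and the land-use mask
    (synthetic generation or file load) → baseline and future
    suitability → transition classification per scenario → km² area
    summaries.  Deterministic under a fixed config.
    """
    reqs = (cio.read_requirements(cfg.requirements_file)
            if cfg.requirements_file else bundled_requirements(cfg.crop))

    if cfg.baseline_env:
        base = _stage("load")(cio.read_environment)(cfg.baseline_env)
    else:
        base = _stage("generate")(generate_environment)(
            cfg.grid_spec(), seed=cfg.seed, correlation_cells=cfg.correlation_cells)
    if cfg.future_env:
        fut = _stage("load")(cio.read_environment)(cfg.future_env)
    else:
        delta = ClimateDelta(dT=cfg.dT, precip_factor=cfg.precip_factor,
                             gradient_per_degree_lat=cfg.gradient_per_degree_lat)
        fut = _stage("climate-delta")(apply_climate_delta)(base, delta)

    lst = _stage("suitability-baseline")(compute_suitability)(base, reqs)
    lsf = _stage("suitability-future")(compute_suitability)(fut, reqs)

    if cfg.landuse:
        mask = _stage("load")(cio.read_landuse)(cfg.landuse)
    else:
        mask = _stage("landuse")(generate_landuse)(
            lst, target_used_fraction=cfg.target_used_fraction, seed=cfg.seed + 1)

    transitions: dict[str, TransitionMap] = {}
    summaries: dict[str, AreaSummary] = {}
    for name in cfg.scenarios():
        tmap = _stage(f"classify-{name}")(classify_transitions)(
            lst, lsf, mask, SCENARIOS[name])
        transitions[name] = tmap
        summaries[name] = _stage(f"summarize-{name}")(summarize)(tmap)
        counts = {c: int((tmap.codes == code).sum())
                  for c, code in (("unaltered_notused", 0), ("unaltered_used", 1),
                                  ("abandoned", 2), ("added", 3))}
        log.info("scenario %s: threshold=%.4f cells=%s", name, tmap.threshold_used, counts)

    result = PipelineResult(cfg, base, fut, lst, lsf, mask, transitions, summaries)
    if cfg.output_dir:
        _write_outputs(result)
    return result


def _write_outputs(res: PipelineResult) -> None:
    out = Path(res.config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    prov = {"config_hash": res.config.config_hash(), "seed": res.config.seed,
            "version": __version__}
    for obj, name in ((res.baseline_env, "env_baseline.nc"),
                      (res.future_env, "env_future.nc"),
                      (res.lst, "suitability_baseline.nc"),
                      (res.lsf, "suitability_future.nc"),
                      (res.landuse, "landuse.nc")):
        obj.attrs.update(prov)
        cio.write_netcdf(obj, out / name)
    for name, tmap in res.transitions.items():
        tmap.attrs.update(prov)
        cio.write_transition_map(tmap, out / f"transitions_{name}.nc")
    df = res.summary_frame()
    df.to_csv(out / "area_summary.csv", index=False)
    (out / "provenance.json").write_text(json.dumps(
        {**prov, "config": res.config.__dict__}, indent=2, default=str))
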