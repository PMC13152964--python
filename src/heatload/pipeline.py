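"""End-to-end orchestration: QC -> climatology -> ensemble -> HLI -> exposure.

A run is described by a :class:`RunConfig` (loadable from YAML).  The first
configured period is the climatological baseline and is read from the
``historical`` scenario; every later period is read from each configured
scenario.  All constants of the method — the welfare thresholds, the BGT
branch point, the formula coefficients, the Earth radius — live in the config
with the published values as defaults, so an alternative calibration can be
supplied without code changes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import xarray as xr
import yaml

from .climate_io import GridSpec, LandMask, qc_clean, read_daily_fields
from .exposure import build_summary, cell_areas, load_regions_geojson, \
    rasterize_regions, EARTH_RADIUS_KM
from .hli import HliCoefficients, hli_from_climatology
from .seasonal import Period, SEASONS, build_climatology, ensemble_mean

__all__ = ["RunConfig", "PipelineError", "PipelineResult",
           "validate_config", "run_pipeline"]

log = logging.getLogger("heatload")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


@dataclass
class RunConfig:
    """Everything a pipeline run needs; paths are resolved when used."""

    archive_dir: str
    out_dir: str
    models: list = field(default_factory=list)        # empty: all in manifest
    scenarios: list = field(default_factory=list)     # empty: all non-historical
    periods: list = field(default_factory=list)       # [[label, y0, y1], ...]; first = baseline
    seasons: list = field(default_factory=lambda: list(SEASONS))
    thresholds: list = field(default_factory=lambda: [70.0, 77.0, 86.0, 96.0])
    branch_bgt: float = 25.0
    min_coverage: float = 0.9
    earth_radius_km: float = EARTH_RADIUS_KM
    land_mask_path: str = ""      # default: <archive_dir>/land_mask.nc
    region_path: str = ""         # optional GeoJSON of country polygons
    subzero: str = "comfort"
    djf_spanning: bool = False
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def period_objects(self) -> list[Period]:
        return [Period(str(p[0]), int(p[1]), int(p[2])) for p in self.periods]

    def coefficients(self) -> HliCoefficients:
        return HliCoefficients(branch_bgt=self.branch_bgt,
                               thresholds=tuple(float(t) for t in self.thresholds))


def validate_config(config: RunConfig) -> list[str]:
    """Return the list of violations (empty list means valid)."""
    v = []
    if not os.path.isdir(config.archive_dir):
        v.append(f"archive_dir does not exist: {config.archive_dir}")
    elif not os.path.exists(os.path.join(config.archive_dir, "manifest.csv")):
        v.append(f"no manifest.csv in archive_dir {config.archive_dir}")
    thr = list(config.thresholds)
    if sorted(thr) != thr or len(set(thr)) != len(thr):
        v.append(f"thresholds must be strictly increasing: {thr}")
    if not 0 <= config.min_coverage <= 1:
        v.append(f"min_coverage must be in [0, 1]: {config.min_coverage}")
    if config.earth_radius_km <= 0:
        v.append("earth_radius_km must be positive")
    if len(config.periods) < 2:
        v.append("need a baseline period plus at least one projection period")
    for p in config.periods:
        if len(p) != 3 or int(p[1]) > int(p[2]):
            v.append(f"bad period spec {p!r} (want [label, start_year, end_year])")
    for s in config.seasons:
        if s not in SEASONS:
            v.append(f"unknown season {s!r}")
    if config.subzero not in ("comfort", "missing"):
        v.append(f"subzero must be 'comfort' or 'missing': {config.subzero!r}")
    mask_path = config.land_mask_path or os.path.join(config.archive_dir, "land_mask.nc")
    if not os.path.exists(mask_path):
        v.append(f"land mask not found: {mask_path}")
    if config.region_path and not os.path.exists(config.region_path):
        v.append(f"region layer not found: {config.region_path}")
    return v


@dataclass
class PipelineResult:
    summary: pd.DataFrame
    summary_path: str
    outputs: dict


def _load_mask(path: str) -> LandMask:
    ds = xr.open_dataset(path)
    mask = LandMask(grid=GridSpec.from_dataset(ds),
                    is_land=np.asarray(ds["is_land"]).astype(bool))
    ds.close()
    return mask


def _setup_logging(config: RunConfig) -> None:
    log.setLevel(config.log_level.upper())
    if not any(isinstance(h, logging.StreamHandler) for h in log.handlers):
        h = logging.StreamHandler()
        h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        log.addHandler(h)
    os.makedirs(config.out_dir, exist_ok=True)
    fpath = os.path.join(config.out_dir, "run.log")
    if not any(getattr(h, "baseFilename", "") == os.path.abspath(fpath)
               for h in log.handlers):
        fh = logging.FileHandler(fpath, mode="w")
        fh.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        log.addHandler(fh)


def _read_model_fields(config: RunConfig, manifest: pd.DataFrame, model: str,
                       scenario: str, period: Period):
    """Read and QC the four variables of one model/scenario/period."""
    sel = manifest[(manifest["model"] == model)
                   & (manifest["scenario"] == scenario)
                   & (manifest["period"] == period.label)]
    if sel.empty:
        raise PipelineError(
            f"stage=read: no archive files for model {model!r}, scenario "
            f"{scenario!r}, period {period.label!r}")
    fields = []
    for _, row in sel.iterrows():
        path = os.path.join(config.archive_dir, row["path"])
        if not os.path.exists(path):
            raise PipelineError(f"stage=read: model {model!r} file missing: {path}")
        try:
            raw = read_daily_fields(path, row["variable"])
        except Exception as exc:
            raise PipelineError(
                f"stage=read: model {model!r} file {path}: {exc}") from exc
        clean = qc_clean(raw)
        clean.model_id = clean.model_id or model
        clean.scenario_id = clean.scenario_id or scenario
        log.info("qc %s/%s/%s %s: %s", model, scenario, period.label,
                 row["variable"],
                 ", ".join(f"{k}={v}" for k, v in sorted(clean.qc_counts.items())))
        fields.append(clean)
    return fields


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full chain and write all outputs under ``config.out_dir``.

    Deterministic given config and inputs: rerunning with identical inputs
    produces an identical summary table.  Outputs: per-combination NetCDF of
    ensemble HLI/BGT/category, the exposure summary CSV, a per-country CSV
    when a region layer is configured, a JSON manifest with SHA-256 hashes of
    every product, and ``run.log``.
    """
    violations = validate_config(config)
    if violations:
        raise PipelineError("stage=validate: " + "; ".join(violations))
    _setup_logging(config)
    manifest = pd.read_csv(os.path.join(config.archive_dir, "manifest.csv"))
    models = list(config.models) or sorted(manifest["model"].unique())
    scenarios = list(config.scenarios) or sorted(
        s for s in manifest["scenario"].unique() if s != "historical")
    periods = config.period_objects()
    baseline, proj_periods = periods[0], periods[1:]
    coeffs = config.coefficients()
    mask = _load_mask(config.land_mask_path
                      or os.path.join(config.archive_dir, "land_mask.nc"))

    grids_dir = os.path.join(config.out_dir, "grids")
    os.makedirs(grids_dir, exist_ok=True)
    outputs = {}
    category_grids, baseline_grids = {}, {}

    combos = [("historical", baseline)] + [(sc, p) for p in proj_periods
                                           for sc in scenarios]
    for scenario, period in combos:
        per_model = {}
        for model in models:
            fields = _read_model_fields(config, manifest, model, scenario, period)
            per_model[model] = fields
        for season_label in config.seasons:
            season = SEASONS[season_label]
            try:
                clims = [build_climatology(per_model[m], period, season,
                                           config.min_coverage, config.djf_spanning)
                         for m in models]
                mme = ensemble_mean(clims)
            except Exception as exc:
                raise PipelineError(
                    f"stage=climatology: {scenario}/{period.label}/{season_label}: "
                    f"{exc}") from exc
            hli_field, cats = hli_from_climatology(mme, coeffs, config.subzero)
            cats.codes = cats.codes.where(
                xr.DataArray(mask.is_land, dims=("lat", "lon"),
                             coords={"lat": mask.grid.lat, "lon": mask.grid.lon}),
                other=-1).astype("int8")
            key = f"{scenario}_{period.label}_{season_label}"
            ds = xr.Dataset({"bgt": hli_field.bgt, "hli": hli_field.hli,
                             "category": cats.codes})
            ds.attrs.update(scenario=scenario, period=period.label,
                            season=season_label, source="MME")
            path = os.path.join(grids_dir, f"hli_{key}.nc")
            ds.to_netcdf(path)
            outputs[f"grid:{key}"] = path
            if scenario == "historical":
                baseline_grids[season_label] = cats
            else:
                category_grids[(season_label, period.label, scenario)] = cats
            log.info("hli %s done", key)

    areas = cell_areas(mask.grid, config.earth_radius_km)
    regions = None
    if config.region_path:
        regions = rasterize_regions(load_regions_geojson(config.region_path),
                                    mask.grid)
    try:
        summary = build_summary(category_grids, baseline_grids, areas, mask,
                                regions, seasons=tuple(config.seasons),
                                periods=tuple(p.label for p in proj_periods),
                                scenarios=tuple(scenarios),
                                baseline_label=baseline.label)
    except Exception as exc:
        raise PipelineError(f"stage=exposure: {exc}") from exc

    summary_path = os.path.join(config.out_dir, "exposure_summary.csv")
    summary.to_csv(summary_path, index=False)
    outputs["summary"] = summary_path
    if regions is not None:
        country = summary[summary["region_id"] != "GLOBAL"]
        cpath = os.path.join(config.out_dir, "exposure_by_country.csv")
        country.to_csv(cpath, index=False)
        outputs["summary_by_country"] = cpath

    hashes = {}
    for name, path in sorted(outputs.items()):
        with open(path, "rb") as fh:
            hashes[name] = hashlib.sha256(fh.read()).hexdigest()
    with open(os.path.join(config.out_dir, "outputs.json"), "w") as fh:
        json.dump({"outputs": outputs, "sha256": hashes}, fh, indent=2, sort_keys=True)
    log.info("pipeline complete: %d summary rows", len(summary))
    return PipelineResult(summary=summary, summary_path=summary_path,
                          outputs=outputs)
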