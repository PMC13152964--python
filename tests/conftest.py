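"""Shared fixtures: in-memory daily fields and session-scoped synthetic runs."""

import logging
from dataclasses import replace

import numpy as np
import pytest
import xarray as xr

from heatload import (DailyClimateField, GridSpec, RunConfig, SyntheticConfig,
                      generate_archive, run_pipeline)
from heatload.synthetic import SyntheticTruth

logging.getLogger("heatload").setLevel(logging.WARNING)


def make_field(values, variable="air_temperature", start="2000-01-01",
               calendar="noleap", lat0=0.125, lon0=0.125, step=0.25,
               model_id="m1", scenario_id="historical", units=None):
    """Build a DailyClimateField from a (time, lat, lon) array."""
    values = np.asarray(values, dtype=float)
    n_t, nlat, nlon = values.shape
    time = xr.date_range(start=start, periods=n_t, freq="D",
                         calendar=calendar, use_cftime=True)
    grid = GridSpec.regular(nlat, nlon, lat0, lon0, step)
    da = xr.DataArray(values, dims=("time", "lat", "lon"),
                      coords={"time": time, "lat": grid.lat, "lon": grid.lon})
    from heatload.climate_io import VARIABLES
    return DailyClimateField(variable=variable, data=da, model_id=model_id,
                             scenario_id=scenario_id,
                             units=units if units is not None else VARIABLES[variable])


def zero_noise_config(seed=7, variables=None, **kw):
    base = variables if variables is not None else SyntheticConfig().variables
    silenced = {k: replace(v, noise_sd=0.0) for k, v in base.items()}
    return SyntheticConfig(seed=seed, variables=silenced,
                           missing_rate=0.0, sentinel_rate=0.0, **kw)


def run_synthetic(cfg, root, name):
    """Generate an archive under root/name, run the pipeline, return pieces."""
    archive = str(root / f"arch_{name}")
    out = str(root / f"out_{name}")
    _, truth = generate_archive(cfg, archive)
    rc = RunConfig(archive_dir=archive, out_dir=out,
                   periods=[[p.label, p.start_year, p.end_year]
                            for p in cfg.periods],
                   region_path=f"{archive}/regions.geojson",
                   log_level="WARNING")
    result = run_pipeline(rc)
    return cfg, truth, result, rc


@pytest.fixture(scope="session")
def zero_noise_run(tmp_path_factory):
    root = tmp_path_factory.mktemp("zn")
    return run_synthetic(zero_noise_config(), root, "zn")


@pytest.fixture(scope="session")
def noisy_runs(tmp_path_factory):
    """Default (noisy) archives and pipeline runs for seeds 1..5."""
    root = tmp_path_factory.mktemp("noisy")
    out = {}
    for seed in range(1, 6):
        cfg = SyntheticConfig(seed=seed)
        out[seed] = run_synthetic(cfg, root, f"s{seed}")
    return out


@pytest.fixture()
def truth_only():
    """Analytic truth for the default config, no files generated."""
    return SyntheticTruth(SyntheticConfig(seed=0))
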