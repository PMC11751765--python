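"""NetCDF/CSV input-output with provenance stamps."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

__all__ = ["write_netcdf", "read_grid_netcdf", "write_table", "provenance_attrs"]

_ENGINE = "scipy"  # NetCDF-3 backend


def provenance_attrs(config_hash: str, seed: int, extra: dict | None = None) -> dict:
    attrs = {"config_hash": config_hash, "seed": int(seed)}
    if extra:
        attrs["provenance"] = json.dumps(extra, sort_keys=True)
    return attrs


def write_netcdf(ds: xr.Dataset, path, config_hash: str = "", seed: int = 0, extra=None):
    """Write a dataset with an embedded provenance block (deterministic:
    no wall-clock metadata)."""
    ds = ds.copy()
    ds.attrs.update(provenance_attrs(config_hash, seed, extra))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ds.to_netcdf(path, engine=_ENGINE)
    return path


def read_grid_netcdf(path, variable_map=None, expect_daily=True):
    """Read a gridded cube, validating dimensions, variables and calendar.

    Parameters
    ----------
    variable_map : mapping of canonical name -> file variable name; the
        returned dataset uses the canonical names.
    expect_daily : require a strictly daily time step.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ds = xr.open_dataset(path, engine=_ENGINE)
    missing_dims = {"time", "lat", "lon"} - set(ds.dims)
    if missing_dims:
        raise ValueError(f"{path}: missing dimensions {sorted(missing_dims)}")
    if variable_map:
        absent = [v for v in variable_map.values() if v not in ds.data_vars]
        if absent:
            raise KeyError(
                f"{path}: variables {absent} not found; available: "
                f"{sorted(ds.data_vars)}"
            )
        ds = ds[list(variable_map.values())].rename(
            {v: k for k, v in variable_map.items()}
        )
    t = pd.DatetimeIndex(ds["time"].values)
    if expect_daily and len(t) > 1:
        steps = np.unique(np.diff(t.values).astype("timedelta64[D]"))
        if not (len(steps) == 1 and steps[0] == np.timedelta64(1, "D")):
            raise ValueError(
                f"{path}: expected a daily calendar, found steps {steps.tolist()}"
            )
    return ds.load()


def write_table(df: pd.DataFrame, path, config_hash: str = "", seed: int = 0):
    """CSV writer with a provenance header comment."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config_hash} seed={seed}\n")
        df.to_csv(fh)
    return path
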