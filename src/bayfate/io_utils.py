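"""Gridded and tabular output writers.

Gridded fields go to a self-describing NetCDF file (written through xarray
with the scipy backend, i.e. classic NetCDF3) with x/y cell-center
coordinates in metres; station records and the mass ledger go to CSV.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import xarray as xr

from .grid import BayGrid


def fields_to_dataset(
    grid: BayGrid, fields: Dict[str, np.ndarray], attrs: Optional[Dict[str, str]] = None
) -> xr.Dataset:
    """Bundle (nx, ny) cell fields into an xarray Dataset with coordinates."""
    coords = {"x": ("x", grid.x_centers()), "y": ("y", grid.y_centers())}
    data = {}
    for name, arr in fields.items():
        arr = np.asarray(arr)
        if arr.shape != (grid.nx, grid.ny):
            raise ValueError(f"field {name!r} has shape {arr.shape}, expected {(grid.nx, grid.ny)}")
        data[name] = (("x", "y"), arr)
    ds = xr.Dataset(data, coords=coords)
    ds.attrs.update(attrs or {})
    return ds


def write_fields(
    grid: BayGrid,
    fields: Dict[str, np.ndarray],
    path: str | Path,
    attrs: Optional[Dict[str, str]] = None,
) -> None:
    """Write cell fields to a NetCDF file (classic format via scipy)."""
    ds = fields_to_dataset(grid, fields, attrs)
    ds.to_netcdf(path, engine="scipy")


def write_ledger_csv(ledger_history: pd.DataFrame, path: str | Path) -> None:
    ledger_history.to_csv(path, index=False)
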