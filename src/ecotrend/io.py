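"""NetCDF / JSON round-tripping of cubes, trend maps and scenario truth.

Cubes and map layers travel as CF-style NetCDF (dims time/lat/lon, written
with xarray's scipy backend).  Scenario ground truth is a small JSON file:
region masks as run-length-encoded flat indices plus the injected slopes.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import xarray as xr

from .grid import Grid
from .synthetic import RegionTrend

__all__ = [
    "save_cube", "load_cube",
    "save_dataset", "load_dataset",
    "rle_encode", "rle_decode",
    "save_truth", "load_truth",
]

_ENGINE = "scipy"  # NetCDF3; no binary HDF5 dependency


def save_cube(cube: xr.DataArray, path) -> None:
    ds = cube.to_dataset(name=cube.name or "value")
    ds.attrs.update(cube.attrs)
    ds.to_netcdf(path, engine=_ENGINE)


def load_cube(path, variable: str | None = None) -> xr.DataArray:
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        name = variable or next(iter(ds.data_vars))
        da = ds[name].load()
    da.attrs.update(ds.attrs)
    return da


def save_dataset(ds: xr.Dataset, path) -> None:
    ds.to_netcdf(path, engine=_ENGINE)


def load_dataset(path) -> xr.Dataset:
    with xr.open_dataset(path, engine=_ENGINE) as ds:
        return ds.load()


def rle_encode(mask: np.ndarray) -> list[list[int]]:
    """Run-length encode a boolean grid (row-major) as [start, length] runs."""
    flat = np.asarray(mask, dtype=bool).ravel()
    runs = []
    idx = np.flatnonzero(np.diff(np.concatenate(([0], flat.view(np.int8), [0]))))
    for start, stop in zip(idx[::2], idx[1::2]):
        runs.append([int(start), int(stop - start)])
    return runs


def rle_decode(runs: list[list[int]], shape: tuple[int, int]) -> np.ndarray:
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    for start, length in runs:
        flat[start:start + length] = True
    return flat.reshape(shape)


def save_truth(regions: list[RegionTrend], grid: Grid, seed: int, path) -> None:
    payload = {
        "seed": int(seed),
        "shape": list(grid.shape),
        "cell_km": grid.cell_km,
        "regions": [
            {"label": r.label, "slopes": {k: float(v) for k, v in r.slopes.items()},
             "mask_rle": rle_encode(r.mask)}
            for r in regions
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_truth(path) -> tuple[list[RegionTrend], int]:
    payload = json.loads(Path(path).read_text())
    shape = tuple(payload["shape"])
    regions = [
        RegionTrend(label=r["label"], mask=rle_decode(r["mask_rle"], shape),
                    slopes=r["slopes"])
        for r in payload["regions"]
    ]
    return regions, int(payload["seed"])
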