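import numpy as np
import pytest
import xarray as xr

from ecotrend.grid import Grid
from ecotrend.trend import monthly_time_index


@pytest.fixture
def small_grid() -> Grid:
    return Grid.regular(8, 8, cell_km=25.0, lat0=-10.0)


def make_cube(values: np.ndarray, grid: Grid, name: str = "sm",
              start_year: int = 2010) -> xr.DataArray:
    """Wrap a (time, lat, lon) array as a monthly DataArray on a grid."""
    n_time = values.shape[0]
    assert n_time % 12 == 0
    return xr.DataArray(
        values, dims=("time", "lat", "lon"),
        coords={"time": monthly_time_index(start_year, n_time // 12),
                "lat": grid.lat_centers, "lon": grid.lon_centers},
        name=name, attrs={"cell_km": grid.cell_km})


def make_trend_map(grid: Grid, p: np.ndarray, slope: np.ndarray,
                   mean: np.ndarray, variable: str = "sm",
                   alpha_cell: float = 0.05) -> xr.Dataset:
    """Minimal trend-map dataset with the layers the merge step consumes."""
    ds = xr.Dataset(
        {"p": (("lat", "lon"), p), "sen_slope": (("lat", "lon"), slope),
         "mean": (("lat", "lon"), mean)},
        coords={"lat": grid.lat_centers, "lon": grid.lon_centers})
    ds["significant"] = (ds["p"] < alpha_cell).fillna(False)
    ds.attrs = {"variable": variable, "alpha_cell": alpha_cell}
    return ds
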