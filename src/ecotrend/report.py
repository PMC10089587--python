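"""Per-cluster time-series summaries and tables.

Each detected cluster is characterised by its annual, area-weighted spatial
mean series (annual mean of monthly values for state variables; annual
cumulative total for precipitation), per-year spatial boxplot statistics,
Sen and OLS trends with the relative (%/yr) rate, temporal R² between
variables, and tables of the pooled annual-distribution quantiles for
chosen years.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats

from .grid import Grid
from .trend import QUANTILE_LEVELS, ols_slope, relative_trend, sen_slope

__all__ = [
    "ClusterSeries",
    "cluster_annual_series",
    "series_r2",
    "quantile_table",
]


@dataclass
class ClusterSeries:
    """Annual summary of one variable inside one cluster.

    ``values`` is the area-weighted spatial mean of the per-cell annual
    aggregate; ``box`` holds per-year spatial distribution statistics
    (median, quartiles, 1.5·IQR whiskers).  Trends are in units/yr;
    ``rel_trend`` is 100·sen_trend/series-mean in %/yr.
    """

    variable: str
    years: np.ndarray
    values: np.ndarray
    box: pd.DataFrame
    sen_trend: float
    ols_trend: float
    ols_trend_sd: float
    rel_trend: float


def _annual_aggregate(cube: xr.DataArray, how: str) -> xr.DataArray:
    """Per-cell annual aggregate: 'mean' of monthly values, or 'sum'
    (annual total, estimated as 12 × the mean of available months)."""
    years = cube["time"].dt.year.rename("year")
    ann = cube.groupby(years).mean(dim="time", skipna=True)
    n_valid = cube.notnull().groupby(years).sum(dim="time")
    n_months = xr.ones_like(cube.isel(lat=0, lon=0, drop=True)).groupby(
        years).sum(dim="time")
    ann = ann.where(n_valid > 0.5 * n_months)
    if how == "sum":
        ann = ann * 12.0
    elif how != "mean":
        raise ValueError("annual aggregate must be 'mean' or 'sum'")
    return ann.transpose("year", "lat", "lon")


def cluster_annual_series(cube: xr.DataArray, mask: np.ndarray, grid: Grid,
                          how: str = "mean") -> ClusterSeries:
    """Annual area-weighted spatial mean series over a cluster mask.

    ``how='sum'`` yields annual cumulative values (use for precipitation).
    """
    m = np.asarray(mask, dtype=bool)
    grid.same_shape(m)
    if not m.any():
        raise ValueError("cluster mask is empty")
    ann = _annual_aggregate(cube, how)
    years = ann["year"].values
    vals = ann.values[:, m]                      # (n_years, n_cells)
    w = grid.area_map()[m]
    w = w / w.sum()
    with np.errstate(invalid="ignore"):
        series = np.nansum(vals * w[None, :], axis=1) / np.nansum(
            np.where(np.isnan(vals), 0.0, w[None, :]), axis=1)

    rows = []
    for t, year in enumerate(years):
        x = vals[t][np.isfinite(vals[t])]
        q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])
        iqr = q3 - q1
        lo = x[x >= q1 - 1.5 * iqr].min()
        hi = x[x <= q3 + 1.5 * iqr].max()
        rows.append({"year": int(year), "median": med, "q1": q1, "q3": q3,
                     "whisker_lo": lo, "whisker_hi": hi})
    box = pd.DataFrame(rows).set_index("year")

    if np.ptp(series) == 0:
        sen, ols, ols_sd = 0.0, 0.0, 0.0
    else:
        sen = sen_slope(series)
        ols, ols_sd = ols_slope(series)
    ref = float(series.mean())
    rel = relative_trend(sen, ref) if ref != 0 else float("nan")
    return ClusterSeries(variable=str(cube.name), years=years, values=series,
                         box=box, sen_trend=sen, ols_trend=ols,
                         ols_trend_sd=ols_sd, rel_trend=rel)


def series_r2(x, y) -> float:
    """Squared Pearson correlation between two equal-length annual series."""
    xa, ya = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.size < 3:
        raise ValueError("series must share a length of at least 3")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("R² undefined for a constant series")
    r, _ = stats.pearsonr(xa, ya)
    return float(r * r)


def quantile_table(cube: xr.DataArray, mask: np.ndarray, years,
                   levels=QUANTILE_LEVELS) -> pd.DataFrame:
    """Quantiles of the pooled (spatial × monthly) in-mask distribution.

    One row per requested year, columns Q10..Q90 (or the given levels).
    """
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("cluster mask is empty")
    available = set(int(y) for y in np.unique(cube["time"].dt.year.values))
    rows = {}
    for year in years:
        if int(year) not in available:
            raise ValueError(f"year {year} outside the cube's span")
        sel = cube.sel(time=cube["time"].dt.year == int(year))
        pooled = sel.values[:, m].ravel()
        pooled = pooled[np.isfinite(pooled)]
        rows[int(year)] = np.quantile(pooled, levels)
    cols = [f"Q{int(round(100 * q))}" for q in levels]
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)
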