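"""End-to-end pipeline driver: trend → field significance → merge →
bivariate clustering → land-cover change → per-cluster reports.

The driver consumes either a synthetic scenario (generated on the fly from a
seed) or a directory of NetCDF cubes, runs the whole detection chain for the
variables sm/vod/precip at every configured quantile level, and writes maps
(NetCDF), tables (CSV) and a JSON run manifest.  Identical config + seed
reproduce identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from . import __version__
from .field_significance import (FieldSigConfig, permutation_null_from_annual,
                                 retain_significant_clusters)
from .grid import Grid
from .io import save_cube, save_dataset, save_truth
from .landcover import cluster_landcover_summary, epoch_difference
from .merge import ChangeMap, ClusterSet, bivariate_cluster, merge_quantile_maps
from .report import cluster_annual_series, quantile_table, series_r2
from .synthetic import Scenario, make_five_cluster_scenario
from .trend import QUANTILE_LEVELS, annual_quantile_series, trend_map_from_annual

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

_TREND_VARS = ("sm", "vod", "precip")


@dataclass
class PipelineConfig:
    """Configuration of a full run.

    Either ``scenario_seed`` (synthetic input, default) or ``input_dir``
    (NetCDF cubes named ``<var>.nc``) must be set.
    """

    seed: int = 0
    scenario_seed: int | None = 0
    input_dir: str | None = None
    out_dir: str | None = None
    n_years: int = 10
    noise_scale: float = 1.0
    quantiles: tuple = QUANTILE_LEVELS
    alpha_cell: float = 0.05
    field_threshold: float = 0.95
    n_perm: int = 200
    connectivity: int = 8
    min_area_cells: int = 20
    precip_rel_threshold: float = 1.0

    def field_config(self, seed: int) -> FieldSigConfig:
        return FieldSigConfig(alpha_cell=self.alpha_cell,
                              field_threshold=self.field_threshold,
                              n_perm=self.n_perm,
                              connectivity=self.connectivity, seed=seed)


@dataclass
class PipelineResult:
    """Everything a run produced, in memory."""

    change_maps: dict[str, ChangeMap]
    clusters: ClusterSet
    cluster_series: dict[int, dict[str, object]]
    landcover_change: pd.DataFrame | None
    quantile_tables: dict[int, pd.DataFrame]
    manifest: dict
    scenario: Scenario | None = None


def _load_inputs(cfg: PipelineConfig):
    from .io import load_cube  # local to keep import cost minimal

    if cfg.input_dir is not None:
        base = Path(cfg.input_dir)
        cubes = {}
        for var in (*_TREND_VARS, "ndvi"):
            path = base / f"{var}.nc"
            if not path.exists():
                raise FileNotFoundError(
                    f"pipeline input missing: {path}")
            cubes[var] = load_cube(path, var)
        first = cubes["sm"]
        grid = Grid(lat_centers=first["lat"].values,
                    lon_centers=first["lon"].values,
                    cell_km=float(first.attrs.get("cell_km", 25.0)))
        return cubes, grid, None
    if cfg.scenario_seed is None:
        raise ValueError("config needs scenario_seed or input_dir")
    scen = make_five_cluster_scenario(seed=cfg.scenario_seed,
                                      n_years=cfg.n_years,
                                      noise_scale=cfg.noise_scale)
    return scen.cubes, scen.grid, scen


def variable_change_map(cube: xr.DataArray, grid: Grid, cfg: PipelineConfig,
                        seed: int) -> ChangeMap:
    """Quantile-wise trend maps + permutation retention, merged."""
    maps = []
    ss = np.random.SeedSequence(seed)
    q_seeds = ss.generate_state(len(cfg.quantiles))
    for q, q_seed in zip(cfg.quantiles, q_seeds):
        annual = annual_quantile_series(cube, q)
        tm = trend_map_from_annual(annual, alpha_cell=cfg.alpha_cell)
        fcfg = cfg.field_config(int(q_seed))
        null = permutation_null_from_annual(annual, fcfg)
        retained = retain_significant_clusters(tm, null, fcfg)
        maps.append((tm, retained))
    return merge_quantile_maps(maps, grid)


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Execute the full detection chain; write artifacts if out_dir is set."""
    cfg.field_config(0)  # validates alpha/threshold/n_perm/connectivity
    cubes, grid, scenario = _load_inputs(cfg)

    ss = np.random.SeedSequence(cfg.seed)
    var_seeds = dict(zip(_TREND_VARS, ss.generate_state(len(_TREND_VARS))))
    change = {var: variable_change_map(cubes[var], grid, cfg, int(var_seeds[var]))
              for var in _TREND_VARS}
    clusters = bivariate_cluster(change["sm"], change["vod"], change["precip"],
                                 min_area_cells=cfg.min_area_cells,
                                 connectivity=cfg.connectivity,
                                 precip_rel_threshold=cfg.precip_rel_threshold)

    years = np.unique(cubes["sm"]["time"].dt.year.values)
    series: dict[int, dict[str, object]] = {}
    qtables: dict[int, pd.DataFrame] = {}
    for label in clusters.table["label"]:
        mask = clusters.mask(int(label))
        per_var = {}
        for var, cube in cubes.items():
            how = "sum" if var == "precip" else "mean"
            per_var[var] = cluster_annual_series(cube, mask, grid, how=how)
        per_var["r2_sm_vod"] = series_r2(per_var["sm"].values,
                                         per_var["vod"].values)
        series[int(label)] = per_var
        qtables[int(label)] = pd.concat(
            {var: quantile_table(cubes[var], mask, [years[1], years[-2]])
             for var in ("sm", "vod")}, names=["variable", "year"])

    lc_change = None
    if scenario is not None:
        delta = epoch_difference(*scenario.landcover_epochs)
        classes = scenario.landcover_epochs[0].classes
        lc_change = pd.DataFrame(
            {int(label): cluster_landcover_summary(
                delta, clusters.mask(int(label)), grid, classes)
             for label in clusters.table["label"]})

    manifest = {
        "package": "ecotrend",
        "version": __version__,
        "seed": cfg.seed,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(cfg).items()},
        "n_clusters": clusters.n_clusters,
        "clusters": clusters.table.drop(columns=["precip_high"]).to_dict(
            orient="records"),
    }

    result = PipelineResult(change_maps=change, clusters=clusters,
                            cluster_series=series, landcover_change=lc_change,
                            quantile_tables=qtables, manifest=manifest,
                            scenario=scenario)
    if cfg.out_dir is not None:
        _write_outputs(result, cfg)
    return result


def _write_outputs(result: PipelineResult, cfg: PipelineConfig) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for var, cm in result.change_maps.items():
        save_dataset(cm.to_dataset(), out / f"change_{var}.nc")
    labels = xr.Dataset(
        {"labels": (("lat", "lon"), result.clusters.labels)},
        coords={"lat": result.clusters.grid.lat_centers,
                "lon": result.clusters.grid.lon_centers})
    save_dataset(labels, out / "cluster_labels.nc")
    result.clusters.table.to_csv(out / "clusters.csv", index=False)
    if result.landcover_change is not None:
        result.landcover_change.to_csv(out / "landcover_change_km2.csv")
    rows = []
    for label, per_var in result.cluster_series.items():
        for var in ("sm", "vod", "ndvi", "precip"):
            cs = per_var[var]
            rows.append({"label": label, "variable": var,
                         "sen_trend": cs.sen_trend, "ols_trend": cs.ols_trend,
                         "ols_trend_sd": cs.ols_trend_sd,
                         "rel_trend_pct_yr": cs.rel_trend,
                         "r2_sm_vod": per_var["r2_sm_vod"]})
    pd.DataFrame(rows).to_csv(out / "cluster_trends.csv", index=False)
    if result.scenario is not None:
        save_truth(result.scenario.truth_regions, result.scenario.grid,
                   result.scenario.seed, out / "truth.json")
    (out / "manifest.json").write_text(json.dumps(result.manifest, indent=1,
                                                  default=float))
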