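"""Merging quantile-wise trend maps and bivariate SM/VOD change clustering.

A variable's change is tested independently at five quantile levels of each
cell's annual distribution; the per-quantile, field-significant maps are then
merged into one signed ChangeMap (a cell changes if any quantile's retained
cluster covers it; its sign is the majority sign over significant quantiles,
ties discarded).  Combining the SM and VOD ChangeMaps in bivariate trend-sign
space, splitting the (+,+) group by the precipitation trend and the (−,−)
group by joint trend magnitude, and decomposing into connected components
yields the labeled ecosystem-change clusters:

=========  =====================  ==========================================
category   (sign SM, sign VOD)    auxiliary split
=========  =====================  ==========================================
A          (+, +)                 precipitation rel. trend above threshold
D          (+, +)                 precipitation rel. trend below threshold
B          (−, −)                 milder joint magnitude
E          (−, −)                 stronger joint magnitude
C          (−, +)                 —
X          (+, −)                 — (not observed in the real record)
=========  =====================  ==========================================
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xarray as xr
from sklearn.metrics import silhouette_score

from .field_significance import LabeledClusters, label_clusters
from .grid import Grid

__all__ = [
    "ChangeMap",
    "ClusterSet",
    "merge_quantile_maps",
    "bivariate_cluster",
    "separability_score",
    "cluster_area",
]


@dataclass
class ChangeMap:
    """Merged, field-significant signed change map for one variable.

    ``slope`` (units/yr) is the median Sen slope over the significant
    quantiles where the cell is significant, and over all quantiles elsewhere
    (so a sign/magnitude is always available as auxiliary information);
    ``rel_slope`` is 100·slope/mean in %/yr.  ``sign`` is 0 wherever
    ``significant`` is False.
    """

    variable: str
    grid: Grid
    significant: np.ndarray
    sign: np.ndarray
    slope: np.ndarray
    rel_slope: np.ndarray

    def __post_init__(self) -> None:
        for a in (self.significant, self.sign, self.slope, self.rel_slope):
            self.grid.same_shape(np.asarray(a))
        if np.any(self.sign[~self.significant] != 0):
            raise ValueError("sign must be 0 where not significant")

    def to_dataset(self) -> xr.Dataset:
        ds = xr.Dataset(
            {
                "significant": (("lat", "lon"), self.significant.astype("i1")),
                "sign": (("lat", "lon"), self.sign.astype("i1")),
                "slope": (("lat", "lon"), self.slope),
                "rel_slope": (("lat", "lon"), self.rel_slope),
            },
            coords={"lat": self.grid.lat_centers, "lon": self.grid.lon_centers},
        )
        ds.attrs = {"variable": self.variable, "cell_km": self.grid.cell_km}
        return ds

    @classmethod
    def from_dataset(cls, ds: xr.Dataset) -> "ChangeMap":
        grid = Grid(lat_centers=ds["lat"].values, lon_centers=ds["lon"].values,
                    cell_km=float(ds.attrs.get("cell_km", 25.0)))
        return cls(variable=str(ds.attrs.get("variable", "")), grid=grid,
                   significant=ds["significant"].values.astype(bool),
                   sign=ds["sign"].values.astype(int),
                   slope=ds["slope"].values, rel_slope=ds["rel_slope"].values)


def merge_quantile_maps(maps: list[tuple[xr.Dataset, LabeledClusters]],
                        grid: Grid) -> ChangeMap:
    """Merge per-quantile trend maps + retained clusters into one ChangeMap.

    A cell is significant if it lies inside a retained cluster for at least
    one quantile.  Its sign is the majority sign of the Sen slopes over those
    significant quantiles; an exact tie is conservatively treated as not
    significant.  The merged slope is the median Sen slope over significant
    quantiles (over all quantiles for non-significant cells).
    """
    if not maps:
        raise ValueError("no quantile maps to merge")
    variable = maps[0][0].attrs.get("variable", "")
    shape = grid.shape
    n_q = len(maps)
    sig_q = np.zeros((n_q, *shape), dtype=bool)
    slope_q = np.full((n_q, *shape), np.nan)
    mean_q = np.full((n_q, *shape), np.nan)
    for k, (tm, retained) in enumerate(maps):
        if tm["p"].shape != shape:
            raise ValueError("trend map grid mismatch")
        sig_q[k] = retained.labels > 0
        slope_q[k] = tm["sen_slope"].values
        mean_q[k] = tm["mean"].values

    pos = (sig_q & (slope_q > 0)).sum(axis=0)
    neg = (sig_q & (slope_q < 0)).sum(axis=0)
    significant = (pos + neg > 0) & (pos != neg)
    sign = np.where(significant, np.sign(pos - neg), 0).astype(int)

    slope_sig = np.where(sig_q, slope_q, np.nan)
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.filterwarnings("ignore", "All-NaN slice", RuntimeWarning)
        warnings.filterwarnings("ignore", "Mean of empty slice", RuntimeWarning)
        med_sig = np.nanmedian(slope_sig, axis=0)
        med_all = np.nanmedian(slope_q, axis=0)
        ref_mean = np.nanmean(mean_q, axis=0)
    slope = np.where(significant, med_sig, med_all)
    rel = np.full(shape, np.nan)
    np.divide(100.0 * slope, ref_mean, out=rel,
              where=np.isfinite(ref_mean) & (ref_mean != 0))
    return ChangeMap(variable=variable, grid=grid, significant=significant,
                     sign=sign, slope=slope, rel_slope=rel)


@dataclass
class ClusterSet:
    """Labeled ecosystem-change clusters with signatures and areas.

    ``labels`` is an integer grid (0 = background); ``table`` has one row per
    cluster: category (A/B/C/D/E/X), sign signature, precipitation-split
    flag, cell count, cosine-weighted area and member trend statistics.
    """

    labels: np.ndarray
    table: pd.DataFrame
    grid: Grid

    @property
    def n_clusters(self) -> int:
        return len(self.table)

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label

    def category_mask(self, category: str) -> np.ndarray:
        rows = self.table[self.table["category"] == category]
        return np.isin(self.labels, rows["label"].to_numpy())


def _two_class_split(values: np.ndarray, min_separation: float = 1.0
                     ) -> float | None:
    """Deterministic 1-D two-class threshold (within-variance minimising).

    Returns the midpoint between the two class means, or None when the best
    split separates the class centres by less than ``min_separation`` pooled
    standard deviations (the population is then treated as homogeneous).
    """
    x = np.sort(values[np.isfinite(values)])
    n = x.size
    if n < 4 or np.ptp(x) == 0:
        return None
    best, best_k = np.inf, None
    csum, csum2 = np.cumsum(x), np.cumsum(x * x)
    for k in range(2, n - 1):  # at least 2 members per side
        n1, n2 = k, n - k
        s1 = csum2[k - 1] - csum[k - 1] ** 2 / n1
        s2 = (csum2[-1] - csum2[k - 1]) - (csum[-1] - csum[k - 1]) ** 2 / n2
        if s1 + s2 < best:
            best, best_k = s1 + s2, k
    m1 = csum[best_k - 1] / best_k
    m2 = (csum[-1] - csum[best_k - 1]) / (n - best_k)
    pooled_sd = np.sqrt(best / (n - 2)) if best > 0 else 0.0
    if pooled_sd > 0 and (m2 - m1) < min_separation * pooled_sd:
        return None
    return float((m1 + m2) / 2.0)


def bivariate_cluster(sm: ChangeMap, vod: ChangeMap, precip: ChangeMap,
                      min_area_cells: int = 20, connectivity: int = 8,
                      precip_rel_threshold: float = 1.0,
                      magnitude_split: str = "auto") -> ClusterSet:
    """Group cells into labeled change clusters in SM/VOD trend-sign space.

    Cells significant in SM and/or VOD are categorised by their
    (sign SM, sign VOD) pair, the non-significant variable's sign taken from
    its slope layer.  (+,+) cells split into A (precipitation relative trend
    above ``precip_rel_threshold`` %/yr) vs D; (−,−) cells split into
    B (milder) vs E (stronger) by the joint relative-slope magnitude
    (``magnitude_split='auto'`` uses a deterministic two-class threshold; a
    float uses that fixed magnitude).  Each category is decomposed into
    connected components and components smaller than ``min_area_cells`` are
    dropped.
    """
    grid = sm.grid
    if vod.grid.shape != grid.shape or precip.grid.shape != grid.shape:
        raise ValueError("change maps live on different grids")
    cand = sm.significant | vod.significant
    s_sm = np.where(sm.significant, sm.sign, np.sign(sm.slope)).astype(int)
    s_vod = np.where(vod.significant, vod.sign, np.sign(vod.slope)).astype(int)
    valid = cand & (s_sm != 0) & (s_vod != 0)

    joint_mag = np.hypot(np.abs(sm.rel_slope), np.abs(vod.rel_slope))
    neg_neg = valid & (s_sm < 0) & (s_vod < 0)
    if magnitude_split == "auto":
        mag_thr = _two_class_split(joint_mag[neg_neg]) if neg_neg.any() else None
    else:
        mag_thr = float(magnitude_split)

    categories = {
        "A": valid & (s_sm > 0) & (s_vod > 0)
        & (precip.rel_slope > precip_rel_threshold),
        "D": valid & (s_sm > 0) & (s_vod > 0)
        & ~(precip.rel_slope > precip_rel_threshold),
        "B": neg_neg if mag_thr is None else neg_neg & (joint_mag <= mag_thr),
        "E": np.zeros_like(valid) if mag_thr is None
        else neg_neg & (joint_mag > mag_thr),
        "C": valid & (s_sm < 0) & (s_vod > 0),
        "X": valid & (s_sm > 0) & (s_vod < 0),
    }

    labels = np.zeros(grid.shape, dtype=int)
    rows = []
    nxt = 0
    for cat, mask in categories.items():
        comp = label_clusters(mask, connectivity=connectivity)
        for k in range(1, comp.n_clusters + 1):
            cmask = comp.labels == k
            if cmask.sum() < min_area_cells:
                continue
            nxt += 1
            labels[cmask] = nxt
            rows.append({
                "label": nxt,
                "category": cat,
                "sign_sm": int(np.sign(np.median(s_sm[cmask]))),
                "sign_vod": int(np.sign(np.median(s_vod[cmask]))),
                "precip_high": bool(cat == "A"),
                "n_cells": int(cmask.sum()),
                "area_km2": cluster_area(cmask, grid),
                "median_slope_sm": float(np.nanmedian(sm.slope[cmask])),
                "median_slope_vod": float(np.nanmedian(vod.slope[cmask])),
                "median_rel_slope_sm": float(np.nanmedian(sm.rel_slope[cmask])),
                "median_rel_slope_vod": float(np.nanmedian(vod.rel_slope[cmask])),
            })
    cols = ["label", "category", "sign_sm", "sign_vod", "precip_high",
            "n_cells", "area_km2", "median_slope_sm", "median_slope_vod",
            "median_rel_slope_sm", "median_rel_slope_vod"]
    table = pd.DataFrame(rows, columns=cols)
    return ClusterSet(labels=labels, table=table, grid=grid)


def separability_score(features: np.ndarray, labels: np.ndarray) -> float:
    """Mean silhouette coefficient of the labeled cells in z-scored
    feature space; in [−1, 1], higher = better separated clusters."""
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels)
    if np.unique(y).size < 2:
        raise ValueError("separability needs at least two clusters")
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xz = (X - X.mean(axis=0)) / sd
    return float(silhouette_score(Xz, y))


def cluster_area(mask: np.ndarray, grid: Grid) -> float:
    """Cosine-of-latitude-weighted area (km²) of a boolean cell mask."""
    m = np.asarray(mask, dtype=bool)
    grid.same_shape(m)
    return float((m * grid.area_map()).sum())
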