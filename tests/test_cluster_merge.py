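"""Tests of quantile-map merging, bivariate clustering and separability."""

import numpy as np
import pytest

from ecotrend.field_significance import LabeledClusters, label_clusters
from ecotrend.grid import Grid
from ecotrend.merge import (ChangeMap, bivariate_cluster, cluster_area,
                            merge_quantile_maps, separability_score)

from conftest import make_trend_map


def retained_from_mask(mask):
    lc = label_clusters(mask, connectivity=8)
    return lc


def quantile_maps(grid, sig_masks, slopes, mean=0.3):
    """Build (trend_map, retained) pairs from boolean masks + slope grids."""
    out = []
    for mask, slope in zip(sig_masks, slopes):
        p = np.where(mask, 0.001, 0.9)
        tm = make_trend_map(grid, p, slope, np.full(grid.shape, mean))
        out.append((tm, retained_from_mask(mask)))
    return out


def test_merge_unanimous_positive_cell(small_grid):
    shape = small_grid.shape
    mask = np.zeros(shape, bool)
    mask[2:6, 2:6] = True
    slopes = [np.full(shape, s) for s in (1.0, 2.0, 3.0, 4.0, 5.0)]
    maps = quantile_maps(small_grid, [mask] * 5, slopes)
    cm = merge_quantile_maps(maps, small_grid)
    assert cm.significant[3, 3]
    assert cm.sign[3, 3] == 1
    assert cm.slope[3, 3] == 3.0                      # median of 1..5
    assert not cm.significant[0, 0]
    assert cm.sign[0, 0] == 0


def test_merge_no_significant_quantiles(small_grid):
    shape = small_grid.shape
    maps = quantile_maps(small_grid, [np.zeros(shape, bool)] * 5,
                         [np.ones(shape)] * 5)
    cm = merge_quantile_maps(maps, small_grid)
    assert not cm.significant.any()
    assert (cm.sign == 0).all()


def test_merge_sign_tie_is_not_significant(small_grid):
    shape = small_grid.shape
    mask = np.zeros(shape, bool)
    mask[4, 4] = True
    slopes = [np.full(shape, s) for s in (1.0, 1.0, -1.0, -1.0)]
    maps = quantile_maps(small_grid, [mask] * 4, slopes)
    cm = merge_quantile_maps(maps, small_grid)
    assert not cm.significant[4, 4]
    assert cm.sign[4, 4] == 0


def test_merge_is_idempotent(small_grid):
    shape = small_grid.shape
    rng = np.random.default_rng(2)
    masks = [rng.random(shape) < 0.3 for _ in range(5)]
    slopes = [rng.normal(size=shape) for _ in range(5)]
    maps = quantile_maps(small_grid, masks, slopes)
    once = merge_quantile_maps(maps, small_grid)
    twice = merge_quantile_maps(maps + maps, small_grid)
    np.testing.assert_array_equal(once.significant, twice.significant)
    np.testing.assert_array_equal(once.sign, twice.sign)
    sig = once.significant
    np.testing.assert_allclose(once.slope[sig], twice.slope[sig])


def make_change_map(grid, variable, sig, slope, mean=0.3):
    slope = np.asarray(slope, float)
    sign = np.where(sig, np.sign(slope), 0).astype(int)
    rel = 100.0 * slope / mean
    return ChangeMap(variable=variable, grid=grid, significant=sig,
                     sign=sign, slope=slope, rel_slope=rel)


def test_bivariate_single_neg_pos_region_is_category_C(small_grid):
    shape = small_grid.shape
    region = np.zeros(shape, bool)
    region[1:6, 1:6] = True
    sm = make_change_map(small_grid, "sm", region,
                         np.where(region, -0.01, 1e-4))
    vod = make_change_map(small_grid, "vod", region,
                          np.where(region, 0.02, 1e-4))
    precip = make_change_map(small_grid, "precip", np.zeros(shape, bool),
                             np.zeros(shape), mean=80.0)
    cs = bivariate_cluster(sm, vod, precip, min_area_cells=5)
    assert cs.n_clusters == 1
    row = cs.table.iloc[0]
    assert row["category"] == "C"
    assert (row["sign_sm"], row["sign_vod"]) == (-1, 1)


def test_bivariate_min_area_filter_dominates(small_grid):
    shape = small_grid.shape
    region = np.zeros(shape, bool)
    region[2:4, 2:4] = True                      # 4 cells only
    sm = make_change_map(small_grid, "sm", region,
                         np.where(region, -0.01, 1e-4))
    vod = make_change_map(small_grid, "vod", region,
                          np.where(region, 0.02, 1e-4))
    precip = make_change_map(small_grid, "precip", np.zeros(shape, bool),
                             np.zeros(shape), mean=80.0)
    cs = bivariate_cluster(sm, vod, precip, min_area_cells=100)
    assert cs.n_clusters == 0


def test_bivariate_signature_consistency(small_grid):
    """Every clustered cell's category signs agree with the sign layers."""
    shape = small_grid.shape
    pos = np.zeros(shape, bool)
    pos[0:3, 0:3] = True
    neg = np.zeros(shape, bool)
    neg[5:8, 5:8] = True
    slope_sm = np.where(pos, 0.01, np.where(neg, -0.01, 1e-4))
    slope_vod = np.where(pos, 0.02, np.where(neg, -0.02, 1e-4))
    sm = make_change_map(small_grid, "sm", pos | neg, slope_sm)
    vod = make_change_map(small_grid, "vod", pos | neg, slope_vod)
    precip = make_change_map(small_grid, "precip", np.zeros(shape, bool),
                             np.where(pos, 4.0, 0.0), mean=80.0)
    cs = bivariate_cluster(sm, vod, precip, min_area_cells=4)
    assert cs.n_clusters == 2
    for _, row in cs.table.iterrows():
        cells = cs.mask(int(row["label"]))
        assert (np.sign(sm.slope[cells]) == row["sign_sm"]).all()
        assert (np.sign(vod.slope[cells]) == row["sign_vod"]).all()
    assert set(cs.table["category"]) == {"A", "B"}


def test_separability_well_separated_blobs():
    rng = np.random.default_rng(0)
    a = rng.normal([0, 0], 0.2, size=(100, 2))
    b = rng.normal([5, 5], 0.2, size=(100, 2))
    X = np.vstack([a, b])
    y = np.repeat([0, 1], 100)
    assert separability_score(X, y) > 0.7


def test_separability_random_labels_near_zero():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(200, 2))
    y = rng.integers(0, 2, size=200)
    assert abs(separability_score(X, y)) < 0.1


def test_separability_single_cluster_raises():
    with pytest.raises(ValueError):
        separability_score(np.zeros((10, 2)), np.zeros(10))


def test_cluster_area_equator_and_60N():
    eq = Grid(lat_centers=np.array([0.0]), lon_centers=np.array([10.0]),
              cell_km=25.0)
    assert cluster_area(np.ones((1, 1), bool), eq) == pytest.approx(625.0)
    g60 = Grid(lat_centers=np.array([60.0]), lon_centers=np.array([10.0]),
               cell_km=25.0)
    assert cluster_area(np.ones((1, 1), bool), g60) == pytest.approx(
        312.5, rel=0.01)


def test_cluster_area_additive(small_grid):
    a = np.zeros(small_grid.shape, bool)
    b = np.zeros(small_grid.shape, bool)
    a[0:2, 0:2] = True
    b[5:7, 5:7] = True
    assert cluster_area(a | b, small_grid) == pytest.approx(
        cluster_area(a, small_grid) + cluster_area(b, small_grid))
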