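"""Unit and property tests for the per-cell trend machinery."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ecotrend.grid import Grid
from ecotrend.synthetic import RegionTrend, SyntheticSpec, generate_cube
from ecotrend.trend import (annual_quantile_series, lag1_autocorrelation,
                            mk_statistic, prewhiten_ar1, relative_trend,
                            sen_slope, trend_map)

from conftest import make_cube


# -- independent oracles ----------------------------------------------------

def mk_oracle(y):
    """Exhaustive O(n²) pair count + textbook tie-corrected variance."""
    y = np.asarray(y, float)
    n = y.size
    S = sum(np.sign(y[j] - y[i]) for i in range(n) for j in range(i + 1, n))
    _, counts = np.unique(y, return_counts=True)
    ties = sum(int(t) * (t - 1) * (2 * t + 5) for t in counts if t > 1)
    var = (n * (n - 1) * (2 * n + 5) - ties) / 18.0
    return S, var


def sen_oracle(y):
    y = np.asarray(y, float)
    slopes = [(y[j] - y[i]) / (j - i)
              for i in range(y.size) for j in range(i + 1, y.size)]
    return float(np.median(slopes))


# -- lag-1 autocorrelation / pre-whitening ----------------------------------

@pytest.mark.parametrize("series, expected", [
    ([1, 2, 3, 4, 5], 0.4),
    ([7.0] * 6, 0.0),                       # constant → defined fallback
])
def test_lag1_known_values(series, expected):
    assert lag1_autocorrelation(series) == pytest.approx(expected)


def test_lag1_alternating_series_is_negative():
    assert lag1_autocorrelation([1, -1, 1, -1, 1, -1]) < 0


def test_lag1_rejects_short_series():
    with pytest.raises(ValueError):
        lag1_autocorrelation([1.0, 2.0])


def test_prewhiten_known_series():
    np.testing.assert_allclose(prewhiten_ar1([1, 2, 3, 4, 5]),
                               [1.6, 2.2, 2.8, 3.4])


def test_prewhiten_white_series_is_identity_shift():
    rng = np.random.default_rng(0)
    y = rng.normal(size=40)
    r1 = lag1_autocorrelation(y)
    np.testing.assert_allclose(prewhiten_ar1(y), y[1:] - r1 * y[:-1])


def test_prewhiten_removes_serial_correlation():
    rng = np.random.default_rng(3)
    n = 200
    y = np.empty(n)
    y[0] = rng.normal()
    for t in range(1, n):
        y[t] = 0.7 * y[t - 1] + rng.normal()
    r1_resid = lag1_autocorrelation(prewhiten_ar1(y))
    assert -0.15 < r1_resid < 0.15


# -- Mann-Kendall -----------------------------------------------------------

def test_mk_monotone_series():
    r = mk_statistic([1, 2, 3, 4, 5])
    assert r.S == 10
    assert r.var_S == pytest.approx(250 / 15)
    assert r.Z == pytest.approx(9 / np.sqrt(250 / 15))
    assert r.p == pytest.approx(0.0275, abs=2e-4)


def test_mk_tied_series():
    r = mk_statistic([1, 2, 2, 3])
    assert r.S == 5
    assert r.var_S == pytest.approx(138 / 18)
    assert r.Z == pytest.approx(4 / np.sqrt(138 / 18))


def test_mk_reversal_antisymmetry():
    r = mk_statistic([5, 4, 3, 2, 1])
    assert r.S == -10
    assert r.Z == pytest.approx(-9 / np.sqrt(250 / 15))


def test_mk_all_equal_series():
    r = mk_statistic([2.0, 2.0, 2.0, 2.0])
    assert (r.S, r.Z, r.p) == (0.0, 0.0, 1.0)


def test_mk_z_p_consistency_random_series():
    from scipy.stats import norm
    rng = np.random.default_rng(11)
    for _ in range(50):
        r = mk_statistic(rng.normal(size=rng.integers(4, 20)))
        assert r.p == pytest.approx(2 * norm.sf(abs(r.Z)))
        if abs(r.S) > 1:            # |S| = 1 maps to Z = 0 by the
            assert np.sign(r.S) == np.sign(r.Z)  # continuity correction


@settings(derandomize=True, max_examples=100)
@given(st.lists(st.integers(min_value=0, max_value=5), min_size=4, max_size=12))
def test_mk_antisymmetry_property(seq):
    assert mk_statistic(seq[::-1]).S == -mk_statistic(seq).S


@settings(derandomize=True, max_examples=60)
@given(st.lists(st.floats(min_value=-50, max_value=50), min_size=4,
                max_size=12, unique=True))
def test_mk_monotone_transform_invariance(seq):
    """A rank statistic is unchanged by strictly increasing transforms."""
    from hypothesis import assume

    y = np.asarray(seq)
    z = np.exp(y / 50.0)
    assume(np.unique(z).size == y.size)   # transform must not round to ties
    r0, r1 = mk_statistic(y), mk_statistic(z)
    assert r0.S == r1.S
    assert r0.p == pytest.approx(r1.p)


# -- Sen slope --------------------------------------------------------------

@pytest.mark.parametrize("series, expected", [
    ([3, 5, 7, 9], 2.0),
    ([1, 2, 4], 1.5),
])
def test_sen_known_values(series, expected):
    assert sen_slope(series) == pytest.approx(expected)


def test_sen_affine_equivariance():
    rng = np.random.default_rng(5)
    y = rng.normal(size=15)
    assert sen_slope(-2 * y + 7) == pytest.approx(-2 * sen_slope(y))


def test_sen_rejects_constant_series():
    with pytest.raises(ValueError):
        sen_slope([4.0, 4.0, 4.0])


# -- annual quantile series -------------------------------------------------

def test_annual_median_of_months_1_to_12(small_grid):
    vals = np.tile(np.arange(1.0, 37.0)[:, None, None] % 12 + 1,
                   (1, 8, 8))  # each year cycles 2..12,1 — same multiset
    cube = make_cube(vals, small_grid)
    ann = annual_quantile_series(cube, 0.5)
    np.testing.assert_allclose(ann.values, 6.5)


def test_annual_quantile_constant_cube(small_grid):
    cube = make_cube(np.full((48, 8, 8), 3.25), small_grid)
    for q in (0.1, 0.5, 0.9):
        np.testing.assert_allclose(annual_quantile_series(cube, q).values, 3.25)


def test_annual_quantile_matches_sort_oracle(small_grid):
    rng = np.random.default_rng(9)
    vals = rng.normal(size=(36, 8, 8))
    cube = make_cube(vals, small_grid)
    ann = annual_quantile_series(cube, 0.9)
    oracle = np.quantile(vals[:12, 3, 4], 0.9)  # linear interpolation rule
    assert ann.values[0, 3, 4] == pytest.approx(oracle)


def test_annual_quantile_missing_year_rule(small_grid):
    vals = np.ones((48, 8, 8))
    vals[12:19, 2, 2] = np.nan           # 7 of 12 months missing in year 2
    cube = make_cube(vals, small_grid)
    ann = annual_quantile_series(cube, 0.5)
    assert np.isnan(ann.values[1, 2, 2])
    assert ann.values[0, 2, 2] == 1.0


# -- trend_map --------------------------------------------------------------

def test_trend_map_perfect_ramp_no_noise():
    spec = SyntheticSpec(n_lat=8, n_lon=8, noise_sd=0.0, seasonal_amp=0.01,
                         base_mean=0.3, n_years=10)
    mask = np.zeros((8, 8), bool)
    mask[1:5, 1:5] = True
    region = RegionTrend("R", mask, {"sm": 0.01})
    cube = generate_cube(spec, [region], "sm", seed=0)
    tm = trend_map(cube, 0.5, alpha_cell=1e-3)
    assert (tm["p"].values[mask] < 1e-3).all()
    assert (tm["sen_slope"].values[mask] > 0).all()
    np.testing.assert_allclose(tm["sen_slope"].values[mask], 0.01, atol=1e-9)
    assert (~tm["significant"].values[~mask]).all()


def test_trend_map_type1_rate_near_alpha():
    spec = SyntheticSpec(n_lat=50, n_lon=50, noise_sd=0.02, ar1_phi=0.3,
                         spatial_corr_cells=0.0, base_mean=0.3, n_years=10,
                         seed=21)
    cube = generate_cube(spec, [], "sm")
    tm = trend_map(cube, 0.5, alpha_cell=0.05)
    rate = tm["significant"].values.mean()
    assert 0.03 <= rate <= 0.07


# -- relative trend ---------------------------------------------------------

def test_relative_trend():
    assert relative_trend(0.005, 0.10) == pytest.approx(5.0)
    assert relative_trend(0.0, 0.2) == 0.0
    assert relative_trend(-0.0106 * 0.3, 0.3) == pytest.approx(-1.06)
    with pytest.raises(ValueError):
        relative_trend(0.01, 0.0)


# -- oracle equivalence (exact) --------------------------------------------

def test_mk_and_sen_match_oracles_exactly():
    rng = np.random.default_rng(42)
    for _ in range(200):
        n = int(rng.integers(4, 16))
        y = rng.integers(0, 6, size=n).astype(float)  # heavy ties
        if np.ptp(y) == 0:
            y[0] += 1.0
        S, var = mk_oracle(y)
        r = mk_statistic(y)
        assert r.S == S
        assert r.var_S == pytest.approx(var, rel=1e-12)
        assert sen_slope(y) == pytest.approx(sen_oracle(y), rel=1e-12)
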