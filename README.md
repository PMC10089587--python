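# ecotrend

Detection and clustering of monotonic ecosystem change in gridded
soil-moisture (SM) and vegetation-optical-depth (VOD) records.

Passive L-band microwave satellites deliver monthly maps of surface soil
moisture and of vegetation optical depth — a proxy for vegetation water
content and above-ground biomass that, unlike NDVI, does not saturate over
dense canopies. Decade-scale monotonic trends in the *joint* (SM, VOD)
plane separate kinds of ecosystem change that either variable alone
confounds: wetting with greening (natural reforestation or rain shifts),
joint drying (deforestation, wildfire), or soil drying under greening
(artificial reforestation drawing down soil water). `ecotrend` is for
researchers who want that analysis chain — robust per-cell trend testing,
honest multiple-testing control over a spatially correlated grid, and
reproducible cluster summaries — with a fully synthetic, ground-truthed
test bed so every stage can be validated without downloading satellite data.

## Method at its core

Per grid cell and per quantile level q ∈ {0.1, 0.25, 0.5, 0.75, 0.9} of the
annual distribution:

* annual series *y_t* = empirical q-quantile of year *t*'s monthly values;
* AR(1) pre-whitening: *y′_t = y_t − r₁ y_{t−1}* with *r₁* the sample lag-1
  autocorrelation (controls the false-positive inflation from serial
  correlation);
* Mann–Kendall test on *y′*: *S* = Σ_{i<j} sign(y′_j − y′_i), tie-corrected
  Var(S), continuity-corrected *Z*, two-sided *p*;
* Sen's slope (median of pairwise slopes) on the un-whitened series.

Field significance uses a cluster-based permutation null: one shared
permutation of the year labels per replicate (preserving each year's
spatial field, hence the spatial correlation), re-running the full chain,
and recording the largest patch of *p* < α cells; observed patches are kept
only if larger than the 0.95 null quantile. Per variable, the quantile-wise
maps are merged into a signed change map; cells are then clustered in the
bivariate (SM, VOD) trend-sign space — with a precipitation-trend split for
(+,+) and a magnitude split for (−,−) — into spatially contiguous labeled
clusters with cos(latitude)-weighted areas, per-cluster trend series,
quantile tables and fractional land-cover change. See `docs/methods.md`
for the full specification of every rule and default.

## Worked example

Run the full chain on the built-in five-region synthetic scenario (48×48
grid of 25-km cells, 10 years of monthly data, AR(1) noise with spatial
correlation, five disjoint regions with injected trends):

```python
from ecotrend import PipelineConfig, run_pipeline

res = run_pipeline(PipelineConfig(seed=1, scenario_seed=1, n_perm=200))
cols = ["label", "category", "sign_sm", "sign_vod", "n_cells", "area_km2",
        "median_rel_slope_sm", "median_rel_slope_vod"]
print(res.clusters.table[cols].round(2).to_string(index=False))
```

```
 label category  sign_sm  sign_vod  n_cells  area_km2  median_rel_slope_sm  median_rel_slope_vod
     1        A        1         1      100  55077.27                 2.34                  2.15
     2        D        1         1      100  56923.46                 1.55                  3.34
     3        B       -1        -1      102  56178.63                -1.93                 -3.51
     4        E       -1        -1      100  56923.46                -4.97                -10.66
     5        C       -1         1      102  56178.63                -8.54                  3.58
```

All five injected regions are recovered with their trend-sign signatures:
A and D jointly wetting/greening (split by the precipitation trend), B and
E jointly drying (E markedly stronger), C drying soil under rising VOD.
`median_rel_slope_*` are cluster-median relative trends in %/yr; areas are
cosine-weighted km². Per-cluster annual series and correlations follow the
same accessors:

```python
c_label = int(res.clusters.table.query("category == 'C'")["label"].iloc[0])
cs = res.cluster_series[c_label]
print(f"cluster C: SM trend {cs['sm'].rel_trend:+.1f} %/yr, "
      f"VOD trend {cs['vod'].rel_trend:+.1f} %/yr, "
      f"R2(SM, VOD) = {cs['r2_sm_vod']:.2f}")
# cluster C: SM trend -8.3 %/yr, VOD trend +3.5 %/yr, R2(SM, VOD) = 1.00
```

The area-mean series smooths cell noise, so the temporal R² between SM and
VOD is essentially 1 on clean synthetic ramps; on real records it measures
how tightly soil and vegetation water content co-evolve.

A command-line interface mirrors the library
(`ecotrend simulate | trend | cluster | run`), e.g.

```sh
ecotrend simulate --out sim/ --seed 1
ecotrend trend --cube sim/sm.nc --alpha 0.05 --field-threshold 0.95 \
    --n-perm 500 --seed 1 --out maps/
ecotrend run --config run.yaml
```

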