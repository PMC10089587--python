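"""Fractional land cover: aggregation, epoch differencing, per-cluster tables.

Categorical land-cover maps (one class per fine pixel, e.g. a 500-m product)
are aggregated to the coarse analysis grid as per-class area fractions.
Differencing two epochs gives a per-class fraction-change field whose
per-cell sum is zero by construction (classes partition each cell), and
multiplying by cosine-weighted cell areas turns changes into km².
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import Grid

__all__ = [
    "DEFAULT_CLASSES",
    "FractionalLandCover",
    "aggregate_fractions",
    "epoch_difference",
    "cluster_landcover_summary",
]

#: the 11 broad plant-functional-type categories of the annual PFT
#: classification scheme used for the land-cover analysis
DEFAULT_CLASSES = (
    "water_bodies",
    "evergreen_needleleaf_forest",
    "evergreen_broadleaf_forest",
    "deciduous_needleleaf_forest",
    "deciduous_broadleaf_forest",
    "grasslands",
    "shrublands",
    "cereal_croplands",
    "broadleaf_croplands",
    "urban_built_up",
    "snow_ice_barren",
)


@dataclass
class FractionalLandCover:
    """Per-class area fractions on the coarse grid for one epoch.

    ``fractions`` has shape (n_class, n_lat, n_lon) and sums to 1 over the
    class axis at every cell.
    """

    grid: Grid
    classes: list[str]
    fractions: np.ndarray
    epoch: int = 0

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        if f.shape != (len(self.classes), *self.grid.shape):
            raise ValueError("fractions shape does not match classes × grid")
        if np.any(f < -1e-9) or np.any(f > 1 + 1e-9):
            raise ValueError("fractions must lie in [0, 1]")
        sums = f.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("per-cell class fractions must sum to 1")
        self.fractions = f

    def fraction_of(self, cls: str) -> np.ndarray:
        return self.fractions[self.classes.index(cls)]


def aggregate_fractions(fine_classes: np.ndarray, factor: int,
                        classes, grid: Grid | None = None,
                        epoch: int = 0) -> FractionalLandCover:
    """Aggregate a fine categorical grid to coarse per-class fractions.

    Each coarse cell covers a ``factor × factor`` block of fine cells; the
    fraction of a class is its share of cells within the block.
    """
    classes = list(classes)
    fine = np.asarray(fine_classes)
    if fine.ndim != 2:
        raise ValueError("fine_classes must be a 2-D categorical grid")
    if fine.shape[0] % factor or fine.shape[1] % factor:
        raise ValueError("fine grid dimensions must be divisible by factor")
    if fine.min() < 0 or fine.max() >= len(classes):
        raise ValueError("unknown class code in fine grid")
    h, w = fine.shape[0] // factor, fine.shape[1] // factor
    blocks = fine.reshape(h, factor, w, factor)
    fracs = np.stack([(blocks == k).mean(axis=(1, 3))
                      for k in range(len(classes))])
    if grid is None:
        grid = Grid.regular(h, w)
    return FractionalLandCover(grid=grid, classes=classes, fractions=fracs,
                               epoch=epoch)


def epoch_difference(a: FractionalLandCover,
                     b: FractionalLandCover) -> np.ndarray:
    """Per-class fraction change Δ = b − a, shape (n_class, n_lat, n_lon).

    The change sums to zero over classes at every cell (area conservation).
    """
    if a.classes != b.classes:
        raise ValueError("epochs use different class lists")
    if a.grid.shape != b.grid.shape:
        raise ValueError("epochs live on different grids")
    if a.epoch >= b.epoch:
        raise ValueError("first epoch must precede the second")
    return b.fractions - a.fractions


def cluster_landcover_summary(delta: np.ndarray, cluster_mask: np.ndarray,
                              grid: Grid, classes) -> pd.Series:
    """Net per-class area change (km²) inside a cluster mask.

    For each class: Σ over cluster cells of Δfraction × cell area.  The column
    sum over classes is ~0 (what one class loses another gains).
    """
    classes = list(classes)
    mask = np.asarray(cluster_mask, dtype=bool)
    grid.same_shape(mask)
    if delta.shape != (len(classes), *grid.shape):
        raise ValueError("delta shape does not match classes × grid")
    area = grid.area_map()
    vals = (delta * (mask * area)[None, :, :]).sum(axis=(1, 2))
    return pd.Series(vals, index=classes, name="net_change_km2")
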