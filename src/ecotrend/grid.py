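"""Regular lat/lon analysis grid with cosine-weighted cell areas.

All maps in this package live on a regular grid of nominally square cells
(``cell_km`` × ``cell_km`` at the equator).  The true east–west extent of a
cell shrinks with ``cos(latitude)``, so per-cell areas are latitude dependent;
every area reported by the package (cluster areas, land-cover change in km²)
uses these weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Grid"]


@dataclass(frozen=True)
class Grid:
    """A regular latitude/longitude grid of nominally ``cell_km``-sized cells.

    Parameters
    ----------
    lat_centers, lon_centers : ndarray
        Strictly monotone cell-center coordinates in degrees.
    cell_km : float
        Nominal (equatorial) cell edge length in kilometres.
    """

    lat_centers: np.ndarray
    lon_centers: np.ndarray
    cell_km: float = 25.0
    cell_area_km2: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        lat = np.asarray(self.lat_centers, dtype=float)
        lon = np.asarray(self.lon_centers, dtype=float)
        for name, c in (("lat_centers", lat), ("lon_centers", lon)):
            d = np.diff(c)
            if c.ndim != 1 or c.size == 0 or not (np.all(d > 0) or np.all(d < 0)):
                raise ValueError(f"{name} must be strictly monotone and 1-D")
        if not self.cell_km > 0:
            raise ValueError("cell_km must be positive")
        object.__setattr__(self, "lat_centers", lat)
        object.__setattr__(self, "lon_centers", lon)
        area = self.cell_km**2 * np.cos(np.deg2rad(lat))
        if np.any(area <= 0):
            raise ValueError("cell areas must be positive (|lat| < 90 required)")
        object.__setattr__(self, "cell_area_km2", area)

    @property
    def n_lat(self) -> int:
        return self.lat_centers.size

    @property
    def n_lon(self) -> int:
        return self.lon_centers.size

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_lat, self.n_lon)

    def area_map(self) -> np.ndarray:
        """Per-cell area in km² as an (n_lat, n_lon) array."""
        return np.repeat(self.cell_area_km2[:, None], self.n_lon, axis=1)

    @classmethod
    def regular(cls, n_lat: int, n_lon: int, cell_km: float = 25.0,
                lat0: float = -30.0, lon0: float = 0.0) -> "Grid":
        """Build a grid of ``n_lat`` × ``n_lon`` cells starting at the
        southern edge ``lat0`` / western edge ``lon0`` (degrees)."""
        step = cell_km / 111.195  # km per degree of latitude (spherical Earth)
        lat = lat0 + step * (np.arange(n_lat) + 0.5)
        lon = lon0 + step * (np.arange(n_lon) + 0.5)
        return cls(lat_centers=lat, lon_centers=lon, cell_km=cell_km)

    def same_shape(self, arr: np.ndarray) -> None:
        if tuple(arr.shape[-2:]) != self.shape:
            raise ValueError(
                f"array shape {arr.shape} does not match grid {self.shape}")
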