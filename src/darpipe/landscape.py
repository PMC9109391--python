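"""Synthetic water-index landscape.

Habitat features use a gridded water index in [-1, 1] (the MNDWI convention:
positive = surface water).  Real applications would supply a satellite-derived
monthly composite; here the grid is a plain in-memory raster with CSV
round-tripping, and a generator produces smooth random landscapes with a
controlled water fraction for simulation and testing.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage


@dataclasses.dataclass
class WaterIndexGrid:
    """Regular grid of water-index values over a projected (metre) extent.

    ``values[i, j]`` covers the cell whose lower-left corner is
    ``(x0 + j*cell_size, y0 + i*cell_size)``; row 0 is the southernmost row.
    """

    x0: float
    y0: float
    cell_size: float
    values: np.ndarray  # (ny, nx), float in [-1, 1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        ny, nx = self.values.shape
        return (self.x0, self.y0,
                self.x0 + nx * self.cell_size, self.y0 + ny * self.cell_size)

    def cell_index(self, x, y) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Row/col of each point plus an in-bounds mask."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x0) / self.cell_size).astype(int)
        row = np.floor((y - self.y0) / self.cell_size).astype(int)
        ny, nx = self.values.shape
        ok = (col >= 0) & (col < nx) & (row >= 0) & (row < ny)
        return row, col, ok

    def sample(self, x, y) -> np.ndarray:
        """Water index at each point; NaN outside the grid extent."""
        row, col, ok = self.cell_index(x, y)
        out = np.full(np.shape(row), np.nan, dtype=float)
        out[ok] = self.values[row[ok], col[ok]]
        return out

    @property
    def water_fraction(self) -> float:
        return float((self.values > 0).mean())

    def cell_center(self, row, col) -> tuple[np.ndarray, np.ndarray]:
        return (self.x0 + (np.asarray(col) + 0.5) * self.cell_size,
                self.y0 + (np.asarray(row) + 0.5) * self.cell_size)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# x0={self.x0} y0={self.y0} cell_size={self.cell_size}\n")
            np.savetxt(fh, self.values, delimiter=",", fmt="%.5f")

    @classmethod
    def from_csv(cls, path) -> "WaterIndexGrid":
        with open(path) as fh:
            header = fh.readline().lstrip("# ").split()
            meta = dict(kv.split("=") for kv in header)
            values = np.loadtxt(fh, delimiter=",", ndmin=2)
        return cls(float(meta["x0"]), float(meta["y0"]),
                   float(meta["cell_size"]), values)


def generate_landscape(
    extent_m: float,
    cell_size: float,
    water_fraction: float,
    rng: np.random.Generator,
    correlation_cells: float = 6.0,
) -> WaterIndexGrid:
    """Generate a smooth random water-index landscape centred on the origin.

    White noise is smoothed with a Gaussian kernel (``correlation_cells``
    cells) to form contiguous wetland patches, rank-transformed to uniform,
    then shifted so that exactly ``water_fraction`` of cells are positive.
    Values span [-1, 1]; magnitude grows away from the land/water boundary.
    """
    if extent_m <= 0 or cell_size <= 0:
        raise ValueError("extent and cell size must be positive")
    if not 0.0 <= water_fraction <= 1.0:
        raise ValueError("water_fraction must be in [0, 1]")
    n = max(int(round(extent_m / cell_size)), 2)
    field = rng.standard_normal((n, n))
    field = ndimage.gaussian_filter(field, sigma=correlation_cells, mode="wrap")
    # rank transform -> uniform (0, 1), ties impossible for continuous field
    ranks = field.ravel().argsort().argsort().reshape(field.shape)
    u = (ranks + 0.5) / field.size
    v = np.empty_like(u)
    land = u <= (1.0 - water_fraction)
    if water_fraction < 1.0:
        v[land] = (u[land] / (1.0 - water_fraction)) - 1.0  # (-1, 0]
    if water_fraction > 0.0:
        v[~land] = (u[~land] - (1.0 - water_fraction)) / water_fraction  # (0, 1]
    # avoid exact zeros so water/land classification (> 0) is unambiguous
    v[land] = np.minimum(v[land], -1e-4)
    half = extent_m / 2.0
    return WaterIndexGrid(-half, -half, cell_size, v)
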