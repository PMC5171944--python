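"""Topographic-complexity indices from a tower-centred elevation quadrat.

Terrain complexity around an eddy-covariance tower favours air drainage and
advection and is therefore screened as a covariate of EC-BM flux
divergence.  Two indices are computed on a square elevation grid (by
default 27 x 27 pixels of 90 m, i.e. a 2,430 x 2,430 m quadrat centred at
the tower):

* elevation variability — the population standard deviation of all pixel
  elevations (the pixels are the full quadrat, not a sample);
* topographical slope — the elevation drop between the highest and lowest
  pixels divided by the distance between their centres, in percent.

The grid is treated as a plane with fixed spacing; no geodesy.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["DemQuadrat", "read_dem", "elevation_variability", "topographic_slope"]

DEFAULT_GRID_SIZE = 27
DEFAULT_CELLSIZE_M = 90.0  # 2,430 m / 27


@dataclass
class DemQuadrat:
    """Square elevation grid in metres, row-major, north-up."""

    elevations: np.ndarray
    cellsize: float = DEFAULT_CELLSIZE_M

    def __post_init__(self) -> None:
        self.elevations = np.asarray(self.elevations, dtype=float)
        if self.elevations.ndim != 2 or self.elevations.shape[0] != self.elevations.shape[1]:
            raise ValueError("elevation grid must be square (n x n)")
        if not np.all(np.isfinite(self.elevations)):
            raise ValueError("elevation grid contains missing/non-finite cells")
        if self.cellsize <= 0:
            raise ValueError("pixel size must be > 0")


def read_dem(path: str | Path, cellsize: float = DEFAULT_CELLSIZE_M) -> DemQuadrat:
    """Read an ESRI ASCII grid or a headerless whitespace-separated matrix.

    ESRI ASCII headers (ncols/nrows/cellsize/nodata_value...) are parsed
    case-insensitively; a headerless file uses `cellsize` as pixel size.
    """
    path = Path(path)
    lines = path.read_text().strip().splitlines()
    header: dict[str, float] = {}
    data_start = 0
    for i, line in enumerate(lines):
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "xllcenter",
            "yllcenter", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
        else:
            data_start = i
            break
    grid = np.loadtxt(lines[data_start:])
    if header.get("cellsize"):
        cellsize = header["cellsize"]
    nodata = header.get("nodata_value")
    if nodata is not None and np.any(grid == nodata):
        raise ValueError("elevation grid contains NODATA cells; no interpolation is performed")
    return DemQuadrat(elevations=grid, cellsize=cellsize)


def elevation_variability(q: DemQuadrat) -> float:
    """Population standard deviation (divisor n) of all pixel elevations, metres."""
    return float(np.std(q.elevations))


def topographic_slope(q: DemQuadrat) -> float:
    """Percent slope between the highest and lowest pixels of the quadrat.

    100 * (z_max - z_min) / d, with d the Euclidean distance between the
    two pixel centres.  Ties for the extremes are broken by first occurrence
    in row-major order; a flat grid returns 0.
    """
    z = q.elevations
    zmin, zmax = float(z.min()), float(z.max())
    if zmax == zmin:
        return 0.0
    imax = np.unravel_index(int(np.argmax(z)), z.shape)
    imin = np.unravel_index(int(np.argmin(z)), z.shape)
    d = q.cellsize * float(np.hypot(imax[0] - imin[0], imax[1] - imin[1]))
    return 100.0 * (zmax - zmin) / d
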