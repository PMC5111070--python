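"""Planar-km rasters with plain-text (ESRI ASCII grid) persistence.

Coordinates are planar kilometres.  Row 0 is the northernmost row, matching
the ASCII-grid convention.  NoData is represented internally as NaN for
float grids and as ``nodata_int`` (-1) for integer class grids.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

NODATA_FLOAT = -9999.0
NODATA_INT = -1


@dataclass
class Raster:
    """A single-band grid in planar km coordinates.

    Parameters
    ----------
    values
        2-D array (nrow, ncol).  Float grids use NaN for NoData, integer
        grids use :data:`NODATA_INT`.
    cell_km
        Cell side length in km (square cells).
    origin
        (x, y) of the lower-left corner of the grid, km.
    """

    values: np.ndarray
    cell_km: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cell_km <= 0:
            raise ValueError("cell_km must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) in km."""
        nrow, ncol = self.values.shape
        x0, y0 = self.origin
        return (x0, y0, x0 + ncol * self.cell_km, y0 + nrow * self.cell_km)

    def xy_to_rowcol(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map point coordinates to (row, col); no bounds check."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        nrow = self.values.shape[0]
        col = np.floor((x - self.origin[0]) / self.cell_km).astype(int)
        row = nrow - 1 - np.floor((y - self.origin[1]) / self.cell_km).astype(int)
        return row, col

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        xmin, ymin, xmax, ymax = self.extent
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= xmin) & (x < xmax) & (y >= ymin) & (y < ymax)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) arrays of cell-centre coordinates, same shape as values."""
        nrow, ncol = self.values.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(ncol) + 0.5) * self.cell_km
        ys = y0 + (nrow - 1 - np.arange(nrow) + 0.5) * self.cell_km
        return np.meshgrid(xs, ys)

    def sample(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Cell values at point coordinates; raises on out-of-extent points."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        inside = self.contains(x, y)
        if not np.all(inside):
            bad = np.flatnonzero(~inside)
            raise ValueError(f"points outside raster extent at indices {bad.tolist()}")
        row, col = self.xy_to_rowcol(x, y)
        return self.values[row, col]


def validate_suitability(raster: Raster) -> None:
    """Raise if any non-NoData value falls outside [0, 1]."""
    v = raster.values
    finite = v[np.isfinite(v)]
    if finite.size and (finite.min() < 0.0 or finite.max() > 1.0):
        raise ValueError(
            f"suitability values outside [0, 1]: min={finite.min():.4g} max={finite.max():.4g}"
        )


@dataclass
class ClassMap:
    """Categorical suitability grid.

    Codes: 0 unsuitable, 1 marginal, 2 medium, 3 high; NoData = -1.
    ``bounds`` records (threshold, medium_lower, high_lower).
    """

    values: np.ndarray
    cell_km: float
    origin: tuple[float, float] = (0.0, 0.0)
    bounds: tuple[float, float, float] = (0.364, 0.5, 0.75)

    UNSUITABLE: int = field(default=0, init=False, repr=False)
    MARGINAL: int = field(default=1, init=False, repr=False)
    MEDIUM: int = field(default=2, init=False, repr=False)
    HIGH: int = field(default=3, init=False, repr=False)

    def as_raster(self) -> Raster:
        return Raster(self.values, self.cell_km, self.origin)

    def class_areas_km2(self) -> dict[str, float]:
        cell_area = self.cell_km**2
        names = ["unsuitable", "marginal", "medium", "high"]
        return {
            name: float(np.count_nonzero(self.values == code) * cell_area)
            for code, name in enumerate(names)
        }

    def suitable_mask(self) -> np.ndarray:
        return self.values >= 1

    def good_mask(self) -> np.ndarray:
        """Medium + high condition cells."""
        return self.values >= 2


def write_ascii_grid(raster: Raster, path: str | Path, fmt: str = "%.6g") -> None:
    v = raster.values
    if np.issubdtype(v.dtype, np.floating):
        out = np.where(np.isfinite(v), v, NODATA_FLOAT)
        nodata = NODATA_FLOAT
    else:
        out = v
        nodata = NODATA_INT
        fmt = "%d"
    nrow, ncol = v.shape
    header = (
        f"ncols {ncol}\n"
        f"nrows {nrow}\n"
        f"xllcorner {raster.origin[0]}\n"
        f"yllcorner {raster.origin[1]}\n"
        f"cellsize {raster.cell_km}\n"
        f"NODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt=fmt)


def read_ascii_grid(path: str | Path, dtype: str = "float") -> Raster:
    meta: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            meta[key.lower()] = float(val)
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)
    nodata = meta.get("nodata_value", NODATA_FLOAT)
    if dtype == "float":
        data = data.astype(float)
        data[data == nodata] = np.nan
    else:
        data = data.astype(int)
    return Raster(data, cell_km=meta["cellsize"], origin=(meta["xllcorner"], meta["yllcorner"]))
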