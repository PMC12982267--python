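"""Aligned raster grids on a projected planar CRS in metres.

:class:`RasterGrid` is the common spatial container for every stage of the
pipeline: land cover, predictors, suitability, resistance and current maps
all live on one of these. Rows run north to south (row 0 is the top edge),
columns west to east, matching the on-disk ESRI ASCII grid layout. Nodata
is represented as NaN in float grids.

All grids in one analysis must share a single projected CRS with metre
units; the package performs no reprojection and the file format carries no
CRS metadata, so alignment is checked purely on geometry (origin, cell
size, shape).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RasterGrid", "read_raster", "write_raster"]


@dataclass
class RasterGrid:
    """A 2-D grid of cell values with square cells.

    Parameters
    ----------
    data
        2-D float array, NaN marking nodata.
    cell_size
        Cell edge length in metres.
    origin
        (x, y) of the lower-left corner of the grid (metres).
    """

    data: np.ndarray
    cell_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("RasterGrid data must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    # -- geometry -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    @property
    def n_cols(self) -> int:
        return self.data.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid footprint."""
        x0, y0 = self.origin
        return (
            x0,
            y0,
            x0 + self.n_cols * self.cell_size,
            y0 + self.n_rows * self.cell_size,
        )

    @property
    def valid(self) -> np.ndarray:
        """Boolean mask of non-nodata cells."""
        return np.isfinite(self.data)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) arrays of cell-centre coordinates, same shape as data."""
        x0, y0 = self.origin
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = x0 + (cols + 0.5) * self.cell_size
        y = y0 + (self.n_rows - rows - 0.5) * self.cell_size
        return np.meshgrid(x, y)

    def index_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) of the cell containing each point; -1 if outside."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        x0, y0 = self.origin
        col = np.floor((x - x0) / self.cell_size).astype(int)
        row = self.n_rows - 1 - np.floor((y - y0) / self.cell_size).astype(int)
        inside = (col >= 0) & (col < self.n_cols) & (row >= 0) & (row < self.n_rows)
        col = np.where(inside, col, -1)
        row = np.where(inside, row, -1)
        return row, col

    def value_at(self, x, y) -> np.ndarray:
        """Cell value at each point, NaN outside the grid."""
        row, col = self.index_of(x, y)
        out = np.full(np.shape(row), np.nan)
        inside = row >= 0
        out[inside] = self.data[row[inside], col[inside]]
        return out

    def aligned_with(self, other: "RasterGrid", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and abs(self.cell_size - other.cell_size) <= tol
            and abs(self.origin[0] - other.origin[0]) <= tol
            and abs(self.origin[1] - other.origin[1]) <= tol
        )

    def like(self, data: np.ndarray) -> "RasterGrid":
        """A new grid with the same geometry and the given data."""
        data = np.asarray(data, dtype=float)
        if data.shape != self.shape:
            raise ValueError("data shape does not match grid")
        return RasterGrid(data, self.cell_size, self.origin)

    def copy(self) -> "RasterGrid":
        return RasterGrid(self.data.copy(), self.cell_size, self.origin)


def check_aligned(*grids: RasterGrid) -> None:
    ref = grids[0]
    for g in grids[1:]:
        if not ref.aligned_with(g):
            raise ValueError("raster grids are not aligned (origin/cell size/shape differ)")


# -- ESRI ASCII grid I/O ----------------------------------------------------

_NODATA = -9999.0


def write_raster(grid: RasterGrid, path) -> None:
    """Write a grid as an ESRI ASCII grid (.asc), a plain-text raster format.

    Values are written at full double precision so a write/read round trip
    is bit-identical.
    """
    data = np.where(np.isfinite(grid.data), grid.data, _NODATA)
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {grid.origin[0]!r}\n"
        f"yllcorner {grid.origin[1]!r}\n"
        f"cellsize {grid.cell_size!r}\n"
        f"NODATA_value {_NODATA!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, data, fmt="%.17g")


def read_raster(path) -> RasterGrid:
    """Read an ESRI ASCII grid written by :func:`write_raster` (or any .asc)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            parts = line.split()
            if len(parts) != 2 or not _is_number(parts[1]):
                fh.seek(pos)
                break
            header[parts[0].lower()] = float(parts[1])
            pos = fh.tell()
        data = np.loadtxt(fh, ndmin=2)
    for key in ("ncols", "nrows", "cellsize"):
        if key not in header:
            raise ValueError(f"not an ESRI ASCII grid: missing {key} in {path}")
    if data.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"grid shape mismatch in {path}")
    nodata = header.get("nodata_value", _NODATA)
    data = np.where(data == nodata, np.nan, data)
    return RasterGrid(
        data,
        cell_size=header["cellsize"],
        origin=(header.get("xllcorner", 0.0), header.get("yllcorner", 0.0)),
    )


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False
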