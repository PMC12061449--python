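"""Regular-grid raster container and plain-text (ESRI ASCII grid) I/O.

The whole pipeline operates on north-up, row-major, square-cell grids:
row 0 is the northernmost row, cell values are sampled at cell centres,
and a point is attributed to the cell that contains it.  Missing cells
are carried as NaN in memory and serialized with an explicit nodata
sentinel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["RasterGrid", "read_ascii_grid", "write_ascii_grid", "block_aggregate"]


@dataclass
class RasterGrid:
    """A single-band raster on a regular planar grid.

    Parameters
    ----------
    values
        2-D float array; NaN marks nodata cells.
    cell_size
        Edge length of a (square) cell in metres.
    origin
        (x, y) of the *outer* corner of cell (0, 0), i.e. the north-west
        corner of the grid.
    nodata
        Sentinel written to disk in place of NaN.
    """

    values: np.ndarray
    cell_size: float = 50.0
    origin: tuple[float, float] = (0.0, 0.0)
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    # -- geometry ----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def cell_area(self) -> float:
        return self.cell_size ** 2

    def same_geometry(self, other: "RasterGrid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size, other.cell_size)
            and np.allclose(self.origin, other.origin)
        )

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        x0, y0 = self.origin
        x = x0 + (col + 0.5) * self.cell_size
        y = y0 - (row + 0.5) * self.cell_size
        return x, y

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """x and y coordinate arrays of every cell centre (each shape of grid)."""
        rows, cols = np.mgrid[0 : self.nrows, 0 : self.ncols]
        x0, y0 = self.origin
        return x0 + (cols + 0.5) * self.cell_size, y0 - (rows + 0.5) * self.cell_size

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """Row/col of the cell containing point (x, y)."""
        x0, y0 = self.origin
        col = int(np.floor((x - x0) / self.cell_size))
        row = int(np.floor((y0 - y) / self.cell_size))
        if not (0 <= row < self.nrows and 0 <= col < self.ncols):
            raise IndexError(f"point ({x}, {y}) outside raster extent")
        return row, col

    def sample(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Value of the containing cell for each point; outside points get NaN."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        x0, y0 = self.origin
        col = np.floor((x - x0) / self.cell_size).astype(int)
        row = np.floor((y0 - y) / self.cell_size).astype(int)
        inside = (row >= 0) & (row < self.nrows) & (col >= 0) & (col < self.ncols)
        out = np.full(x.shape, np.nan)
        out[inside] = self.values[row[inside], col[inside]]
        return out

    # -- data --------------------------------------------------------------
    @property
    def valid_mask(self) -> np.ndarray:
        return np.isfinite(self.values)

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    def with_values(self, values: np.ndarray) -> "RasterGrid":
        """Same geometry, new values."""
        return replace(self, values=np.asarray(values, dtype=float))


def write_ascii_grid(grid: RasterGrid, path: str | Path) -> None:
    """Write as ESRI ASCII grid (.asc); NaN cells become the nodata sentinel."""
    path = Path(path)
    vals = np.where(np.isfinite(grid.values), grid.values, grid.nodata)
    x0, y_top = grid.origin
    yll = y_top - grid.nrows * grid.cell_size
    header = (
        f"ncols {grid.ncols}\n"
        f"nrows {grid.nrows}\n"
        f"xllcorner {x0:.6f}\n"
        f"yllcorner {yll:.6f}\n"
        f"cellsize {grid.cell_size:.6f}\n"
        f"NODATA_value {grid.nodata:.6f}\n"
    )
    with path.open("w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.8g")


def read_ascii_grid(path: str | Path) -> RasterGrid:
    """Read an ESRI ASCII grid; nodata cells become NaN."""
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    values = values.reshape(nrows, ncols)
    nodata = header.get("nodata_value", -9999.0)
    values = np.where(values == nodata, np.nan, values)
    cell = header["cellsize"]
    origin = (header["xllcorner"], header["yllcorner"] + nrows * cell)
    return RasterGrid(values, cell_size=cell, origin=origin, nodata=nodata)


def block_aggregate(grid: RasterGrid, factor: int, how: str = "mean") -> RasterGrid:
    """Aggregate ``factor``×``factor`` fine cells into one coarse cell.

    Partial edge blocks are aggregated over the cells they do contain.
    NaN cells are ignored; an all-NaN block is NaN.
    """
    if factor < 1:
        raise ValueError("aggregation factor must be >= 1")
    nr = -(-grid.nrows // factor)
    nc = -(-grid.ncols // factor)
    padded = np.full((nr * factor, nc * factor), np.nan)
    padded[: grid.nrows, : grid.ncols] = grid.values
    blocks = padded.reshape(nr, factor, nc, factor).transpose(0, 2, 1, 3)
    blocks = blocks.reshape(nr, nc, factor * factor)
    with np.errstate(invalid="ignore"):
        if how == "mean":
            agg = np.nanmean(blocks, axis=2)
        elif how == "max":
            agg = np.nanmax(np.where(np.isnan(blocks), -np.inf, blocks), axis=2)
            agg = np.where(np.isinf(agg), np.nan, agg)
        elif how == "sum":
            agg = np.nansum(blocks, axis=2)
            agg = np.where(np.all(np.isnan(blocks), axis=2), np.nan, agg)
        else:
            raise ValueError(f"unknown aggregation: {how!r}")
    return RasterGrid(
        agg,
        cell_size=grid.cell_size * factor,
        origin=grid.origin,
        nodata=grid.nodata,
    )
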