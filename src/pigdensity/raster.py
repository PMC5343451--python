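"""Planar raster grids and ESRI ASCII grid (.asc) I/O.

All covariate and density surfaces in this package live on regular,
north-up planar grids measured in kilometres.  The grid is the unit of
exchange between the synthetic-landscape generator, the moving-window
covariate engine, and the prediction mapper.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["RasterGrid", "read_ascii_grid", "write_ascii_grid", "GeometryError"]

DEFAULT_NODATA = -9999.0


class GeometryError(ValueError):
    """Raised when raster geometries do not line up."""


@dataclass
class RasterGrid:
    """A regular planar grid of real values.

    Parameters
    ----------
    values : ndarray, shape (nrows, ncols)
        Cell values, row 0 at the *north* edge.  NaN marks NODATA.
    xllcorner, yllcorner : float
        Coordinates of the lower-left corner of the lower-left cell, km.
    cell_size : float
        Cell edge length, km.
    """

    values: np.ndarray
    xllcorner: float = 0.0
    yllcorner: float = 0.0
    cell_size: float = 1.0
    nodata: float = field(default=DEFAULT_NODATA, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise GeometryError("raster values must be 2-D")
        if self.cell_size <= 0:
            raise GeometryError("cell_size must be positive")

    # -- geometry -----------------------------------------------------
    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def same_geometry(self, other: "RasterGrid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.xllcorner, other.xllcorner)
            and np.isclose(self.yllcorner, other.yllcorner)
            and np.isclose(self.cell_size, other.cell_size)
        )

    def require_same_geometry(self, other: "RasterGrid") -> None:
        if not self.same_geometry(other):
            raise GeometryError("raster geometries differ")

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) coordinate arrays of cell centers, shape (nrows, ncols)."""
        xs = self.xllcorner + (np.arange(self.ncols) + 0.5) * self.cell_size
        ys = self.yllcorner + (np.arange(self.nrows)[::-1] + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """Row/col of the cell containing the point (x, y); raises if outside."""
        col = int(np.floor((x - self.xllcorner) / self.cell_size))
        row_from_bottom = int(np.floor((y - self.yllcorner) / self.cell_size))
        row = self.nrows - 1 - row_from_bottom
        if not (0 <= row < self.nrows and 0 <= col < self.ncols):
            raise GeometryError(f"point ({x}, {y}) outside raster extent")
        return row, col

    def value_at(self, x: float, y: float) -> float:
        r, c = self.index_of(x, y)
        return float(self.values[r, c])

    def copy_with(self, values: np.ndarray) -> "RasterGrid":
        if values.shape != self.shape:
            raise GeometryError("replacement values have wrong shape")
        return RasterGrid(
            values=np.asarray(values, dtype=float),
            xllcorner=self.xllcorner,
            yllcorner=self.yllcorner,
            cell_size=self.cell_size,
            nodata=self.nodata,
        )


def write_ascii_grid(grid: RasterGrid, path: str | Path) -> None:
    """Write a grid as an ESRI ASCII raster (.asc), NaN as NODATA."""
    path = Path(path)
    vals = np.where(np.isnan(grid.values), grid.nodata, grid.values)
    with path.open("w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {grid.xllcorner:.6f}\n")
        fh.write(f"yllcorner {grid.yllcorner:.6f}\n")
        fh.write(f"cellsize {grid.cell_size:.6f}\n")
        fh.write(f"NODATA_value {grid.nodata:.6f}\n")
        for row in vals:
            fh.write(" ".join(f"{v:.8g}" for v in row) + "\n")


def read_ascii_grid(path: str | Path) -> RasterGrid:
    """Read an ESRI ASCII raster (.asc); NODATA cells become NaN."""
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines):
        parts = lines[i].split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner",
            "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            i += 1
        else:
            break
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"missing ASCII grid header field: {key}")
    body = " ".join(lines[i:])
    vals = np.array(body.split(), dtype=float)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if vals.size != nrows * ncols:
        raise ValueError(
            f"expected {nrows * ncols} values, found {vals.size} in {path}"
        )
    vals = vals.reshape(nrows, ncols)
    nodata = header.get("nodata_value", DEFAULT_NODATA)
    vals = np.where(vals == nodata, np.nan, vals)
    return RasterGrid(
        values=vals,
        xllcorner=header["xllcorner"],
        yllcorner=header["yllcorner"],
        cell_size=header["cellsize"],
        nodata=nodata,
    )
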