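"""Regular bathymetry rasters and ESRI ASCII grid I/O.

Depths are stored in metres, positive down, with ``numpy.nan`` marking nodata
cells in memory.  Row 0 is the northernmost row (ESRI ASCII convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["BathyGrid", "read_ascii_grid", "write_ascii_grid"]


@dataclass
class BathyGrid:
    """A rectangular depth raster.

    Parameters
    ----------
    depths
        2-D float array of water depths (m, positive down); nan = nodata.
    cell_size
        Cell edge length in metres (> 0).
    origin_x, origin_y
        Coordinates (m) of the lower-left corner of the lower-left cell.
    nodata
        Value used for nodata cells on disk.
    """

    depths: np.ndarray
    cell_size: float
    origin_x: float = 0.0
    origin_y: float = 0.0
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=float)
        if self.depths.ndim != 2:
            raise ValueError("depths must be a 2-D array")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.depths.shape

    @property
    def elevation(self) -> np.ndarray:
        """Elevation (m, positive up): the negated depth."""
        return -self.depths

    def x_coords(self) -> np.ndarray:
        """Cell-centre x coordinates per column (west to east)."""
        ncols = self.depths.shape[1]
        return self.origin_x + (np.arange(ncols) + 0.5) * self.cell_size

    def y_coords(self) -> np.ndarray:
        """Cell-centre y coordinates per row (row 0 = northernmost)."""
        nrows = self.depths.shape[0]
        return self.origin_y + (nrows - 1 - np.arange(nrows) + 0.5) * self.cell_size

    def cell_at(self, x: float | np.ndarray, y: float | np.ndarray):
        """(row, col) indices of the cells containing points (x, y)."""
        nrows = self.depths.shape[0]
        col = np.floor((np.asarray(x) - self.origin_x) / self.cell_size).astype(int)
        row_from_bottom = np.floor((np.asarray(y) - self.origin_y) / self.cell_size).astype(int)
        row = nrows - 1 - row_from_bottom
        return row, col

    def validate_range(self, depth_range: tuple[float, float]) -> None:
        lo, hi = depth_range
        vals = self.depths[np.isfinite(self.depths)]
        if vals.size and (vals.min() < lo or vals.max() > hi):
            raise ValueError(
                f"depths [{vals.min():.1f}, {vals.max():.1f}] outside allowed range {depth_range}"
            )


def read_ascii_grid(path) -> BathyGrid:
    """Read an ESRI ASCII grid (.asc) of depths."""
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    n_header = 0
    for line in lines:
        parts = line.split()
        if len(parts) == 2 and parts[0].lower() in {
            "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
        }:
            header[parts[0].lower()] = float(parts[1])
            n_header += 1
        else:
            break
    data = np.loadtxt(lines[n_header:], dtype=float)
    data = np.atleast_2d(data)
    nodata = header.get("nodata_value", -9999.0)
    data[data == nodata] = np.nan
    if data.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError("ASCII grid data shape does not match header")
    return BathyGrid(
        depths=data,
        cell_size=header["cellsize"],
        origin_x=header.get("xllcorner", 0.0),
        origin_y=header.get("yllcorner", 0.0),
        nodata=nodata,
    )


def write_ascii_grid(grid: BathyGrid, path, values: np.ndarray | None = None) -> None:
    """Write a grid (its depths, or an aligned ``values`` array) as .asc."""
    data = grid.depths if values is None else np.asarray(values, dtype=float)
    if data.shape != grid.depths.shape:
        raise ValueError("values shape does not match grid")
    nrows, ncols = data.shape
    out = np.where(np.isfinite(data), data, grid.nodata)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {grid.origin_x:.6f}\n")
        fh.write(f"yllcorner {grid.origin_y:.6f}\n")
        fh.write(f"cellsize {grid.cell_size:.6f}\n")
        fh.write(f"NODATA_value {grid.nodata}\n")
        np.savetxt(fh, out, fmt="%.4f")
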