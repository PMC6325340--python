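"""Benthic terrain derivatives and landscape classification.

Computes a broad bathymetric position index (BPI) and a terrain ruggedness
index (TRI) from a depth raster, and classifies cells into the three abyssal
landscape types (flat / ridge / trough) using fixed threshold boxes.

Sign conventions: both indices are computed on *elevation* (negative depth),
so positive BPI marks cells shallower than their annulus mean, i.e. local
highs.  TRI is the mean absolute elevation difference between a cell and its
circular neighbourhood, hence >= 0 and invariant to adding a constant depth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve

from . import reference
from .grids import BathyGrid

__all__ = [
    "CLASS_LABELS",
    "TerrainMaps",
    "compute_bpi",
    "compute_tri",
    "classify_landscape",
    "compute_terrain",
]

#: integer codes of the landscape classes in the `classes` raster
CLASS_LABELS = {0: "unclassified", 1: "flat", 2: "ridge", 3: "trough"}
CLASS_CODES = {v: k for k, v in CLASS_LABELS.items()}


def _disk_offsets(radius_m: float, cell_size: float) -> np.ndarray:
    """Boolean kernel of cell-centre offsets with distance <= radius."""
    r_cells = int(np.floor(radius_m / cell_size))
    di = np.arange(-r_cells, r_cells + 1)
    dist = np.hypot(*np.meshgrid(di, di, indexing="ij")) * cell_size
    return dist <= radius_m


def _annulus_kernel(inner_m: float, outer_m: float, cell_size: float) -> np.ndarray:
    """Annulus kernel: inner < distance <= outer (cell-centre distances)."""
    r_cells = int(np.floor(outer_m / cell_size))
    di = np.arange(-r_cells, r_cells + 1)
    dist = np.hypot(*np.meshgrid(di, di, indexing="ij")) * cell_size
    return (dist > inner_m) & (dist <= outer_m)


def _masked_mean_filter(values: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Nodata-aware moving mean: mean of valid cells under the kernel.

    Edge cells use whatever part of the kernel overlaps the grid.
    """
    valid = np.isfinite(values)
    filled = np.where(valid, values, 0.0)
    k = kernel.astype(float)
    total = fftconvolve(filled, k, mode="same")
    count = fftconvolve(valid.astype(float), k, mode="same")
    count = np.round(count)  # fft jitter on the integer counts
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return mean


def compute_bpi(
    grid: BathyGrid,
    inner_radius_m: float = reference.BPI_INNER_RADIUS_M,
    outer_radius_m: float = reference.BPI_OUTER_RADIUS_M,
) -> np.ndarray:
    """Bathymetric position index: elevation minus annulus-mean elevation.

    The annulus spans inner < r <= outer around each cell; near the grid edge
    the available annulus cells are used.  Units: metres.
    """
    if not inner_radius_m < outer_radius_m:
        raise ValueError("inner radius must be smaller than outer radius")
    if inner_radius_m < grid.cell_size or outer_radius_m < grid.cell_size:
        raise ValueError("radii must be at least one cell")
    kernel = _annulus_kernel(inner_radius_m, outer_radius_m, grid.cell_size)
    if not kernel.any():
        raise ValueError("annulus contains no cells at this resolution")
    elev = grid.elevation
    annulus_mean = _masked_mean_filter(elev, kernel)
    return elev - annulus_mean


def compute_tri(grid: BathyGrid, radius_m: float = reference.TRI_RADIUS_M,
                variant: str = "mean_abs") -> np.ndarray:
    """Terrain ruggedness index within a circular neighbourhood.

    ``mean_abs`` (default): mean |z_cell - z_neighbour| over all neighbours
    within ``radius_m`` (centre excluded).  ``rms``: root-mean-square of the
    same differences.  Units: metres; >= 0.
    """
    if radius_m < grid.cell_size:
        raise ValueError("radius must be at least one cell")
    if variant not in {"mean_abs", "rms"}:
        raise ValueError(f"unknown TRI variant {variant!r}")
    kernel = _disk_offsets(radius_m, grid.cell_size)
    centre = tuple(s // 2 for s in kernel.shape)
    kernel = kernel.copy()
    kernel[centre] = False
    if not kernel.any():
        raise ValueError("neighbourhood contains no cells at this resolution")

    elev = grid.elevation
    valid = np.isfinite(elev)
    acc = np.zeros_like(elev)
    count = np.zeros_like(elev)
    nrows, ncols = elev.shape
    offs = np.argwhere(kernel) - centre
    for di, dj in offs:
        # overlap of the grid with itself shifted by (di, dj)
        src_i = slice(max(0, di), min(nrows, nrows + di))
        dst_i = slice(max(0, -di), min(nrows, nrows - di))
        src_j = slice(max(0, dj), min(ncols, ncols + dj))
        dst_j = slice(max(0, -dj), min(ncols, ncols - dj))
        diff = elev[dst_i, dst_j] - elev[src_i, src_j]
        ok = valid[dst_i, dst_j] & valid[src_i, src_j]
        contrib = np.where(ok, np.abs(diff) if variant == "mean_abs" else diff**2, 0.0)
        acc[dst_i, dst_j] += contrib
        count[dst_i, dst_j] += ok
    with np.errstate(invalid="ignore", divide="ignore"):
        tri = np.where(count > 0, acc / np.maximum(count, 1), np.nan)
    if variant == "rms":
        tri = np.sqrt(tri)
    tri[~valid] = np.nan
    return tri


def classify_landscape(bpi: np.ndarray, tri: np.ndarray,
                       boxes: dict | None = None) -> np.ndarray:
    """Classify cells into flat / ridge / trough by threshold boxes.

    Membership is closed-interval; cells outside every box (or nodata) are
    unclassified.  Boundary ties at |BPI| = 50 go to flat (flat is tested
    first), which makes the labelling deterministic.
    """
    bpi = np.asarray(bpi, dtype=float)
    tri = np.asarray(tri, dtype=float)
    if bpi.shape != tri.shape:
        raise ValueError("bpi and tri shapes differ")
    boxes = dict(reference.CLASS_BOXES) if boxes is None else boxes
    classes = np.zeros(bpi.shape, dtype=np.int8)
    ok = np.isfinite(bpi) & np.isfinite(tri)
    for name in ("flat", "ridge", "trough"):   # flat first: owns the +-50 boundary
        (blo, bhi), (tlo, thi) = boxes[name]
        inside = ok & (classes == 0) & (bpi >= blo) & (bpi <= bhi) & (tri >= tlo) & (tri <= thi)
        classes[inside] = CLASS_CODES[name]
    return classes


@dataclass
class TerrainMaps:
    """BPI, TRI and landscape-class rasters aligned with their source grid."""

    grid: BathyGrid
    bpi: np.ndarray
    tri: np.ndarray
    classes: np.ndarray

    def class_fraction(self, name: str) -> float:
        ok = np.isfinite(self.bpi)
        return float(np.mean(self.classes[ok] == CLASS_CODES[name]))

    def find_stratum_rectangle(self, name: str, width_m: float, height_m: float):
        """Axis-aligned rectangle of the given size maximizing the fraction of
        cells in class ``name``; returns (x0, y0, x1, y1) in grid coordinates.

        Used to place the per-landscape survey areas automatically.
        """
        cs = self.grid.cell_size
        w = max(1, int(round(width_m / cs)))
        h = max(1, int(round(height_m / cs)))
        nrows, ncols = self.classes.shape
        if w > ncols or h > nrows:
            raise ValueError("rectangle larger than grid")
        target = (self.classes == CLASS_CODES[name]).astype(float)
        # moving-window sum via cumulative sums
        c = np.cumsum(np.cumsum(np.pad(target, ((1, 0), (1, 0))), axis=0), axis=1)
        win = c[h:, w:] - c[:-h, w:] - c[h:, :-w] + c[:-h, :-w]
        r, col = np.unravel_index(np.argmax(win), win.shape)
        # convert (row, col) of the window's top-left cell to map coordinates
        x0 = self.grid.origin_x + col * cs
        y1 = self.grid.origin_y + (nrows - r) * cs
        y0 = y1 - h * cs
        x1 = x0 + w * cs
        return (x0, y0, x1, y1)


def compute_terrain(
    grid: BathyGrid,
    inner_radius_m: float = reference.BPI_INNER_RADIUS_M,
    outer_radius_m: float = reference.BPI_OUTER_RADIUS_M,
    tri_radius_m: float = reference.TRI_RADIUS_M,
    standardize_bpi: bool = False,
) -> TerrainMaps:
    """Full terrain stack: BPI, TRI and the classified landscape raster.

    ``standardize_bpi`` rescales BPI to z-scores x 100 (a common GIS
    convention) before thresholding; raw metres is the default.
    """
    bpi = compute_bpi(grid, inner_radius_m, outer_radius_m)
    if standardize_bpi:
        vals = bpi[np.isfinite(bpi)]
        sd = vals.std()
        if sd > 0:
            bpi = (bpi - vals.mean()) / sd * 100.0
    tri = compute_tri(grid, tri_radius_m)
    classes = classify_landscape(bpi, tri)
    return TerrainMaps(grid=grid, bpi=bpi, tri=tri, classes=classes)
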