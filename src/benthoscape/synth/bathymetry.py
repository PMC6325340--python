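"""Horst-and-graben bathymetry generator."""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from ..grids import BathyGrid
from .specs import BathymetrySpec, as_rng

__all__ = ["generate_bathymetry"]


def _smooth_unit_noise(shape, sigma_cells: float, rng: np.random.Generator) -> np.ndarray:
    """Correlated Gaussian noise standardized to zero mean, unit variance."""
    white = rng.standard_normal(shape)
    smooth = gaussian_filter(white, sigma=sigma_cells, mode="wrap")
    sd = smooth.std()
    if sd == 0:
        return np.zeros(shape)
    return (smooth - smooth.mean()) / sd


def generate_bathymetry(spec: BathymetrySpec, seed) -> BathyGrid:
    """Generate a depth raster of quasi-periodic north-south ridges and troughs.

    The deterministic part is a cosine in easting with period
    ``ridge_spacing_m`` (crests are shallow); quasi-periodicity comes from a
    smooth along-northing phase drift, and small-scale relief from smooth
    correlated noise.  Deterministic under a fixed seed.
    """
    rng = as_rng(seed)
    nrows, ncols = spec.nrows, spec.ncols
    x = (np.arange(ncols) + 0.5) * spec.cell_size_m + spec.origin_x

    if spec.phase_jitter_rad > 0:
        drift = gaussian_filter1d(rng.standard_normal(nrows),
                                  sigma=max(spec.noise_corr_m / spec.cell_size_m, 1.0),
                                  mode="wrap")
        sd = drift.std()
        phase = (drift / sd if sd > 0 else drift) * spec.phase_jitter_rad
    else:
        phase = np.zeros(nrows)

    wave = np.cos(2 * np.pi * x[None, :] / spec.ridge_spacing_m + phase[:, None])
    depths = spec.base_depth_m - spec.relief_amplitude_m * wave

    if spec.noise_sd_m > 0:
        sigma_cells = max(spec.noise_corr_m / spec.cell_size_m, 0.5)
        depths = depths + spec.noise_sd_m * _smooth_unit_noise((nrows, ncols), sigma_cells, rng)

    grid = BathyGrid(depths=depths, cell_size=spec.cell_size_m,
                     origin_x=spec.origin_x, origin_y=spec.origin_y)
    grid.validate_range(spec.depth_range_m)
    return grid
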