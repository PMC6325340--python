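"""Patchy nodule-cover fields and per-image nodule samplers.

Cover is modelled as ``expit(mu + sd * Z(x, y))`` with Z a unit-variance
Gaussian random field; ``mu`` is solved numerically so that the *marginal*
mean cover equals the requested per-area mean.  Per-image nodule counts are
Poisson with expectation (local cover x footprint) / (mean nodule area), and
individual areas are lognormal.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import lognorm

from .specs import NoduleFieldSpec, as_rng

__all__ = ["NoduleField", "solve_logit_mean"]

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(81)


def _expected_expit(mu: float, sd: float) -> float:
    """E[expit(mu + sd Z)], Z ~ N(0,1), by Gauss-Hermite quadrature."""
    z = np.sqrt(2.0) * _GH_NODES
    return float(np.sum(_GH_WEIGHTS * expit(mu + sd * z)) / np.sqrt(np.pi))


def solve_logit_mean(target_fraction: float, sd: float) -> float:
    """Solve mu so that E[expit(mu + sd Z)] equals ``target_fraction``."""
    if not 0 < target_fraction < 1:
        raise ValueError("target fraction must lie strictly in (0, 1)")
    return brentq(lambda m: _expected_expit(m, sd) - target_fraction, -40.0, 40.0)


class NoduleField:
    """Continuous nodule-cover function plus nodule-size sampler for one area.

    Parameters
    ----------
    spec
        Field and size-distribution parameters.
    bounds
        (x0, y0, x1, y1) rectangle (m) the field must span.
    seed
        Seed or Generator for the field realization.
    """

    def __init__(self, spec: NoduleFieldSpec, bounds, seed):
        self.spec = spec
        self.bounds = tuple(float(b) for b in bounds)
        rng = as_rng(seed)
        x0, y0, x1, y1 = self.bounds
        if x1 <= x0 or y1 <= y0:
            raise ValueError("degenerate area rectangle")
        self.mean_fraction = spec.mean_cover_pct / 100.0
        res = spec.field_resolution_m
        nx = max(int(np.ceil((x1 - x0) / res)) + 1, 2)
        ny = max(int(np.ceil((y1 - y0) / res)) + 1, 2)
        self._xs = np.linspace(x0, x1, nx)
        self._ys = np.linspace(y0, y1, ny)

        if self.mean_fraction <= 0:
            self._mu = -np.inf
            self._interp = None
            return
        white = rng.standard_normal((ny, nx))
        # smoothing white noise with a Gaussian of sd ell/2 gives spatial
        # correlation rho(h) = exp(-h^2 / ell^2), i.e. e-folding at ell
        z = gaussian_filter(white, sigma=spec.corr_length_m / (2 * res), mode="wrap")
        z = (z - z.mean()) / z.std()
        self._mu = solve_logit_mean(self.mean_fraction, spec.logit_sd)
        self._interp = RegularGridInterpolator((self._ys, self._xs), z,
                                               bounds_error=False, fill_value=None)

    @property
    def mean_nodule_area_cm2(self) -> float:
        s = self.spec
        return float(np.exp(s.size_log_mu + 0.5 * s.size_log_sigma**2))

    def fraction_below(self, area_cm2: float) -> float:
        """P(nodule area < ``area_cm2``) under the size distribution."""
        s = self.spec
        return float(lognorm.cdf(area_cm2, s.size_log_sigma, scale=np.exp(s.size_log_mu)))

    def cover_at(self, x, y) -> np.ndarray:
        """Cover fraction at points (x, y), bilinear in the latent field."""
        x = np.clip(np.asarray(x, dtype=float), self._xs[0], self._xs[-1])
        y = np.clip(np.asarray(y, dtype=float), self._ys[0], self._ys[-1])
        if self._interp is None:
            return np.zeros(np.broadcast(x, y).shape)
        z = self._interp(np.stack([y, x], axis=-1))
        return expit(self._mu + self.spec.logit_sd * z)

    def marginal_cover(self, n: int, seed) -> np.ndarray:
        """n i.i.d. draws from the marginal cover distribution (no spatial field)."""
        if self.mean_fraction <= 0:
            return np.zeros(n)
        rng = as_rng(seed)
        return expit(self._mu + self.spec.logit_sd * rng.standard_normal(n))

    def sample_image_nodules(self, footprint_m2: float, cover: float, seed) -> np.ndarray:
        """Per-nodule areas (cm^2) for one image with the given local cover."""
        if cover <= 0 or footprint_m2 <= 0:
            return np.empty(0)
        rng = as_rng(seed)
        expected_area_cm2 = cover * footprint_m2 * 1e4
        n = rng.poisson(expected_area_cm2 / self.mean_nodule_area_cm2)
        s = self.spec
        return np.exp(rng.normal(s.size_log_mu, s.size_log_sigma, size=n))
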