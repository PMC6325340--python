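"""Sampling-unit-size adequacy evaluation.

Images pooled within a study area are resampled (with or without
replacement) into synthetic sampling units of increasing image count; at
each size the centre statistic (mean, or median for biomass), the precision
(CV), percentile confidence intervals, and the mean seabed area and
individual count represented are recorded.  Autosimilarity — the Bray-Curtis
similarity between two disjoint random image groups — measures precision of
assemblage description.  A stabilization detector locates the minimum
adequate unit size for each parameter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ImagePool",
    "PARAMETERS",
    "CurveResult",
    "StabilizationReport",
    "size_grid",
    "resample_parameter",
    "autosimilarity",
    "detect_stabilization",
]


@dataclass
class ImagePool:
    """Per-image data of one study area, pooled across sampling units.

    ``counts`` is (n_images x n_species); ``footprints`` m^2 per image;
    ``biovolumes`` the summed specimen biovolume (ml) per image.
    """

    footprints: np.ndarray
    counts: np.ndarray
    biovolumes: np.ndarray | None = None
    species: list | None = None

    def __post_init__(self) -> None:
        self.footprints = np.asarray(self.footprints, dtype=float)
        self.counts = np.asarray(self.counts)
        if self.counts.shape[0] != self.footprints.size:
            raise ValueError("counts and footprints disagree on image number")
        if self.biovolumes is None:
            self.biovolumes = np.zeros(self.footprints.size)
        self.biovolumes = np.asarray(self.biovolumes, dtype=float)

    @property
    def n_images(self) -> int:
        return self.footprints.size

    @classmethod
    def from_survey(cls, survey, area: str, include_xeno: bool = False) -> "ImagePool":
        """Pool the images of one area of a (standardized) survey."""
        from .diversity import biovolume

        imgs = survey.images[survey.images["area"] == area]
        ids = imgs["image_id"].to_numpy()
        pos = {i: k for k, i in enumerate(ids)}
        sp = survey.specimens_with_meta()
        sp = sp[sp["image_id"].isin(set(ids))]
        if not include_xeno:
            sp = sp[~sp["is_xeno"]]
        species = sorted(sp["msp"].unique())
        col = {m: j for j, m in enumerate(species)}
        counts = np.zeros((ids.size, len(species)), dtype=np.int32)
        if len(sp):
            np.add.at(counts,
                      (sp["image_id"].map(pos).to_numpy(), sp["msp"].map(col).to_numpy()), 1)
        biov = np.zeros(ids.size)
        if len(sp):
            v = biovolume(sp["length_mm"].to_numpy(), sp["width_mm"].to_numpy())
            np.add.at(biov, sp["image_id"].map(pos).to_numpy(), v)
        return cls(footprints=imgs["footprint_m2"].to_numpy(), counts=counts,
                   biovolumes=biov, species=species)


def _p_from_agg(agg: np.ndarray):
    tot = agg.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(tot > 0, agg / tot, 0.0), tot[:, 0]


def _density(agg, area, biov):
    return agg.sum(axis=1) / area

def _biomass_density(agg, area, biov):
    return biov / area

def _richness(agg, area, biov):
    return (agg > 0).sum(axis=1).astype(float)

def _exp_shannon(agg, area, biov):
    p, tot = _p_from_agg(agg)
    with np.errstate(invalid="ignore", divide="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    return np.where(tot > 0, np.exp(-plogp.sum(axis=1)), np.nan)

def _inv_simpson(agg, area, biov):
    p, tot = _p_from_agg(agg)
    s2 = (p**2).sum(axis=1)
    return np.where(tot > 0, 1.0 / np.where(s2 > 0, s2, 1.0), np.nan)


#: parameter name -> (vectorized function over aggregated draws, centre statistic,
#: default replacement policy): bootstrap for density/biomass/exp H'/1/D,
#: without replacement for richness
PARAMETERS = {
    "density": (_density, "mean", True),
    "biomass_density": (_biomass_density, "median", True),
    "richness": (_richness, "mean", False),
    "exp_shannon": (_exp_shannon, "mean", True),
    "inv_simpson": (_inv_simpson, "mean", True),
}


@dataclass
class CurveResult:
    """Per-size resampling statistics for one ecological parameter."""

    parameter: str
    data: pd.DataFrame    # n_images, mean_area_m2, mean_individuals, centre, cv, lo, hi
    replace: bool
    reps: int
    centre_stat: str = "mean"

    def at_area(self, area_m2: float) -> pd.Series:
        """Row whose mean aggregate area is closest to ``area_m2``."""
        i = (self.data["mean_area_m2"] - area_m2).abs().idxmin()
        return self.data.loc[i]


@dataclass
class StabilizationReport:
    """Minimum adequate sampling-unit size for one parameter."""

    parameter: str
    reached: bool
    n_images: float = np.nan
    individuals: float = np.nan
    area_m2: float = np.nan
    tol_fraction: float = 0.05
    window: int = 3


def size_grid(n_pool: int, n_sizes: int = 16, smallest: int = 10) -> np.ndarray:
    """Geometric grid of image counts from ``smallest`` to the pool size."""
    if n_pool < smallest:
        raise ValueError("pool smaller than the smallest size")
    return np.unique(np.geomspace(smallest, n_pool, n_sizes).round().astype(int))


def _draw_indices(n: int, size: int, reps: int, replace: bool,
                  rng: np.random.Generator) -> np.ndarray:
    if replace:
        return rng.integers(0, n, size=(reps, size))
    if size > n:
        raise ValueError("size exceeds pool for without-replacement draws")
    # per-rep random permutation via argsort of uniforms
    return np.argsort(rng.random((reps, n)), axis=1)[:, :size]


def _aggregate(pool: ImagePool, idx: np.ndarray):
    """Selection-count matrix-multiply aggregation of counts/areas/biovolumes."""
    reps, size = idx.shape
    sel = np.zeros((reps, pool.n_images), dtype=np.float32)
    rows = np.repeat(np.arange(reps), size)
    np.add.at(sel, (rows, idx.ravel()), 1.0)
    agg = sel @ pool.counts.astype(np.float32)
    area = sel @ pool.footprints
    biov = sel @ pool.biovolumes
    return agg, area, biov


def resample_parameter(pool: ImagePool, parameter: str, sizes=None, reps: int = 1000,
                       replace: bool | None = None, seed=None,
                       conf: float = 0.95, max_redraws: int = 10) -> CurveResult:
    """Bootstrap/subsample a parameter over a grid of sampling-unit sizes.

    At each size, ``reps`` image sets are drawn and the parameter evaluated
    on each aggregated set; the centre (mean, or median for biomass
    density), CV = sd/mean over replicate values, and percentile CIs are
    recorded together with the mean seabed area and mean individual count of
    the sets.  Draws on which the parameter is undefined (no individuals)
    are redrawn and counted, with a warning past ``max_redraws`` rounds.
    """
    if parameter not in PARAMETERS:
        raise ValueError(f"unknown parameter {parameter!r}; options: {sorted(PARAMETERS)}")
    fn, centre_stat, default_replace = PARAMETERS[parameter]
    replace = default_replace if replace is None else replace
    if pool.n_images == 0:
        raise ValueError("empty image pool")
    rng = np.random.default_rng(seed)
    sizes = size_grid(pool.n_images) if sizes is None else \
        np.asarray(sizes, dtype=int)
    qlo, qhi = 0.5 - conf / 2, 0.5 + conf / 2

    rows = []
    for size in sizes:
        idx = _draw_indices(pool.n_images, int(size), reps, replace, rng)
        agg, area, biov = _aggregate(pool, idx)
        vals = fn(agg, area, biov)
        bad = ~np.isfinite(vals)
        rounds = 0
        while bad.any() and rounds < max_redraws:
            redraw = _draw_indices(pool.n_images, int(size), int(bad.sum()), replace, rng)
            a2, ar2, b2 = _aggregate(pool, redraw)
            v2 = fn(a2, ar2, b2)
            vals[bad], area[bad], agg[bad] = v2, ar2, a2
            bad = ~np.isfinite(vals)
            rounds += 1
        if bad.any():
            warnings.warn(f"{parameter}: {bad.sum()} undefined draws remain at size {size}")
            vals = vals[~bad]
        centre = float(np.median(vals)) if centre_stat == "median" else float(vals.mean())
        mean = vals.mean()
        rows.append({
            "n_images": int(size),
            "mean_area_m2": float(area.mean()),
            "mean_individuals": float(agg.sum(axis=1).mean()),
            "centre": centre,
            "cv": float(vals.std(ddof=1) / mean) if mean != 0 else 0.0,
            "lo": float(np.quantile(vals, qlo)),
            "hi": float(np.quantile(vals, qhi)),
        })
    return CurveResult(parameter=parameter, data=pd.DataFrame(rows), replace=replace,
                       reps=reps, centre_stat=centre_stat)


def autosimilarity(pool: ImagePool, sizes=None, reps: int = 1000, seed=None,
                   conf: float = 0.95) -> CurveResult:
    """Bray-Curtis autosimilarity (%) between two disjoint random image groups.

    At each size two without-replacement, non-overlapping groups of that
    many images are drawn, aggregated, square-root density transformed, and
    100 x (1 - Bray-Curtis dissimilarity) recorded.  Sizes for which the
    pool cannot supply two disjoint groups are skipped with a warning.
    """
    rng = np.random.default_rng(seed)
    n = pool.n_images
    sizes = size_grid(max(n // 2, 1)) if sizes is None else np.asarray(sizes, dtype=int)
    qlo, qhi = 0.5 - conf / 2, 0.5 + conf / 2
    rows = []
    for size in sizes:
        if 2 * size > n:
            warnings.warn(f"autosimilarity size {size} skipped: pool of {n} too small")
            continue
        perm = np.argsort(rng.random((reps, n)), axis=1)
        ia, ib = perm[:, :size], perm[:, size: 2 * size]
        agg_a, area_a, _ = _aggregate(pool, ia)
        agg_b, area_b, _ = _aggregate(pool, ib)
        ya = np.sqrt(agg_a / area_a[:, None])
        yb = np.sqrt(agg_b / area_b[:, None])
        num = np.abs(ya - yb).sum(axis=1)
        den = (ya + yb).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            sim = np.where(den > 0, 100.0 * (1.0 - num / den), np.nan)
        sim = sim[np.isfinite(sim)]
        rows.append({
            "n_images": int(size),
            "mean_area_m2": float(area_a.mean()),
            "mean_individuals": float(agg_a.sum(axis=1).mean()),
            "centre": float(sim.mean()),
            "cv": float(sim.std(ddof=1) / sim.mean()) if sim.mean() != 0 else 0.0,
            "lo": float(np.quantile(sim, qlo)),
            "hi": float(np.quantile(sim, qhi)),
        })
    if not rows:
        raise ValueError("no evaluable sizes for autosimilarity")
    return CurveResult(parameter="autosimilarity", data=pd.DataFrame(rows),
                       replace=False, reps=reps)


def detect_stabilization(curve: CurveResult, tol_fraction: float = 0.05,
                         window: int = 3) -> StabilizationReport:
    """Minimum unit size after which the centre stays within +-tol of the
    terminal (largest-size) centre, over a tail of at least ``window`` grid
    points.

    A curve that never stabilizes is reported ``reached=False`` with nan
    sizes.
    """
    df = curve.data.sort_values("n_images").reset_index(drop=True)
    centres = df["centre"].to_numpy()
    terminal = centres[-1]
    tol = abs(terminal) * tol_fraction
    within = np.abs(centres - terminal) <= tol
    # first index from which everything stays within tolerance
    ok_from = None
    for i in range(len(centres)):
        if within[i:].all() and len(centres) - i >= window:
            ok_from = i
            break
    if ok_from is None:
        return StabilizationReport(parameter=curve.parameter, reached=False,
                                   tol_fraction=tol_fraction, window=window)
    row = df.iloc[ok_from]
    return StabilizationReport(parameter=curve.parameter, reached=True,
                               n_images=float(row["n_images"]),
                               individuals=float(row["mean_individuals"]),
                               area_m2=float(row["mean_area_m2"]),
                               tol_fraction=tol_fraction, window=window)
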