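"""Environmental descriptors from image tables and sediment samples.

Nodule metrics (size-filtered % cover and total area per unit, hard-substrata
density), grain-size statistics by the geometric method of moments, and
sediment chemistry (CaCO3 by TC - TOC difference, molar C:N).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import reference

__all__ = [
    "filter_nodules",
    "image_cover_pct",
    "unit_nodule_metrics",
    "hard_substrata_density",
    "SedimentSample",
    "grain_stats",
    "carbonate_cn",
]

# molar masses (g/mol)
M_C = 12.01
M_N = 14.007
M_CACO3 = 100.09


def filter_nodules(areas_cm2, lo: float = reference.NODULE_FILTER_CM2[0],
                   hi: float = reference.NODULE_FILTER_CM2[1]) -> np.ndarray:
    """Keep nodules with area in the closed interval [lo, hi] cm^2.

    The default window (0.5-60 cm^2, ~1-10 cm maximum diameter) excludes
    detection noise and large non-nodule formations.
    """
    a = np.asarray(areas_cm2, dtype=float)
    if (a < 0).any():
        raise ValueError("nodule areas must be non-negative")
    return a[(a >= lo) & (a <= hi)]


def image_cover_pct(areas_cm2, footprint_m2: float) -> float:
    """Percent of the image footprint covered by (filtered) nodules."""
    if footprint_m2 <= 0:
        raise ValueError("footprint must be positive")
    return 100.0 * float(np.sum(areas_cm2)) / (footprint_m2 * 1e4)


def unit_nodule_metrics(images: pd.DataFrame, nodules: pd.DataFrame,
                        size_filter: bool = True,
                        area_weighted: bool = False) -> pd.DataFrame:
    """Per-unit nodule summary from an image table and a nodule table.

    ``images`` needs columns unit, image_id, footprint_m2; ``nodules`` needs
    image_id, area_cm2.  Unit cover is the unweighted mean of per-image
    covers (the default; ``area_weighted`` divides summed nodule area by
    summed footprint instead), total nodule area is the exact per-image sum,
    and the mean nodule size is pooled over every retained nodule in the unit.
    """
    nod = nodules
    if size_filter:
        keep = (nod["area_cm2"] >= reference.NODULE_FILTER_CM2[0]) & \
               (nod["area_cm2"] <= reference.NODULE_FILTER_CM2[1])
        nod = nod[keep]
    per_img = nod.groupby("image_id")["area_cm2"].agg(["sum", "count"])
    img = images.merge(per_img, left_on="image_id", right_index=True, how="left")
    img[["sum", "count"]] = img[["sum", "count"]].fillna(0.0)
    img["cover_pct"] = 100.0 * img["sum"] / (img["footprint_m2"] * 1e4)

    g = img.groupby("unit", sort=False)
    out = pd.DataFrame({
        "n_images": g.size(),
        "unit_area_m2": g["footprint_m2"].sum(),
        "cover_pct": g["cover_pct"].mean(),
        "total_nodule_m2": g["sum"].sum() / 1e4,
        "n_nodules": g["count"].sum().astype(int),
    })
    if area_weighted:
        out["cover_pct"] = 100.0 * (out["total_nodule_m2"] / out["unit_area_m2"])
    with np.errstate(invalid="ignore"):
        out["mean_nodule_cm2"] = np.where(
            out["n_nodules"] > 0,
            g["sum"].sum() / np.maximum(out["n_nodules"], 1), np.nan)
    return out.reset_index()


def hard_substrata_density(counts, unit_areas_m2) -> np.ndarray:
    """Hard-substrata density in items per hectare."""
    c = np.asarray(counts, dtype=float)
    a = np.asarray(unit_areas_m2, dtype=float)
    if (a <= 0).any():
        raise ValueError("unit areas must be positive")
    return c / (a / 1e4)


@dataclass
class SedimentSample:
    """Particle-size distribution plus bulk chemistry of one sediment sample.

    ``class_bounds_um`` are the (lo, hi) bounds of each size class and
    ``fractions`` the volume fractions (summing to ~1).  TC/TOC/TN in % dry
    weight.
    """

    class_bounds_um: list
    fractions: list
    tc_pct: float = np.nan
    toc_pct: float = np.nan
    tn_pct: float = np.nan

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        if (f < 0).any():
            raise ValueError("fractions must be non-negative")
        if f.sum() > 0 and not np.isclose(f.sum(), 1.0, atol=0.02):
            raise ValueError("fractions must sum to ~1")


def grain_stats(sample: SedimentSample, mud_threshold_um: float = 63.0) -> dict:
    """Geometric method-of-moments mean grain size and mud fraction.

    Mean = exp(sum f_i ln m_i) with m_i the geometric midpoints of the size
    classes; mud % is the summed fraction below ``mud_threshold_um``, the
    straddling class prorated linearly in ln-size.
    """
    f = np.asarray(sample.fractions, dtype=float)
    bounds = np.asarray(sample.class_bounds_um, dtype=float)
    if f.sum() <= 0:
        raise ValueError("all-zero particle-size distribution")
    if (bounds <= 0).any():
        raise ValueError("size-class bounds must be positive")
    f = f / f.sum()
    mid = np.sqrt(bounds[:, 0] * bounds[:, 1])
    gmean = float(np.exp(np.sum(f * np.log(mid))))

    lnt = np.log(mud_threshold_um)
    lo, hi = np.log(bounds[:, 0]), np.log(bounds[:, 1])
    below = np.clip((lnt - lo) / (hi - lo), 0.0, 1.0)
    mud = 100.0 * float(np.sum(f * below))
    return {"geometric_mean_um": gmean, "mud_pct": mud}


def carbonate_cn(sample: SedimentSample) -> dict:
    """CaCO3 (% dry weight) from TC - TOC, and the molar C:N ratio."""
    tc, toc, tn = sample.tc_pct, sample.toc_pct, sample.tn_pct
    if tc < toc:
        raise ValueError("TC must be >= TOC")
    if toc < 0:
        raise ValueError("TOC must be non-negative")
    caco3 = (tc - toc) * (M_CACO3 / M_C)
    if tn > 0:
        cn = (toc / M_C) / (tn / M_N)
    else:
        warnings.warn("TN is zero; molar C:N undefined")
        cn = np.nan
    return {"caco3_pct": caco3, "cn_molar": cn}
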