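"""Standing stock and diversity descriptors for standardized sampling units.

Implements per-unit and pooled numerical density, the ellipsoid biovolume
biomass proxy, Hill numbers of order 0/1/2, K-dominance curves, and
sample-based / individual-based rarefaction with Chao-type extrapolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import norm

from . import reference

__all__ = [
    "AbundanceTable",
    "HillNumbers",
    "biovolume",
    "hill_numbers",
    "hill_profile",
    "k_dominance",
    "chao1",
    "chao2",
    "RarefactionCurve",
    "rarefy_richness",
    "rarefy_diversity",
]


@dataclass
class AbundanceTable:
    """Units x morphospecies count matrix with per-unit areas and groups.

    ``counts`` is indexed by unit id; ``unit_areas`` (m^2) and ``groups``
    (area / landscape-type label) align with that index.
    """

    counts: pd.DataFrame
    unit_areas: pd.Series
    groups: pd.Series
    species_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        c = self.counts.to_numpy()
        if (c < 0).any() or not np.allclose(c, np.round(c)):
            raise ValueError("counts must be non-negative integers")
        self.counts = self.counts.astype(int)
        self.unit_areas = self.unit_areas.reindex(self.counts.index).astype(float)
        self.groups = self.groups.reindex(self.counts.index)
        if (self.unit_areas <= 0).any():
            raise ValueError("unit areas must be positive")

    @classmethod
    def from_survey(cls, survey, include_xeno: bool = False) -> "AbundanceTable":
        """Build the table from a (standardized) :class:`~benthoscape.synth.Survey`."""
        sp = survey.specimens_with_meta()
        if not include_xeno:
            sp = sp[~sp["is_xeno"]]
        units = survey.images.groupby("unit", sort=False)
        areas = units["footprint_m2"].sum()
        groups = units["area"].first()
        counts = pd.crosstab(sp["unit"], sp["msp"]).reindex(areas.index, fill_value=0)
        counts.columns.name = None
        meta = survey.community.species.set_index("msp")
        return cls(counts=counts, unit_areas=areas, groups=groups,
                   species_meta=meta.loc[meta.index.intersection(counts.columns)])

    # -- standing stock ---------------------------------------------------------

    def densities(self) -> pd.DataFrame:
        """Per-unit, per-species density (ind m^-2)."""
        return self.counts.div(self.unit_areas, axis=0)

    def unit_density(self) -> pd.Series:
        """Per-unit total density (ind m^-2)."""
        return self.counts.sum(axis=1) / self.unit_areas

    def density_by(self, level: str) -> pd.DataFrame:
        """Per-unit density split by a species metadata column (guild/habit/group)."""
        if self.species_meta is None or level not in self.species_meta:
            raise ValueError(f"no species metadata column {level!r}")
        lab = self.species_meta[level].reindex(self.counts.columns)
        sums = self.counts.T.groupby(lab).sum().T
        return sums.div(self.unit_areas, axis=0)

    def pooled_counts(self, group=None) -> pd.Series:
        sub = self.counts if group is None else self.counts[self.groups == group]
        return sub.sum(axis=0)

    def incidence_frequencies(self, group=None) -> tuple[pd.Series, int]:
        """(number of units each species occurs in, number of units)."""
        sub = self.counts if group is None else self.counts[self.groups == group]
        return (sub > 0).sum(axis=0), len(sub)


class HillNumbers(NamedTuple):
    richness: float
    exp_shannon: float
    inv_simpson: float


def hill_numbers(counts) -> HillNumbers:
    """Hill numbers of order 0, 1, 2 of one count vector.

    S = number of species present; exp H' = exp(-sum p ln p);
    1/D = 1 / sum p^2.  For any non-empty sample S >= exp H' >= 1/D >= 1.
    """
    n = np.asarray(counts, dtype=float)
    n = n[n > 0]
    if n.size == 0 or n.sum() <= 0:
        raise ValueError("empty sample has no diversity")
    p = n / n.sum()
    return HillNumbers(
        richness=float(p.size),
        exp_shannon=float(np.exp(-np.sum(p * np.log(p)))),
        inv_simpson=float(1.0 / np.sum(p**2)),
    )


def hill_profile(table: AbundanceTable, include_pooled: bool = True) -> pd.DataFrame:
    rows = {u: hill_numbers(table.counts.loc[u])._asdict() for u in table.counts.index}
    df = pd.DataFrame.from_dict(rows, orient="index")
    if include_pooled:
        df.loc["pooled"] = hill_numbers(table.pooled_counts())._asdict()
    return df


def biovolume(length_mm, width_mm, shape_factor: float = 1.0):
    """Ellipsoid-of-revolution biovolume (ml) from length and width (mm).

    V = shape_factor * (pi/6) L W^2 mm^3, converted to ml; 1 ml is taken as
    1 g fresh wet weight downstream.  Requires length >= width > 0.
    """
    L = np.asarray(length_mm, dtype=float)
    W = np.asarray(width_mm, dtype=float)
    if np.any(W <= 0) or np.any(L < W):
        raise ValueError("requires length >= width > 0")
    return shape_factor * (np.pi / 6.0) * L * W**2 / 1000.0


def biomass_density(specimens: pd.DataFrame, unit_areas: pd.Series,
                    shape_factor: float = 1.0) -> pd.Series:
    """Per-unit biovolume biomass proxy (ml m^-2 ~ g fwwt m^-2).

    ``specimens`` needs columns unit, length_mm, width_mm.
    """
    if len(specimens):
        v = biovolume(specimens["length_mm"], specimens["width_mm"], shape_factor)
        tot = pd.Series(v, index=specimens.index).groupby(specimens["unit"]).sum()
    else:
        tot = pd.Series(dtype=float)
    return tot.reindex(unit_areas.index, fill_value=0.0) / unit_areas


def k_dominance(table: AbundanceTable, group=None, conf: float = 0.95) -> pd.DataFrame:
    """Mean cumulative ranked relative-abundance curve across replicate units.

    Per unit, species are ranked by descending abundance and the cumulative
    percentage is taken; curves are padded at 100 % beyond each unit's
    richness and averaged, with a normal-theory CI across units.
    """
    sub = table.counts if group is None else table.counts[table.groups == group]
    if len(sub) == 0:
        raise ValueError("no units to compute K-dominance from")
    curves = []
    for _, row in sub.iterrows():
        n = np.sort(row.to_numpy()[row.to_numpy() > 0])[::-1]
        if n.size == 0:
            raise ValueError("empty unit in K-dominance")
        curves.append(100.0 * np.cumsum(n) / n.sum())
    max_rank = max(c.size for c in curves)
    mat = np.vstack([np.pad(c, (0, max_rank - c.size), constant_values=100.0)
                     for c in curves])
    mean = mat.mean(axis=0)
    z = norm.ppf(0.5 + conf / 2)
    se = mat.std(axis=0, ddof=1) / np.sqrt(mat.shape[0]) if mat.shape[0] > 1 else \
        np.zeros(max_rank)
    return pd.DataFrame({
        "rank": np.arange(1, max_rank + 1),
        "cum_pct": mean,
        "lo": np.clip(mean - z * se, 0, 100),
        "hi": np.clip(mean + z * se, 0, 100),
    })


# -- rarefaction ----------------------------------------------------------------


def chao2(incidence, n_units: int) -> float:
    """Chao2 asymptotic richness from incidence frequencies."""
    y = np.asarray(incidence)
    s_obs = float((y > 0).sum())
    q1 = float((y == 1).sum())
    q2 = float((y == 2).sum())
    t = n_units
    if q2 > 0:
        return s_obs + (t - 1) / t * q1**2 / (2 * q2)
    return s_obs + (t - 1) / t * q1 * (q1 - 1) / 2.0

def chao1(abundance) -> float:
    """Chao1 asymptotic richness from abundances."""
    x = np.asarray(abundance)
    s_obs = float((x > 0).sum())
    f1 = float((x == 1).sum())
    f2 = float((x == 2).sum())
    n = x.sum()
    if n <= 1:
        return s_obs
    if f2 > 0:
        return s_obs + (n - 1) / n * f1**2 / (2 * f2)
    return s_obs + (n - 1) / n * f1 * (f1 - 1) / 2.0


def _log_choose(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


@dataclass
class RarefactionCurve:
    """Expected richness (or diversity) versus sampling effort."""

    data: pd.DataFrame           # effort, x, expected, se, lo, hi, extrapolated
    mode: str
    observed: float
    asymptote: float | None = None
    meta: dict = field(default_factory=dict)


def _interp_expected(freqs: np.ndarray, total: float, t: np.ndarray):
    """Hypergeometric E[S(t)] and the per-species retention probabilities."""
    y = freqs[freqs > 0]
    # alpha_it = C(total - y_i, t) / C(total, t): P(species i missed at effort t)
    with np.errstate(invalid="ignore"):
        log_a = _log_choose((total - y)[None, :], t[:, None]) - \
            _log_choose(total, t)[:, None]
    alpha = np.where((total - y)[None, :] >= t[:, None], np.exp(log_a), 0.0)
    return y.size - alpha.sum(axis=1), alpha


def rarefy_richness(freqs, total: int, effort=None, mode: str = "sample",
                    extrapolate_to: float | None = None, conf: float = 0.95,
                    area_per_sample: float | None = None) -> RarefactionCurve:
    """Rarefaction (interpolation) and Chao-type extrapolation of richness.

    Parameters
    ----------
    freqs
        Sample mode: incidence frequencies over ``total`` sampling units.
        Individual mode: species abundances, ``total`` = sum of abundances.
    effort
        Efforts (units or individuals) to evaluate; defaults to 1..total.
        Efforts beyond ``total`` are extrapolated (flagged); extrapolation
        beyond 3x the observed effort is additionally flagged in ``meta``.
    area_per_sample
        If given, an ``x`` column in m^2 is added (sample mode: effort x
        area per unit), which is how area-based curves are expressed.
    """
    if mode not in {"sample", "individual"}:
        raise ValueError("mode must be 'sample' or 'individual'")
    y = np.asarray(freqs, dtype=float)
    y = y[y > 0]
    if y.size == 0:
        raise ValueError("no occurrences to rarefy")
    total = int(total)
    s_obs = float(y.size)
    asym = chao2(y, total) if mode == "sample" else chao1(y)
    rare_count = float((y == 1).sum())  # Q1 or f1

    if effort is None:
        effort = np.arange(1, total + 1)
        if extrapolate_to is not None:
            step = max(int((extrapolate_to - total) / 20), 1)
            effort = np.concatenate([effort, np.arange(total + step,
                                                       extrapolate_to + step, step)])
    effort = np.asarray(effort, dtype=int)
    if (effort < 1).any():
        raise ValueError("efforts must be >= 1")

    interp = effort[effort <= total]
    extrap = effort[effort > total]
    exp_i, alpha = _interp_expected(y, total, interp)
    # Chao-anchored unconditional variance: vanishes at t=0, equals
    # S_obs (1 - S_obs / S_chao) at t = total
    var_i = np.maximum(((1 - alpha) ** 2).sum(axis=1) - exp_i**2 / asym, 0.0)

    s0 = asym - s_obs
    if s0 > 0 and rare_count > 0:
        m = (extrap - total).astype(float)
        exp_e = s_obs + s0 * (1 - (1 - rare_count / (rare_count + total * s0)) ** m)
    else:
        exp_e = np.full(extrap.shape, s_obs)
    var_T = float(max(s_obs * (1 - s_obs / asym), 0.0))
    var_e = np.full(extrap.shape, var_T)  # held at the observed-effort value

    expected = np.concatenate([exp_i, exp_e])
    se = np.sqrt(np.concatenate([var_i, var_e]))
    z = norm.ppf(0.5 + conf / 2)
    df = pd.DataFrame({
        "effort": effort,
        "expected": expected,
        "se": se,
        "lo": np.maximum(expected - z * se, 0.0),
        "hi": np.minimum(expected + z * se, asym if asym > 0 else np.inf),
        "extrapolated": effort > total,
    })
    if area_per_sample is not None:
        df.insert(1, "x_m2", df["effort"] * float(area_per_sample))
    meta = {"beyond_3x": bool((effort > 3 * total).any())}
    return RarefactionCurve(data=df, mode=mode, observed=s_obs, asymptote=asym, meta=meta)


def rarefy_diversity(table: AbundanceTable, effort=None, mode: str = "sample",
                     reps: int = 1000, seed=None, conf: float = 0.95,
                     group=None) -> pd.DataFrame:
    """Bootstrap (with replacement) exp H' and 1/D at increasing effort.

    Sample mode draws whole sampling units with replacement and pools them;
    individual mode draws individuals with replacement from the pooled
    relative abundances.  Percentile CIs across replicates.
    """
    rng = np.random.default_rng(seed)
    sub = table.counts if group is None else table.counts[table.groups == group]
    counts = sub.to_numpy()
    if mode == "sample":
        n_max = len(sub)
        efforts = np.asarray(effort if effort is not None else np.arange(1, n_max + 1),
                             dtype=int)
    elif mode == "individual":
        pooled = counts.sum(axis=0)
        p = pooled / pooled.sum()
        n_max = int(pooled.sum())
        efforts = np.asarray(effort if effort is not None
                             else np.unique(np.geomspace(2, n_max, 15).astype(int)), dtype=int)
    else:
        raise ValueError("mode must be 'sample' or 'individual'")
    if (efforts < 1).any():
        raise ValueError("effort must be >= 1")

    qlo, qhi = 0.5 - conf / 2, 0.5 + conf / 2
    rows = []
    for t in efforts:
        eh = np.empty(reps)
        iv = np.empty(reps)
        for r in range(reps):
            if mode == "sample":
                agg = counts[rng.integers(0, len(counts), size=t)].sum(axis=0)
            else:
                agg = rng.multinomial(t, p)
            h = hill_numbers(agg)
            eh[r], iv[r] = h.exp_shannon, h.inv_simpson
        rows.append({
            "effort": t,
            "exp_shannon": eh.mean(), "exp_shannon_lo": np.quantile(eh, qlo),
            "exp_shannon_hi": np.quantile(eh, qhi),
            "inv_simpson": iv.mean(), "inv_simpson_lo": np.quantile(iv, qlo),
            "inv_simpson_hi": np.quantile(iv, qhi),
        })
    return pd.DataFrame(rows)
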