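"""Long-tailed megafauna community model.

The metazoan pool draws per-species reference abundances from a log-series
distribution, perturbs them lognormally per survey area (composition turnover
between landscape types), and scales each area's relative abundances to the
specified total density.  Individuals are realized per image as independent
Poisson counts; nodule-attached (NA) taxa have their local intensity
modulated by nodule cover so that they co-occur with nodules while the
area-mean density stays exactly at the configured value.

Xenophyophores are a separate pool, dominated by a single species
("A-monile") with fixed per-area densities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .specs import CommunitySpec, as_rng

__all__ = ["Community"]

GUILDS = ("SF", "DF", "PS")
HABITS = ("NA", "NFL")

# cosmetic higher-taxon groups per guild, loosely matching abyssal megafauna
_GROUPS = {
    "SF": ["Porifera", "Alcyonacea", "Actiniaria", "Antipatharia",
           "Cheilostomatida", "Crinoidea", "Tunicata"],
    "DF": ["Holothuroidea", "Ophiuroidea", "Polychaeta", "Echiura"],
    "PS": ["Decapoda", "Asteroidea", "Actinopterygii"],
}


class Community:
    """Per-area intensity model over a fixed morphospecies pool.

    Attributes
    ----------
    species : pandas.DataFrame
        One row per morphospecies: msp, group, guild, habit, is_xeno,
        log_mean_length, width_ratio, and a ``dens_<area>`` column of
        individuals m^-2 for every survey area.
    """

    def __init__(self, spec: CommunitySpec, seed):
        if spec.n_morphospecies < 1:
            raise ValueError("empty morphospecies pool")
        self.spec = spec
        rng = as_rng(seed)
        areas = spec.areas

        n = spec.n_morphospecies
        ref = stats.logser.rvs(spec.logseries_x, size=n, random_state=rng).astype(float)
        guild = rng.choice(GUILDS, size=n, p=[spec.guild_probs[g] for g in GUILDS])
        group = np.array([rng.choice(_GROUPS[g]) for g in guild])
        # the most abundant fraction of taxa is nodule-attached
        order = np.argsort(-ref, kind="stable")
        habit = np.full(n, "NFL", dtype=object)
        habit[order[: max(1, int(round(spec.na_richness_fraction * n)))]] = "NA"

        log_len = rng.normal(np.log(spec.length_log_median_mm),
                             spec.length_species_sigma, size=n)
        wr = rng.uniform(*spec.width_ratio_range, size=n)

        rows = pd.DataFrame({
            "msp": [f"msp-{i + 1:03d}" for i in range(n)],
            "group": group, "guild": guild, "habit": habit,
            "is_xeno": False, "log_mean_length": log_len, "width_ratio": wr,
        })
        # per-area densities: lognormal turnover on the shared pool, scaled to
        # the specified area totals (mean-one noise keeps rel-abundance shape)
        for area in areas:
            noise = np.exp(rng.normal(-0.5 * spec.area_sigma**2, spec.area_sigma, size=n))
            w = ref * noise
            rows[f"dens_{area}"] = spec.metazoan_density[area] * w / w.sum()

        if spec.n_xenophyophores > 0:
            nx = spec.n_xenophyophores
            xref = stats.logser.rvs(spec.logseries_x, size=nx - 1, random_state=rng).astype(float) \
                if nx > 1 else np.empty(0)
            xhabit = np.where(rng.random(nx) < 0.5, "NA", "NFL").astype(object)
            xrows = pd.DataFrame({
                "msp": ["xeno-amonile"] + [f"xeno-{i + 2:03d}" for i in range(nx - 1)],
                "group": "Xenophyophorea", "guild": "SF", "habit": xhabit,
                "is_xeno": True,
                "log_mean_length": rng.normal(np.log(40.0), 0.4, size=nx),
                "width_ratio": rng.uniform(0.3, 0.7, size=nx),
            })
            for area in areas:
                total = spec.xenophyophore_density.get(area, 0.0)
                amon = min(spec.amonile_density.get(area, 0.0), total)
                rest = total - amon
                dens = np.empty(nx)
                dens[0] = amon
                if nx > 1:
                    noise = np.exp(rng.normal(-0.5 * spec.area_sigma**2, spec.area_sigma,
                                              size=nx - 1))
                    w = xref * noise
                    dens[1:] = rest * w / w.sum() if w.sum() > 0 else 0.0
                xrows[f"dens_{area}"] = dens
            rows = pd.concat([rows, xrows], ignore_index=True)

        self.species = rows

    @property
    def areas(self) -> tuple[str, ...]:
        return self.spec.areas

    @property
    def n_species(self) -> int:
        return len(self.species)

    def intensities(self, area: str) -> np.ndarray:
        """Per-species density (ind m^-2) in the given area."""
        return self.species[f"dens_{area}"].to_numpy()

    def total_density(self, area: str, include_xeno: bool = True) -> float:
        d = self.intensities(area)
        if not include_xeno:
            d = d[~self.species["is_xeno"].to_numpy()]
        return float(d.sum())

    def sample_image_counts(self, area: str, footprints_m2, seed,
                            covers=None, mean_cover: float | None = None) -> np.ndarray:
        """Poisson specimen counts per image and morphospecies.

        Parameters
        ----------
        footprints_m2 : array (n_images,)
        covers : array (n_images,), optional
            Local nodule-cover fractions; with ``mean_cover`` > 0 the
            intensity of NA taxa is modulated by
            ``(1 - q) + q * cover / mean_cover`` (q = attachment probability),
            which has unit mean over images, so area densities are unbiased.

        Returns
        -------
        (n_images, n_species) int32 array.
        """
        rng = as_rng(seed)
        fp = np.asarray(footprints_m2, dtype=float)
        dens = self.intensities(area)
        lam = fp[:, None] * dens[None, :]
        if covers is not None and mean_cover is not None and mean_cover > 0:
            q = self.spec.attachment_prob
            mod = (1.0 - q) + q * np.asarray(covers, dtype=float) / mean_cover
            is_na = (self.species["habit"] == "NA").to_numpy()
            lam[:, is_na] *= mod[:, None]
        return rng.poisson(lam).astype(np.int32)

    def sample_specimens(self, counts: np.ndarray, image_ids, seed) -> pd.DataFrame:
        """Expand a per-image count matrix into a specimen table.

        Columns: image_id, msp index (``msp_idx``), length_mm, width_mm,
        attached.  Lengths are lognormal around the species mean; widths are
        the species width ratio times length (so length >= width > 0).
        """
        rng = as_rng(seed)
        counts = np.asarray(counts)
        image_ids = np.asarray(image_ids)
        img_idx, sp_idx = np.nonzero(counts)
        reps = counts[img_idx, sp_idx]
        sp = np.repeat(sp_idx, reps)
        img = np.repeat(image_ids[img_idx], reps)

        log_mu = self.species["log_mean_length"].to_numpy()[sp]
        length = np.exp(rng.normal(log_mu, self.spec.length_individual_sigma))
        width = length * self.species["width_ratio"].to_numpy()[sp]
        is_na = (self.species["habit"] == "NA").to_numpy()[sp]
        attached = is_na & (rng.random(sp.size) < self.spec.attachment_prob)
        return pd.DataFrame({
            "image_id": img.astype(np.int64),
            "msp_idx": sp.astype(np.int32),
            "length_mm": length.astype(np.float32),
            "width_mm": width.astype(np.float32),
            "attached": attached,
        })
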