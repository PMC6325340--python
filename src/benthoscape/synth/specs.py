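"""Parameter specifications for the synthetic generators.

Defaults reproduce the study conditions of the APEI6 AUV survey collected in
:mod:`benthoscape.reference`: three landscape strata, 40 zig-zag sampling
units per area of which 4 are analysed, a 3 m target altitude imaging
1.71 m^2 per photograph, units standardized to c. 1320 m^2, a 129-morphospecies
metazoan pool with a log-series abundance distribution, and nodule cover
means of 10.1/6.3/3.8 % patchy at tens of metres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .. import reference

__all__ = ["BathymetrySpec", "NoduleFieldSpec", "CommunitySpec", "SurveySpec", "as_rng"]


def as_rng(seed) -> np.random.Generator:
    """Coerce an int seed, SeedSequence or Generator to a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class BathymetrySpec:
    """Horst-and-graben depth raster parameters.

    The waveform is a north-south elongated quasi-periodic ridge/trough
    succession (a cosine in easting with a slowly drifting phase) on a base
    depth, plus smooth correlated noise.
    """

    nrows: int = 200
    ncols: int = 200
    cell_size_m: float = 100.0
    base_depth_m: float = 4100.0
    ridge_spacing_m: float = 5000.0     # 1-10 km characteristic spacing
    relief_amplitude_m: float = 75.0
    noise_sd_m: float = 5.0
    noise_corr_m: float = 500.0
    phase_jitter_rad: float = 0.25      # sd of the along-ridge phase drift
    depth_range_m: tuple[float, float] = reference.DEPTH_RANGE_M
    origin_x: float = 0.0
    origin_y: float = 0.0

    def __post_init__(self) -> None:
        if self.cell_size_m <= 0:
            raise ValueError("cell size must be positive")
        if self.ridge_spacing_m < 2 * self.cell_size_m:
            raise ValueError("ridge spacing below 2 cells would alias the waveform")


@dataclass
class NoduleFieldSpec:
    """Nodule cover field and size distribution for one survey area.

    Cover is a stationary Gaussian random field squashed through a logit
    link, with correlation length ``corr_length_m`` (patchiness at tens of
    metres).  Nodule areas (cm^2) are lognormal; the default (mu, sigma) is
    the analytic solution of mean area 2.5 cm^2 with 90 % of nodules below
    5 cm^2.
    """

    mean_cover_pct: float = 6.4          # survey-wide average cover
    corr_length_m: float = 50.0
    logit_sd: float = 1.0
    size_log_mu: float = 0.61547
    size_log_sigma: float = 0.77552
    field_resolution_m: float = 10.0
    #: density of larger non-nodule hard substrata (rocks, whale bones), items ha^-1
    hard_substrata_per_ha: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mean_cover_pct <= 100.0:
            raise ValueError("mean cover must be within [0, 100] %")
        if self.corr_length_m <= 0:
            raise ValueError("patch correlation length must be positive")


@dataclass
class CommunitySpec:
    """Morphospecies pool and per-area intensity parameters.

    Metazoan relative abundances follow a log-series (parameter ``logseries_x``),
    which at the default reproduces both the long tail and the observed
    one-third fraction of taxa with <= 3 records without further tuning.
    Between-area composition differences are lognormal perturbations of the
    shared pool (``area_sigma``).  Xenophyophores form a separate pool whose
    dominant species (A. monile) has fixed per-area densities.
    """

    n_morphospecies: int = reference.METAZOAN_RICHNESS
    logseries_x: float = 0.99663
    metazoan_density: dict = field(default_factory=lambda: dict(reference.METAZOAN_DENSITY))
    n_xenophyophores: int = reference.XENOPHYOPHORE_RICHNESS
    xenophyophore_density: dict = field(
        default_factory=lambda: dict(reference.XENOPHYOPHORE_DENSITY))
    amonile_density: dict = field(default_factory=lambda: dict(reference.AMONILE_DENSITY))
    guild_probs: dict = field(default_factory=lambda: dict(reference.GUILD_SHARES))
    na_richness_fraction: float = 0.30   # most-abundant taxa become nodule-attached
    attachment_prob: float = reference.NODULE_ATTACHMENT_PROB
    area_sigma: float = 0.3
    # body-size model (mm): species-level lognormal mean lengths, lognormal
    # individual variation, uniform width-to-length ratios
    length_log_median_mm: float = 30.0
    length_species_sigma: float = 0.8
    length_individual_sigma: float = 0.3
    width_ratio_range: tuple[float, float] = (0.2, 0.6)

    def __post_init__(self) -> None:
        if self.n_morphospecies < 1:
            raise ValueError("morphospecies pool must not be empty")
        if not 0 < self.logseries_x < 1:
            raise ValueError("log-series parameter must lie in (0, 1)")
        for d in (self.metazoan_density, self.xenophyophore_density, self.amonile_density):
            if any(v < 0 for v in d.values()):
                raise ValueError("densities must be non-negative")
        for area, v in self.amonile_density.items():
            if v > self.xenophyophore_density.get(area, 0.0):
                raise ValueError("A. monile density cannot exceed total xenophyophore density")

    @property
    def areas(self) -> tuple[str, ...]:
        return tuple(self.metazoan_density)


@dataclass
class SurveySpec:
    """Zig-zag AUV photo-survey geometry and standardization parameters."""

    units_per_area: int = reference.UNITS_PER_AREA
    replicates_per_area: int = reference.REPLICATES_PER_AREA
    unit_length_m: float = 1800.0
    image_spacing_m: float = 1.02        # 1.2 m/s at a 850 ms interval
    lateral_step_m: float = 37.5         # easting advance per zig or zag
    junction_trim_m: float = 10.0        # images this close to a turn are junction images
    target_altitude_m: float = reference.TARGET_ALTITUDE_M
    altitude_sd_m: float = 0.4
    altitude_trunc_m: tuple[float, float] = (1.5, 4.5)
    altitude_window_m: tuple[float, float] = reference.ALTITUDE_WINDOW_M
    footprint_at_target_m2: float = reference.FOOTPRINT_AT_TARGET_M2
    discard_every_second: bool = True
    standard_area_window_m2: tuple[float, float] = reference.STANDARD_AREA_WINDOW_M2

    def __post_init__(self) -> None:
        lo, hi = self.altitude_window_m
        if not 0 < lo < hi:
            raise ValueError("altitude acceptance window must be positive and ordered")
        alo, ahi = self.standard_area_window_m2
        if not 0 < alo < ahi:
            raise ValueError("standardized-area window must be positive and ordered")
        if self.replicates_per_area < 1:
            raise ValueError("at least one replicate unit per area is required")
        if self.units_per_area < self.replicates_per_area:
            raise ValueError("cannot select more replicate units than surveyed units")
        if self.lateral_step_m >= self.unit_length_m:
            raise ValueError("lateral step must be smaller than the unit length")

    def footprint(self, altitude_m):
        """Image footprint (m^2): area scales with the square of altitude."""
        return self.footprint_at_target_m2 * (np.asarray(altitude_m) / self.target_altitude_m) ** 2
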