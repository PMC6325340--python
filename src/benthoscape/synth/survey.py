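"""Zig-zag AUV photo-transect simulation and sampling-unit standardization.

A survey of an area is a sequence of straight-line sampling units (the zig
and zag sections).  Images are placed at a fixed along-track spacing, tagged
with altitude-dependent footprints, local nodule cover, and Poisson specimen
counts from the community model.  Standardization mirrors the treatment of
the real imagery: junction images and every second image discarded, the 2-4 m
altitude filter applied, the remainder randomly subsampled until the summed
footprint first enters the 1321-1324 m^2 window, and a fixed number of
replicate units randomly selected per area.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .community import Community
from .specs import SurveySpec, as_rng

__all__ = ["Survey", "simulate_survey", "standardize_units"]

IMAGE_COLUMNS = ["image_id", "area", "unit", "seq", "x", "y", "altitude_m",
                 "footprint_m2", "cover", "hard_substrata", "is_junction"]


@dataclass
class Survey:
    """Image, specimen and nodule data of one simulated survey."""

    spec: SurveySpec
    images: pd.DataFrame
    specimens: pd.DataFrame
    community: Community
    nodule_fields: dict = field(default_factory=dict)
    nodule_entropy: int = 0

    def unit_ids(self) -> list[str]:
        return list(dict.fromkeys(self.images["unit"]))

    def subset(self, image_ids) -> "Survey":
        ids = pd.Index(image_ids)
        return Survey(
            spec=self.spec,
            images=self.images[self.images["image_id"].isin(ids)].reset_index(drop=True),
            specimens=self.specimens[self.specimens["image_id"].isin(ids)].reset_index(drop=True),
            community=self.community,
            nodule_fields=self.nodule_fields,
            nodule_entropy=self.nodule_entropy,
        )

    def specimens_with_meta(self) -> pd.DataFrame:
        """Specimen table joined with morphospecies metadata and image info."""
        meta = self.community.species[["msp", "group", "guild", "habit", "is_xeno"]]
        out = self.specimens.merge(meta, left_on="msp_idx", right_index=True, how="left")
        return out.merge(self.images[["image_id", "area", "unit", "footprint_m2"]],
                         on="image_id", how="left")

    def sample_nodule_areas(self, image_ids=None) -> pd.DataFrame:
        """Materialize per-nodule areas (cm^2) for the given images.

        Draws are seeded per image id, so any subset of images yields the
        same nodules for a given survey.
        """
        imgs = self.images if image_ids is None else \
            self.images[self.images["image_id"].isin(pd.Index(image_ids))]
        out_ids, out_areas = [], []
        for row in imgs.itertuples(index=False):
            fld = self.nodule_fields.get(row.area)
            if fld is None:
                continue
            rng = np.random.default_rng(
                np.random.SeedSequence([self.nodule_entropy, int(row.image_id)]))
            areas = fld.sample_image_nodules(row.footprint_m2, row.cover, rng)
            out_ids.append(np.full(areas.size, row.image_id, dtype=np.int64))
            out_areas.append(areas)
        if not out_ids:
            return pd.DataFrame({"image_id": np.empty(0, dtype=np.int64),
                                 "area_cm2": np.empty(0)})
        return pd.DataFrame({"image_id": np.concatenate(out_ids),
                             "area_cm2": np.concatenate(out_areas)})

    def unit_table(self) -> pd.DataFrame:
        """Per-unit summary: area, image count, summed footprint."""
        g = self.images.groupby("unit", sort=False)
        return pd.DataFrame({
            "area": g["area"].first(),
            "n_images": g.size(),
            "area_m2": g["footprint_m2"].sum(),
        }).reset_index()


def _sample_altitudes(spec: SurveySpec, n: int, rng) -> np.ndarray:
    if spec.altitude_sd_m <= 0:
        return np.full(n, spec.target_altitude_m)
    lo, hi = spec.altitude_trunc_m
    a = (lo - spec.target_altitude_m) / spec.altitude_sd_m
    b = (hi - spec.target_altitude_m) / spec.altitude_sd_m
    return stats.truncnorm.rvs(a, b, loc=spec.target_altitude_m,
                               scale=spec.altitude_sd_m, size=n, random_state=rng)


def simulate_survey(areas: dict, spec: SurveySpec, community: Community,
                    nodule_fields: dict | None = None, seed=None) -> Survey:
    """Simulate zig-zag photo surveys over the given area rectangles.

    Parameters
    ----------
    areas
        Mapping of area name -> (x0, y0, x1, y1) rectangle in metres; each
        name must be an area of the community model.
    nodule_fields
        Mapping of area name -> :class:`NoduleField` (or None for nodule-free).

    Raises
    ------
    ValueError
        If an area rectangle is too small for the requested track.
    """
    rng = as_rng(seed)
    nodule_fields = nodule_fields or {}
    nodule_entropy = int(rng.integers(2**31))
    L, s = spec.unit_length_m, spec.lateral_step_m
    span_y = float(np.sqrt(L**2 - s**2))
    n_img_unit = int(L / spec.image_spacing_m)
    if n_img_unit < 1:
        raise ValueError("unit shorter than one image spacing")

    img_frames, spec_frames = [], []
    next_id = 0
    for area in areas:
        if area not in community.areas:
            raise ValueError(f"area {area!r} unknown to the community model")
        x0, y0, x1, y1 = map(float, areas[area])
        width, height = x1 - x0, y1 - y0
        x_extent = spec.units_per_area * s
        if x_extent > width or span_y > height:
            raise ValueError(
                f"area {area!r} ({width:.0f} x {height:.0f} m) too small for "
                f"{spec.units_per_area} units of {L:.0f} m (needs "
                f"{x_extent:.0f} x {span_y:.0f} m)")
        xs = x0 + rng.uniform(0, width - x_extent)
        ylo = y0 + rng.uniform(0, height - span_y)
        going_up = bool(rng.integers(2))

        t = (np.arange(n_img_unit) + 0.5) * spec.image_spacing_m
        frac = t / L
        junction = (t <= spec.junction_trim_m) | (t >= L - spec.junction_trim_m)

        rows = []
        for k in range(spec.units_per_area):
            xa, xb = xs + k * s, xs + (k + 1) * s
            ya, yb = (ylo, ylo + span_y) if going_up else (ylo + span_y, ylo)
            going_up = not going_up
            ids = next_id + np.arange(n_img_unit, dtype=np.int64)
            next_id += n_img_unit
            rows.append(pd.DataFrame({
                "image_id": ids,
                "area": area,
                "unit": f"{area}-U{k + 1:02d}",
                "seq": np.arange(n_img_unit),
                "x": xa + frac * (xb - xa),
                "y": ya + frac * (yb - ya),
                "is_junction": junction,
            }))
        adf = pd.concat(rows, ignore_index=True)
        adf["altitude_m"] = _sample_altitudes(spec, len(adf), rng)
        adf["footprint_m2"] = spec.footprint(adf["altitude_m"].to_numpy())
        fld = nodule_fields.get(area)
        if fld is not None:
            adf["cover"] = fld.cover_at(adf["x"].to_numpy(), adf["y"].to_numpy())
            mean_cover = fld.mean_fraction
        else:
            adf["cover"] = 0.0
            mean_cover = None
        hs_rate = fld.spec.hard_substrata_per_ha if fld is not None else 0.0
        adf["hard_substrata"] = rng.poisson(
            hs_rate * adf["footprint_m2"].to_numpy() / 1e4)
        counts = community.sample_image_counts(
            area, adf["footprint_m2"].to_numpy(), rng,
            covers=adf["cover"].to_numpy(), mean_cover=mean_cover)
        spec_frames.append(community.sample_specimens(
            counts, adf["image_id"].to_numpy(), rng))
        img_frames.append(adf[IMAGE_COLUMNS])

    images = pd.concat(img_frames, ignore_index=True)
    specimens = pd.concat(spec_frames, ignore_index=True) if spec_frames else pd.DataFrame()
    return Survey(spec=spec, images=images, specimens=specimens, community=community,
                  nodule_fields=nodule_fields, nodule_entropy=nodule_entropy)


def _subsample_to_window(fp: np.ndarray, window, rng, max_retries: int):
    """Random permutation + cumulative-sum cutoff at first entry into window.

    Returns indices of the chosen images, or None if the window cannot be hit
    (total area too small, or every permutation jumps the window).
    """
    lo, hi = window
    if fp.sum() < lo:
        return None
    for _ in range(max_retries):
        perm = rng.permutation(fp.size)
        cs = np.cumsum(fp[perm])
        hits = np.flatnonzero((cs >= lo) & (cs <= hi))
        if hits.size:
            return perm[: hits[0] + 1]
    return None


def standardize_units(survey: Survey, seed, max_retries: int = 200):
    """Apply the image discards, altitude filter, area standardization and
    replicate-unit selection; returns (standardized survey, unit summary).

    The unit summary has one row per surveyed unit with the retained image
    count, standardized area, and whether the unit was selected as a
    replicate.  Units that cannot reach the standardized-area window are
    flagged ``excluded`` with a warning.
    """
    rng = as_rng(seed)
    spec = survey.spec
    lo_alt, hi_alt = spec.altitude_window_m
    rows = []
    kept_ids: dict[str, np.ndarray] = {}
    for unit, df in survey.images.groupby("unit", sort=False):
        df = df.sort_values("seq")
        df = df[~df["is_junction"]]
        if spec.discard_every_second:
            df = df.iloc[::2]
        df = df[(df["altitude_m"] >= lo_alt) & (df["altitude_m"] <= hi_alt)]
        fp = df["footprint_m2"].to_numpy()
        chosen = _subsample_to_window(fp, spec.standard_area_window_m2, rng, max_retries) \
            if fp.size else None
        area = survey.images.loc[survey.images["unit"] == unit, "area"].iloc[0]
        if chosen is None:
            warnings.warn(f"unit {unit} cannot reach the standardized-area window; excluded")
            rows.append({"unit": unit, "area": area, "n_images": 0,
                         "std_area_m2": np.nan, "excluded": True, "selected": False})
            continue
        ids = df["image_id"].to_numpy()[chosen]
        kept_ids[unit] = ids
        rows.append({"unit": unit, "area": area, "n_images": ids.size,
                     "std_area_m2": float(fp[chosen].sum()),
                     "excluded": False, "selected": False})
    units = pd.DataFrame(rows)

    selected_ids = []
    for area, adf in units[~units["excluded"]].groupby("area", sort=False):
        k = spec.replicates_per_area
        if len(adf) < k:
            raise ValueError(f"area {area!r}: only {len(adf)} usable units, need {k}")
        pick = rng.choice(adf.index.to_numpy(), size=k, replace=False)
        units.loc[pick, "selected"] = True
        for unit in units.loc[pick, "unit"]:
            selected_ids.append(kept_ids[unit])

    all_ids = np.concatenate(selected_ids) if selected_ids else np.empty(0, dtype=np.int64)
    return survey.subset(all_ids), units
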