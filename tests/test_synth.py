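"""Generator contracts: bathymetry, nodule fields, communities, surveys."""

import numpy as np
import pandas as pd
import pytest

from benthoscape import reference
from benthoscape.grids import BathyGrid, read_ascii_grid, write_ascii_grid
from benthoscape.synth import (BathymetrySpec, Community, CommunitySpec, NoduleField,
                               NoduleFieldSpec, Survey, SurveySpec,
                               generate_bathymetry, standardize_units)

from conftest import make_survey


class TestBathymetry:
    def test_degenerate_flat_grid(self):
        spec = BathymetrySpec(relief_amplitude_m=0.0, noise_sd_m=0.0,
                              phase_jitter_rad=0.0)
        grid = generate_bathymetry(spec, 0)
        assert np.allclose(grid.depths, spec.base_depth_m)

    def test_dominant_period_matches_ridge_spacing(self):
        spec = BathymetrySpec(ridge_spacing_m=5000.0, cell_size_m=100.0,
                              noise_sd_m=2.0)
        grid = generate_bathymetry(spec, 1)
        profile = grid.depths.mean(axis=0)
        spectrum = np.abs(np.fft.rfft(profile - profile.mean()))
        k = int(np.argmax(spectrum[1:])) + 1
        period_cells = spec.ncols / k
        assert period_cells == pytest.approx(50.0, rel=0.15)

    def test_default_depths_within_study_range(self):
        grid = generate_bathymetry(BathymetrySpec(), 3)
        assert grid.depths.min() >= reference.DEPTH_RANGE_M[0]
        assert grid.depths.max() <= reference.DEPTH_RANGE_M[1]

    def test_aliasing_spacing_rejected(self):
        with pytest.raises(ValueError, match="alias"):
            BathymetrySpec(ridge_spacing_m=150.0, cell_size_m=100.0)

    def test_ascii_grid_roundtrip(self, tmp_path):
        grid = generate_bathymetry(BathymetrySpec(nrows=12, ncols=9), 4)
        path = tmp_path / "g.asc"
        write_ascii_grid(grid, path)
        back = read_ascii_grid(path)
        assert back.cell_size == grid.cell_size
        assert np.allclose(back.depths, grid.depths, atol=1e-3)


class TestNoduleField:
    def test_zero_cover_yields_no_nodules(self):
        fld = NoduleField(NoduleFieldSpec(mean_cover_pct=0.0), (0, 0, 100, 100), 0)
        assert np.all(fld.cover_at([5, 50], [5, 50]) == 0)
        assert fld.sample_image_nodules(1.71, 0.0, 0).size == 0

    def test_mean_cover_calibration(self):
        fld = NoduleField(NoduleFieldSpec(mean_cover_pct=10.1), (0, 0, 500, 500), 1)
        covers = fld.marginal_cover(10_000, 2)
        se = covers.std(ddof=1) / np.sqrt(covers.size)
        assert abs(100 * covers.mean() - 10.1) <= 3 * 100 * se

    def test_size_distribution_shape(self):
        fld = NoduleField(NoduleFieldSpec(), (0, 0, 100, 100), 0)
        # 90% of nodules below 5 cm^2, mean area ~2.5 cm^2
        assert fld.fraction_below(5.0) == pytest.approx(0.90, abs=0.01)
        assert fld.mean_nodule_area_cm2 == pytest.approx(
            reference.NODULE_MEAN_AREA_CM2, abs=0.05)
        areas = fld.sample_image_nodules(1.71, 0.10, 3)
        assert areas.min() > 0
        assert np.mean(areas < 5.0) == pytest.approx(0.90, abs=0.03)

    def test_cover_outside_range_rejected(self):
        with pytest.raises(ValueError):
            NoduleFieldSpec(mean_cover_pct=120.0)

    def test_field_is_patchy_at_tens_of_metres(self):
        fld = NoduleField(NoduleFieldSpec(mean_cover_pct=10.0, corr_length_m=50.0),
                          (0, 0, 1000, 1000), 5)
        x = np.linspace(0, 1000, 400)
        c = fld.cover_at(x, np.full_like(x, 500.0))
        near = np.corrcoef(c[:-4], c[4:])[0, 1]     # ~10 m apart
        far = np.corrcoef(c[:-200], c[200:])[0, 1]  # ~500 m apart
        assert near > 0.8
        assert abs(far) < 0.5


class TestCommunity:
    def test_zero_density_produces_no_individuals(self):
        spec = CommunitySpec(metazoan_density={"Flat": 0.0},
                             xenophyophore_density={"Flat": 0.0},
                             amonile_density={"Flat": 0.0})
        comm = Community(spec, 0)
        counts = comm.sample_image_counts("Flat", np.full(200, 1.71), 1)
        assert counts.sum() == 0

    def test_density_recovery_flat(self):
        comm = Community(CommunitySpec(), 1)
        n_img = 20_000
        fp = np.full(n_img, 1.71)
        counts = comm.sample_image_counts("Flat", fp, 2)
        met = counts[:, ~comm.species["is_xeno"].to_numpy()]
        per_image = met.sum(axis=1)
        dens = per_image.sum() / fp.sum()
        mc_se = per_image.std(ddof=1) * np.sqrt(n_img) / fp.sum()
        assert abs(dens - reference.METAZOAN_DENSITY["Flat"]) <= 3 * mc_se

    def test_expected_densities_exact_by_construction(self):
        comm = Community(CommunitySpec(), 3)
        for area in reference.AREAS:
            assert comm.total_density(area, include_xeno=False) == pytest.approx(
                reference.METAZOAN_DENSITY[area])
            assert comm.total_density(area) - comm.total_density(area, include_xeno=False) \
                == pytest.approx(reference.XENOPHYOPHORE_DENSITY[area])

    def test_rare_taxa_fraction_about_a_third(self):
        # fraction of observed metazoan morphospecies with <= 3 records over a
        # whole standardized survey (12 units x ~1320 m^2)
        fractions = []
        for seed in range(3):
            comm = Community(CommunitySpec(), seed)
            met = ~comm.species["is_xeno"].to_numpy()
            rng = np.random.default_rng(100 + seed)
            pooled = np.zeros(met.sum())
            for area in reference.AREAS:
                lam = comm.intensities(area)[met] * 4 * 1320.0
                pooled += rng.poisson(lam)
            observed = pooled[pooled > 0]
            fractions.append(np.mean(observed <= 3))
        assert np.mean(fractions) == pytest.approx(1 / 3, abs=0.1)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            CommunitySpec(n_morphospecies=0)

    def test_specimen_sizes_satisfy_length_width_order(self):
        comm = Community(CommunitySpec(), 4)
        counts = comm.sample_image_counts("Ridge", np.full(300, 1.71), 5)
        sp = comm.sample_specimens(counts, np.arange(300), 6)
        assert (sp["width_mm"] > 0).all()
        assert (sp["length_mm"] >= sp["width_mm"]).all()


class TestSurvey:
    def test_footprint_altitude_square_law(self, std_survey):
        img = std_survey.raw.images
        expect = 1.71 * (img["altitude_m"] / 3.0) ** 2
        assert np.allclose(img["footprint_m2"], expect)

    def test_requested_units_are_returned(self):
        spec = CommunitySpec(metazoan_density={a: 0.0 for a in reference.AREAS},
                             xenophyophore_density={a: 0.0 for a in reference.AREAS},
                             amonile_density={a: 0.0 for a in reference.AREAS})
        raw = make_survey(seed=9, units_per_area=40, community_spec=spec,
                          with_nodules=False)
        per_area = raw.images.groupby("area")["unit"].nunique()
        assert (per_area == 40).all()

    def test_zero_altitude_noise_gives_exact_footprint(self):
        sspec = SurveySpec(units_per_area=2, replicates_per_area=2, altitude_sd_m=0.0)
        raw = make_survey(seed=5, survey_spec=sspec, with_nodules=False)
        assert np.allclose(raw.images["footprint_m2"], 1.71)

    def test_determinism_identical_tables(self):
        a = make_survey(seed=11, units_per_area=2)
        b = make_survey(seed=11, units_per_area=2)
        pd.testing.assert_frame_equal(a.images, b.images)
        pd.testing.assert_frame_equal(a.specimens, b.specimens)
        pd.testing.assert_frame_equal(a.sample_nodule_areas(), b.sample_nodule_areas())

    def test_area_too_small_rejected(self):
        spec = CommunitySpec()
        comm = Community(spec, 0)
        from benthoscape.synth import simulate_survey
        with pytest.raises(ValueError, match="too small"):
            simulate_survey({"Flat": (0, 0, 200, 200)}, SurveySpec(), comm, {}, 0)


def _bare_survey(images: pd.DataFrame, spec: SurveySpec) -> Survey:
    empty = pd.DataFrame({"image_id": np.empty(0, dtype=np.int64)})
    return Survey(spec=spec, images=images, specimens=empty, community=None)


class TestStandardization:
    def test_every_second_discard_arithmetic(self):
        # 1546 equal-footprint images -> 773 retained -> 773 x 1.71 = 1321.83 m^2
        n = 1546
        img = pd.DataFrame({
            "image_id": np.arange(n, dtype=np.int64), "area": "Flat", "unit": "Flat-U01",
            "seq": np.arange(n), "x": 0.0, "y": 0.0, "altitude_m": 3.0,
            "footprint_m2": 1.71, "cover": 0.0, "hard_substrata": 0,
            "is_junction": False,
        })
        spec = SurveySpec(units_per_area=1, replicates_per_area=1)
        std, units = standardize_units(_bare_survey(img, spec), 0)
        assert units.loc[0, "n_images"] == 773
        assert units.loc[0, "std_area_m2"] == pytest.approx(773 * 1.71)
        assert 1321.0 <= units.loc[0, "std_area_m2"] <= 1324.0

    def test_all_images_too_high_unit_excluded(self):
        n = 2000
        base = dict(x=0.0, y=0.0, footprint_m2=1.71, cover=0.0, hard_substrata=0,
                    is_junction=False)
        bad = pd.DataFrame({"image_id": np.arange(n, dtype=np.int64), "area": "Flat",
                            "unit": "Flat-U01", "seq": np.arange(n),
                            "altitude_m": 5.0, **base})
        good = pd.DataFrame({"image_id": np.arange(n, 3 * n, dtype=np.int64),
                             "area": "Flat", "unit": "Flat-U02",
                             "seq": np.arange(2 * n), "altitude_m": 3.0, **base})
        spec = SurveySpec(units_per_area=2, replicates_per_area=1)
        with pytest.warns(UserWarning, match="excluded"):
            std, units = standardize_units(
                _bare_survey(pd.concat([bad, good], ignore_index=True), spec), 0)
        assert bool(units.loc[units["unit"] == "Flat-U01", "excluded"].iloc[0])
        assert bool(units.loc[units["unit"] == "Flat-U02", "selected"].iloc[0])

    def test_standardized_areas_and_retained_counts(self, std_survey):
        sel = std_survey.units[std_survey.units["selected"]]
        assert len(sel) == 12  # 3 areas x 4 replicate units
        assert ((sel["std_area_m2"] >= 1321.0) & (sel["std_area_m2"] <= 1324.0)).all()
        # retained photographs per unit in the hundreds
        assert sel["n_images"].between(400, 900).all()

    def test_junction_images_never_selected(self, std_survey):
        assert not std_survey.std.images["is_junction"].any()

    def test_selection_deterministic_under_seed(self, std_survey):
        std2, units2 = standardize_units(std_survey.raw, np.random.default_rng(7))
        pd.testing.assert_frame_equal(std_survey.units, units2)
        pd.testing.assert_frame_equal(std_survey.std.images, std2.images)
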