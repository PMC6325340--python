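"""Density, biovolume, Hill numbers, K-dominance, rarefaction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from benthoscape.diversity import (AbundanceTable, biomass_density, biovolume, chao2,
                                   hill_numbers, k_dominance, rarefy_diversity,
                                   rarefy_richness)

from _oracles import (expected_diversity_by_multinomial,
                      individual_rarefaction_by_enumeration,
                      rarefaction_by_enumeration)


class TestDensity:
    def test_density_is_count_over_area(self, toy_table):
        d = toy_table.unit_density()
        assert d["u0"] == pytest.approx(11.0)  # area 1.0

    def test_study_scale_division(self):
        # 647 specimens over 1320 m^2
        assert 647 / 1320.0 == pytest.approx(0.4901, abs=1e-4)

    def test_guild_split_arithmetic(self):
        counts = pd.DataFrame([[390, 80, 20]], index=["u"], columns=["a", "b", "c"])
        meta = pd.DataFrame({"guild": ["SF", "DF", "PS"]}, index=["a", "b", "c"])
        t = AbundanceTable(counts=counts, unit_areas=pd.Series({"u": 1000.0}),
                           groups=pd.Series({"u": "Flat"}), species_meta=meta)
        g = t.density_by("guild").loc["u"]
        assert g["SF"] == pytest.approx(0.39)
        assert g["DF"] == pytest.approx(0.08)
        assert g["PS"] == pytest.approx(0.02)

    def test_zero_area_rejected(self, toy_table):
        with pytest.raises(ValueError):
            AbundanceTable(counts=toy_table.counts,
                           unit_areas=pd.Series(0.0, index=toy_table.counts.index),
                           groups=toy_table.groups)


class TestBiovolume:
    def test_sphere_limit(self):
        d = 10.0
        assert biovolume(d, d) == pytest.approx(np.pi * d**3 / 6 / 1000)

    def test_worked_example(self):
        # L 100 mm, W 10 mm -> (pi/6) * 100 * 100 mm^3 = 5.236 ml
        assert biovolume(100.0, 10.0) == pytest.approx(5.23599, abs=1e-4)

    def test_width_doubling_quadruples_volume(self):
        assert biovolume(50.0, 20.0) == pytest.approx(4 * biovolume(50.0, 10.0))

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError):
            biovolume(5.0, 10.0)
        with pytest.raises(ValueError):
            biovolume(5.0, 0.0)

    def test_biomass_density_order_invariant_and_additive(self):
        rng = np.random.default_rng(0)
        L = rng.uniform(10, 80, 40)
        W = L * rng.uniform(0.2, 0.9, 40)
        sp = pd.DataFrame({"unit": ["u"] * 40, "length_mm": L, "width_mm": W})
        areas = pd.Series({"u": 100.0})
        b1 = biomass_density(sp, areas)["u"]
        b2 = biomass_density(sp.sample(frac=1, random_state=1), areas)["u"]
        assert b1 == pytest.approx(b2)
        half = biomass_density(sp.iloc[:20], areas)["u"] + \
            biomass_density(sp.iloc[20:], areas)["u"]
        assert half == pytest.approx(b1)


class TestHillNumbers:
    def test_uniform_community_all_equal(self):
        h = hill_numbers([5, 5, 5, 5])
        assert h.richness == h.exp_shannon == pytest.approx(4.0)
        assert h.inv_simpson == pytest.approx(4.0)

    def test_worked_example_1_2_3(self):
        h = hill_numbers([1, 2, 3])
        assert h.richness == 3
        # direct summation: exp(ln6/6 + ln3/3 + ln2/2) = 2.74946
        assert h.exp_shannon == pytest.approx(2.74946, abs=1e-4)
        assert h.inv_simpson == pytest.approx(2.5714, abs=1e-4)

    def test_single_species(self):
        assert hill_numbers([7]) == (1.0, pytest.approx(1.0), pytest.approx(1.0))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            hill_numbers([0, 0])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=0, max_value=500), min_size=1, max_size=40)
           .filter(lambda v: sum(v) > 0))
    def test_hill_ordering(self, counts):
        h = hill_numbers(counts)
        assert h.richness >= h.exp_shannon - 1e-9
        assert h.exp_shannon >= h.inv_simpson - 1e-9
        assert h.inv_simpson >= 1.0 - 1e-9


class TestKDominance:
    def test_single_species_flat_at_100(self, ):
        t = AbundanceTable(counts=pd.DataFrame([[5]], index=["u"], columns=["a"]),
                           unit_areas=pd.Series({"u": 1.0}),
                           groups=pd.Series({"u": "G"}))
        curve = k_dominance(t)
        assert curve["cum_pct"].tolist() == [pytest.approx(100.0)]

    def test_three_one_split(self):
        t = AbundanceTable(counts=pd.DataFrame([[3, 1]], index=["u"],
                                               columns=["a", "b"]),
                           unit_areas=pd.Series({"u": 1.0}),
                           groups=pd.Series({"u": "G"}))
        curve = k_dominance(t)
        assert curve["cum_pct"].tolist() == [pytest.approx(75.0), pytest.approx(100.0)]

    def test_identical_replicates_zero_ci_width(self):
        counts = pd.DataFrame([[4, 2, 1]] * 2, index=["u1", "u2"],
                              columns=["a", "b", "c"])
        t = AbundanceTable(counts=counts, unit_areas=pd.Series(1.0, index=counts.index),
                           groups=pd.Series("G", index=counts.index))
        curve = k_dominance(t)
        assert np.allclose(curve["hi"] - curve["lo"], 0.0)

    def test_monotone_and_ends_at_100(self, abundance):
        for area in ("Flat", "Ridge", "Trough"):
            curve = k_dominance(abundance, group=area)
            assert (np.diff(curve["cum_pct"]) >= -1e-9).all()
            assert curve["cum_pct"].iloc[-1] == pytest.approx(100.0)


class TestRarefaction:
    def test_endpoint_identity(self):
        rng = np.random.default_rng(0)
        inc = (rng.random((4, 12)) < 0.4).astype(int)
        freqs = inc.sum(axis=0)
        curve = rarefy_richness(freqs, 4, mode="sample")
        s_obs = (freqs > 0).sum()
        assert curve.data.loc[curve.data["effort"] == 4, "expected"].iloc[0] == \
            pytest.approx(s_obs)

    def test_individual_mode_single_draw(self):
        curve = rarefy_richness([10, 5, 1], 16, effort=[1], mode="individual")
        assert curve.data["expected"].iloc[0] == pytest.approx(1.0)

    def test_sample_mode_matches_subset_enumeration(self):
        rng = np.random.default_rng(1)
        inc = (rng.random((5, 10)) < 0.5).astype(int)
        freqs = inc.sum(axis=0)
        freqs_pos = freqs  # species never seen contribute nothing
        curve = rarefy_richness(freqs_pos, 5, mode="sample")
        for t in range(1, 6):
            oracle = rarefaction_by_enumeration(inc, t)
            ours = curve.data.loc[curve.data["effort"] == t, "expected"].iloc[0]
            assert ours == pytest.approx(oracle, abs=1e-9)

    def test_individual_mode_matches_enumeration(self):
        counts = np.array([6, 3, 2, 1])
        curve = rarefy_richness(counts, counts.sum(), effort=[1, 4, 7, 12],
                                mode="individual")
        for _, row in curve.data.iterrows():
            oracle = individual_rarefaction_by_enumeration(counts, int(row["effort"]))
            assert row["expected"] == pytest.approx(oracle, abs=1e-9)

    def test_monotone_including_extrapolation(self):
        rng = np.random.default_rng(2)
        inc = (rng.random((6, 30)) < 0.3).astype(int)
        freqs = inc.sum(axis=0)
        curve = rarefy_richness(freqs, 6, effort=np.arange(1, 21), mode="sample")
        e = curve.data["expected"].to_numpy()
        assert (np.diff(e) >= -1e-9).all()
        assert curve.data["extrapolated"].sum() == 14
        assert curve.meta["beyond_3x"]  # flagged when pushed past 3x effort
        assert curve.asymptote >= curve.observed

    def test_extrapolation_asymptote_is_chao2(self):
        freqs = np.array([1, 1, 2, 3, 4])
        assert chao2(freqs, 5) == pytest.approx(5 + (4 / 5) * 4 / 2)

    def test_zero_effort_rejected(self):
        with pytest.raises(ValueError):
            rarefy_richness([1, 2], 3, effort=[0], mode="sample")


class TestDiversityBootstrap:
    def test_toy_counts_match_exact_multinomial_expectation(self):
        counts = pd.DataFrame([[5, 3, 2]], index=["u"], columns=["a", "b", "c"])
        t = AbundanceTable(counts=counts, unit_areas=pd.Series({"u": 1.0}),
                           groups=pd.Series({"u": "G"}))
        out = rarefy_diversity(t, effort=[4], mode="individual", reps=20_000, seed=0)
        exact = expected_diversity_by_multinomial(np.array([5, 3, 2]), 4)
        assert out["exp_shannon"].iloc[0] == pytest.approx(exact["exp_shannon"], abs=0.02)
        assert out["inv_simpson"].iloc[0] == pytest.approx(exact["inv_simpson"], abs=0.02)

    def test_full_sample_consistency(self, toy_table):
        pooled = hill_numbers(toy_table.pooled_counts())
        out = rarefy_diversity(toy_table, effort=[len(toy_table.counts)],
                               mode="sample", reps=400, seed=1)
        # resampling whole units with replacement is unbiased around the
        # pooled value only approximately; consistency within a broad band
        assert out["exp_shannon"].iloc[0] == pytest.approx(pooled.exp_shannon, rel=0.25)

    def test_uniform_two_species_approaches_two(self):
        counts = pd.DataFrame([[500, 500]], index=["u"], columns=["a", "b"])
        t = AbundanceTable(counts=counts, unit_areas=pd.Series({"u": 1.0}),
                           groups=pd.Series({"u": "G"}))
        out = rarefy_diversity(t, effort=[600], mode="individual", reps=300, seed=2)
        assert out["exp_shannon"].iloc[0] == pytest.approx(2.0, abs=0.02)

    def test_zero_effort_rejected(self, toy_table):
        with pytest.raises(ValueError):
            rarefy_diversity(toy_table, effort=[0], mode="sample", reps=10, seed=0)
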