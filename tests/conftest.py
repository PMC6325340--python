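from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

from benthoscape.diversity import AbundanceTable
from benthoscape.synth import (Community, CommunitySpec, NoduleField, NoduleFieldSpec,
                               SurveySpec, simulate_survey, standardize_units)
from benthoscape import reference

#: non-overlapping survey-area rectangles (m); survey geometry needs no bathymetry
AREA_RECTS = {
    "Flat": (0.0, 0.0, 1600.0, 2000.0),
    "Ridge": (2500.0, 0.0, 4100.0, 2000.0),
    "Trough": (5000.0, 0.0, 6600.0, 2000.0),
}


def make_survey(seed=42, units_per_area=4, community_spec=None, survey_spec=None,
                with_nodules=True):
    spec = survey_spec or SurveySpec(units_per_area=units_per_area,
                                     replicates_per_area=min(4, units_per_area))
    comm = Community(community_spec or CommunitySpec(), np.random.default_rng(seed))
    fields = {}
    if with_nodules:
        rng = np.random.default_rng(seed + 1)
        fields = {
            a: NoduleField(
                NoduleFieldSpec(mean_cover_pct=reference.NODULE_COVER_PCT[a],
                                hard_substrata_per_ha=reference.HARD_SUBSTRATA_PER_HA[a]),
                AREA_RECTS[a], rng)
            for a in AREA_RECTS
        }
    raw = simulate_survey(AREA_RECTS, spec, comm, fields, np.random.default_rng(seed + 2))
    return raw


@pytest.fixture(scope="session")
def std_survey():
    """Study-conditions survey (4 full-length units per area, all analysed)."""
    raw = make_survey(seed=42, units_per_area=4)
    std, units = standardize_units(raw, np.random.default_rng(7))
    return SimpleNamespace(raw=raw, std=std, units=units, community=raw.community)


@pytest.fixture(scope="session")
def abundance(std_survey) -> AbundanceTable:
    return AbundanceTable.from_survey(std_survey.std, include_xeno=False)


@pytest.fixture()
def toy_table() -> AbundanceTable:
    """Six units, two groups, five species; areas of 1.0 for easy arithmetic."""
    counts = pd.DataFrame(
        [[8, 2, 0, 1, 0],
         [6, 3, 1, 0, 0],
         [7, 1, 0, 2, 1],
         [1, 0, 9, 3, 0],
         [0, 1, 7, 4, 1],
         [2, 0, 8, 2, 0]],
        index=[f"u{i}" for i in range(6)],
        columns=list("abcde"),
    )
    groups = pd.Series(["G1"] * 3 + ["G2"] * 3, index=counts.index)
    areas = pd.Series(1.0, index=counts.index)
    return AbundanceTable(counts=counts, unit_areas=areas, groups=groups)
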