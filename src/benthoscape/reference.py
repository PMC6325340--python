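"""Reference values from the APEI6 (Clarion-Clipperton Zone) AUV megafauna survey.

These are the published field-survey quantities that the synthetic generators in
:mod:`benthoscape.synth` are calibrated to emulate: per-landscape-type faunal
densities, nodule statistics, survey geometry, and the terrain-classification
thresholds.  They are inputs to the simulation, not outputs of it.

Landscape types ("areas") are the three strata surveyed: ``Flat``, ``Ridge``
and ``Trough``.
"""

from __future__ import annotations

AREAS = ("Flat", "Ridge", "Trough")

# -- faunal standing stock (individuals m^-2, per landscape type) -------------
METAZOAN_DENSITY = {"Flat": 0.49, "Ridge": 0.47, "Trough": 0.32}
XENOPHYOPHORE_DENSITY = {"Flat": 2.22, "Ridge": 4.09, "Trough": 1.33}
#: density of the dominant xenophyophore, Aschemonella monile
AMONILE_DENSITY = {"Flat": 1.51, "Ridge": 3.27, "Trough": 0.85}

# -- community structure -------------------------------------------------------
METAZOAN_RICHNESS = 129          # morphospecies over the whole survey
XENOPHYOPHORE_RICHNESS = 23
RARE_TAXA_FRACTION = 1.0 / 3.0   # fraction of morphospecies with <= 3 records
GUILD_SHARES = {"SF": 0.78, "DF": 0.16, "PS": 0.06}   # by individuals
NODULE_ATTACHMENT_PROB = 0.8     # attached fraction among nodule-attached taxa

# -- nodule field ---------------------------------------------------------------
NODULE_COVER_PCT = {"Flat": 10.1, "Ridge": 6.3, "Trough": 3.8}
NODULE_MEAN_AREA_CM2 = 2.5
NODULE_FRACTION_BELOW_5CM2 = 0.90
NODULE_FILTER_CM2 = (0.5, 60.0)  # analysis size window
HARD_SUBSTRATA_PER_HA = {"Flat": 62.0, "Ridge": 682.0, "Trough": 64.0}

# -- survey geometry ------------------------------------------------------------
UNITS_PER_AREA = 40
REPLICATES_PER_AREA = 4
TARGET_ALTITUDE_M = 3.0
ALTITUDE_WINDOW_M = (2.0, 4.0)
FOOTPRINT_AT_TARGET_M2 = 1.71
STANDARD_UNIT_AREA_M2 = 1320.0
STANDARD_AREA_WINDOW_M2 = (1321.0, 1324.0)
TYPICAL_IMAGES_PER_UNIT = (555, 781)   # retained photographs per unit
TOTAL_ANALYSED_AREA_M2 = 15840.0       # 3 areas x 4 units x ~1320 m^2

# -- bathymetry and terrain classification --------------------------------------
DEPTH_RANGE_M = (3950.0, 4250.0)
RIDGE_SPACING_RANGE_M = (1000.0, 10000.0)
BPI_INNER_RADIUS_M = 500.0
BPI_OUTER_RADIUS_M = 10000.0
TRI_RADIUS_M = 500.0
#: classification boxes: class -> ((bpi_lo, bpi_hi), (tri_lo, tri_hi))
CLASS_BOXES = {
    "ridge": ((50.0, 100.0), (0.0, 150.0)),
    "trough": ((-100.0, -50.0), (0.0, 150.0)),
    "flat": ((-50.0, 50.0), (0.0, 50.0)),
}

# -- sediments (surface horizon, per landscape type) ----------------------------
SEDIMENT_TOC_PCT = {"Flat": 0.42, "Ridge": 0.41, "Trough": 0.44}
SEDIMENT_CN_MOLAR = {"Flat": 4.0, "Ridge": 3.8, "Trough": 4.1}
SEDIMENT_CACO3_PCT = {"Flat": 0.33, "Ridge": 0.48, "Trough": 0.36}
SEDIMENT_MUD_PCT = {"Flat": 92.6, "Ridge": 92.5, "Trough": 90.7}
SEDIMENT_MEAN_GRAIN_UM = {"Flat": 8.1, "Ridge": 9.5, "Trough": 9.2}

# -- sampling-effort evaluation -------------------------------------------------
AUTOSIMILARITY_AT_UNIT_SIZE_PCT = 70.0   # exceeded at the ~1320 m^2 unit size
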