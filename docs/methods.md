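# Methods

This note documents the models behind `benthoscape`: what each generator and
statistic assumes, the parameters that matter, the numerical choices, and
what passing tests do and do not demonstrate about real surveys.

## The system being emulated

The package emulates an AUV photo-transect survey of abyssal megafauna in a
polymetallic-nodule province (the APEI6 reserve of the Clarion-Clipperton
Zone is the calibration target; its survey values are collected in
`benthoscape.reference`). The seafloor there is a succession of north-south
ridges and troughs spaced 1–10 km apart at 3950–4250 m depth, with dispersed
level-bottom areas between. Three landscape strata — Flat, Ridge, Trough —
are surveyed with 40 straight-line zig-zag sampling units each, of which 4
are randomly selected and standardized to c. 1320 m² of analysed seabed.

## Synthetic generators

**Bathymetry.** Depth is a base level (4100 m) minus a cosine in easting
with period `ridge_spacing_m` (default 5000 m) and amplitude
`relief_amplitude_m` (default 75 m), a slowly drifting phase along northing
(sd 0.25 rad, smoothed at 500 m) to make the ridges quasi-periodic and
crenulated, plus smooth correlated noise (sd 5 m, correlation 500 m). The
75 m amplitude places crest/trough BPI near ±75 m, inside the ridge/trough
classification boxes (±50 to ±100 m), and keeps depths within the observed
3950–4250 m range. Spacing below two grid cells is rejected (aliasing).

**Nodule cover.** Per-area cover is `expit(μ + σ·Z(x, y))` with Z a
unit-variance Gaussian random field of correlation length 50 m ("patchiness
at tens of metres") and σ = 1 on the logit scale; μ is solved by
Gauss-Hermite quadrature so the *marginal* mean equals the area's target
cover (10.1 / 6.3 / 3.8 %). Nodule areas are lognormal with
(μ, σ) = (0.61547, 0.77552), the closed-form solution of two constraints:
mean area 2.5 cm² and 90 % of nodules below 5 cm². Per image, the nodule
count is Poisson with expectation (local cover × footprint)/(mean nodule
area). Because the realized field is standardized empirically, a finite
field's mean cover deviates from the target by a few percent at area scale;
calibration checks therefore use marginal (i.i.d.) cover draws.

**Community.** A shared pool of 129 metazoan morphospecies draws reference
abundances from a log-series with x = 0.99663. That value follows from the
survey's scale (S = 129, N ≈ 6740 ⇒ Fisher α ≈ 22.8) and automatically
reproduces the long tail: the expected fraction of taxa with ≤ 3 records is
(x + x²/2 + x³/3)/(−ln(1−x)) ≈ 0.32, i.e. the observed "third" — no
separate tuning. Per-area relative abundances are lognormal perturbations
of the pool (σ = 0.3, mean-one), scaled to the area's total density
(0.49 / 0.47 / 0.32 ind m⁻²). σ = 0.3 makes the whole-survey PERMANOVA
R² fall in 0.33–0.46 across seeds, bracketing the survey's 0.39. Guilds are
assigned per species with individual-weighted probabilities 0.78 / 0.16 /
0.06 (SF / DF / PS); the most abundant 30 % of taxa are nodule-attached
(NA), and NA individuals sit on nodules with probability 0.8. NA intensity
per image is modulated by `(1−q) + q·cover/E[cover]` (q = 0.8), which has
unit mean, so co-location with nodules never biases area densities.
Xenophyophores are a separate 23-species pool whose dominant species
("A. monile") has fixed per-area densities (1.51 / 3.27 / 0.85 ind m⁻²)
within area totals 2.22 / 4.09 / 1.33. Body sizes are lognormal: species
median length 30 mm (species-level σ = 0.8, individual σ = 0.3), width a
species-specific ratio of length (0.2–0.6), so length ≥ width > 0 always.

**Survey.** Units are straight segments of 1800 m flown at 3 m target
altitude (truncated-normal altitude, sd 0.4 m on [1.5, 4.5] m), images every
1.02 m (1.2 m s⁻¹ at 850 ms), each footprint exactly
`1.71·(altitude/3)² m²`. The 1800 m length gives each unit a comfortable
surplus over the standardization window after the discards below; the
standardized units then retain ~760 photographs, inside the observed
555–781 range. Standardization per unit: drop images within 10 m of a turn
(junctions), drop every second image (overlap), drop images outside 2–4 m
altitude, then randomly permute the rest and cut the cumulative footprint at
its first entry into [1321, 1324] m² (re-permuting if a draw jumps the 3 m²
window, possible because a 4 m-altitude footprint is 3.04 m²); finally 4
units per area are selected by simple random draw. Units that cannot reach
the window are excluded with a warning.

## Terrain

BPI(cell) = elevation − mean elevation of the annulus 500 m < r ≤ 10 000 m
(elevation = −depth, so positive BPI = local high); TRI = mean |Δelevation|
over a 500 m circular neighbourhood, centre excluded (an RMS variant is
available). Both are nodata-aware; edge cells use the available part of the
window; neighbourhood membership is by cell-centre distance. BPI is
reported in raw metres by default (the ±50/±100 thresholds are legible in
metres); a z-score×100 standardization flag exists because GIS practice
varies. Classification boxes are closed intervals — ridge (BPI 50–100, TRI
0–150), trough (BPI −100 to −50, TRI 0–150), flat (BPI −50 to 50, TRI
0–50) — with flat tested first so the |BPI| = 50 boundary is deterministic;
everything else is unclassified. Survey areas are auto-placed as the
rectangle maximizing each class's cell fraction.

## Environmental metrics

Nodules are filtered to the closed interval [0.5, 60] cm² before any cover
statistic. Image cover % = 100·Σareas/(footprint·10⁴); unit cover is the
unweighted mean over images (an area-weighted flag exists; the averaging
convention is genuinely ambiguous), unit total nodule area the exact sum.
"Nodule surface size" is the pooled mean over every retained nodule in a
unit (not a mean of per-image means). Grain statistics use the geometric
method of moments on class geometric midpoints; mud (< 63 µm) prorates the
straddling class linearly in ln-size. CaCO₃ % = (TC − TOC)·100.09/12.01
(all carbonate taken as calcite); molar C:N = (TOC/12.01)/(TN/14.007).

## Diversity and rarefaction

Hill numbers are computed directly from count vectors; biovolume is an
ellipsoid of revolution, V = (π/6)·L·W² (mm³ → ml, 1 ml ≈ 1 g fresh wet
weight), with a per-species shape-factor hook (default 1) — a two-parameter
solid is the only shape two body measurements can constrain. K-dominance
curves pad each unit at 100 % beyond its richness and average across units
with a normal-theory CI.

Sample-based rarefaction uses the hypergeometric expectation
`E[S(t)] = S_obs − Σ_i C(T−Y_i, t)/C(T, t)` (log-gamma arithmetic);
individual-based uses the analogous abundance form. Extrapolation follows
the Chao2 (sample) / Chao1 (individual) asymptote with the standard
exponential-approach form; extrapolation beyond 3× the observed effort is
flagged. The interpolation CI uses an asymptote-anchored unconditional
variance, `σ²(t) = Σ_i (1−α_it)² − S̃(t)²/Ŝ_Chao`, chosen because it
vanishes at t = 0, equals `S_obs(1 − S_obs/Ŝ)` at the full effort, and is
non-negative by Cauchy-Schwarz; extrapolated points carry the full-effort
variance (a known understatement — see limitations). exp H′ and 1/D curves
are bootstrapped with replacement (default 1000 replicates, percentile CI).
Area-based curves map sampling units to m² via the mean standardized unit
area (~1320 m²). Xenophyophores are excluded from metazoan metrics by
default; every relevant function takes an `include_xeno`/joint mode.

## Composition statistics

All from first principles, on `y = √(count/area)` (the transform applies to
densities, not raw counts). Bray-Curtis, with empty-pair nan flagging.
nMDS minimizes Kruskal stress-1 by alternating isotonic regression of
configuration distances on ranked dissimilarities (primary/weak ties: tie
blocks are pre-ordered by current distances) with Guttman-transform updates;
both half-steps decrease the raw stress, so the recorded trace is
non-increasing by construction. Default 50 restarts (one principal
coordinates start, the rest random), best kept. PERMANOVA uses
`SS_T = Σ_{i<j} d²/N`, within-group sums weighted 1/n_g, pseudo-F with
(a−1, N−a) degrees of freedom, and p = (1 + #{F_perm ≥ F_obs})/(1 + n_perm)
under free label permutation (one-way design); an exact mode enumerates all
distinct label arrangements for small N. Pairwise tests report raw and
Holm-adjusted p. SIMPER averages per-pair species contributions
`|y_ik−y_jk|/Σ_s(y_is+y_js)`, which sum exactly to the mean between-group
dissimilarity. Spearman uses mid-ranks with a two-sided permutation p
(appropriate at n = 4–12 units).

## Sampling-unit-size evaluation

Images are pooled per area and resampled into synthetic units of increasing
image count (geometric grid, default 16 sizes from 10 images to the pool).
Replacement policy per parameter: bootstrap (with replacement) for density,
biomass, exp H′ and 1/D; without replacement for richness and
autosimilarity. Centre statistic: median for biomass (its heavy tail makes
the mean erratic), mean otherwise. CV = sd/mean over the replicate
parameter values. Autosimilarity draws two disjoint groups per replicate
and reports 100·(1 − Bray-Curtis) on √densities. Stabilization is declared
at the smallest size from which the centre stays within ±5 % of the
terminal-size centre over a tail of at least 3 grid points — the underlying
field notion ("stabilization of the mean") is qualitative, so the criterion
is explicit, configurable, and reported with results. A curve still
drifting at the full pool is reported "not reached", which downstream
comparisons treat as "larger than any evaluated size" — richness on
long-tailed communities routinely ends this way, and that is the finding,
not a failure.

Under these conditions the package reproduces the survey's qualitative
findings: density is accurate almost immediately (tens of individuals) with
CV ∝ size^(−1/2); richness needs the largest units (still rising at ~2000
individuals per pool); autosimilarity at the ~1320 m² unit size is ~80 %,
comfortably above the 70 % benchmark.

## Pipeline, reproducibility, problem sizes

`run_all` spawns every stage's generator from one `SeedSequence(seed)`, so
identical configs give identical outputs; tables carry the config hash and
seed. Group comparisons of unit-level metrics are permutation one-way F
tests with Holm-adjusted pairwise mean-difference follow-ups — a single
uniform substitution for the family-specific regression fits (quasi-Poisson
/ beta / normal) such studies typically report, and labelled as a
substitution in all outputs. Default run sizes are the study's
(40 units/area surveyed, 4 analysed); resampling-heavy stages default to 200
replicates in the pipeline and acceptance script (1000 in the library
functions), which leaves all resampling distributions converged to well
inside the tolerances used anywhere in the package.

## What the generator does not emulate

Synthetic data supports verification (estimator correctness, calibration,
power-of-design questions), not biology. Not emulated: image overlap and
double counting (the every-second discard is applied to non-overlapping
synthetic images), detection error and mis-identification, morphospecies
taxonomy, within-area spatial gradients beyond nodule patchiness (faunal
placement is Poisson given the cover field, so there is no extra spatial
autocorrelation for the zig-zag design to defeat), currents/food supply as
mechanisms, nodule image segmentation (per-nodule areas are emitted
directly, mimicking a delineation algorithm's output contract), and
photo-realistic imagery. Passing tests therefore show the *analysis chain*
is correct and calibrated under known conditions — not that any particular
field inference is right.

## Known limitations

- Extrapolated rarefaction points reuse the observed-effort variance; their
  CIs are too narrow far beyond the data.
- The nMDS can in principle settle in local minima for pathological
  matrices; restarts mitigate but do not prove global optimality.
- Observed richness in a simulated survey (~110–125) is below the 129-species
  pool, as it must be for a log-series community at N ≈ 6700; Chao2 recovers
  the pool size to within a few species.
- The permutation group tests assume exchangeability across areas; with
  n = 4 units per group the attainable p-values are coarse.
- Hard-substrata counts are homogeneous Poisson per area; the real clustering
  of cobbles and bones on ridges is not modelled.
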