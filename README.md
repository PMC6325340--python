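# benthoscape

A virtual-ecologist toolkit for image-based surveys of abyssal nodule-province
megafauna.

Quantitative seafloor ecology in places like the Clarion-Clipperton Zone (CCZ)
rests on photo-transect surveys: an AUV flies straight-line sections a few
metres above the seabed, each photograph images ~1.7 m² of sediment and
polymetallic nodules, and every animal larger than ~10 mm is annotated to
morphospecies. From those annotations come the quantities that conservation
decisions use — densities, diversity, community composition — and all of them
depend on choices that are rarely examined: how the landscape is stratified,
how large a sampling unit must be, how many replicates are enough.

`benthoscape` packages that whole chain as testable code. It simulates
horst-and-graben bathymetry, patchy nodule-cover fields, long-tailed
megafauna communities and zig-zag AUV surveys with realistic standardization
steps, then analyses the simulated data with the field's standard machinery,
all implemented from first principles and checked against brute-force
oracles. It is aimed at benthic ecologists planning or reviewing image-based
surveys, and at anyone who wants the statistical core of such studies —
PERMANOVA, SIMPER, rarefaction, autosimilarity — as plain, tested Python.

## What is inside

| module | contents |
| --- | --- |
| `benthoscape.synth` | generators: bathymetry, nodule fields (logit-Gaussian cover, lognormal sizes), log-series communities, zig-zag surveys, unit standardization |
| `benthoscape.terrain` | bathymetric position index (BPI), terrain ruggedness index (TRI), flat/ridge/trough classification |
| `benthoscape.envmetrics` | nodule % cover and size filtering, grain-size geometric moments, CaCO₃ and molar C:N |
| `benthoscape.diversity` | densities, ellipsoid biovolume biomass proxy, Hill numbers (S, exp H′, 1/D), K-dominance, rarefaction/extrapolation |
| `benthoscape.multivar` | Bray-Curtis on √densities, nMDS (Kruskal stress-1, isotonic regression), PERMANOVA + pairwise, SIMPER, Spearman |
| `benthoscape.effort` | bootstrap sampling-unit-size curves (accuracy, CV, CI), Bray-Curtis autosimilarity, stabilization detection |
| `benthoscape.pipeline` | `RunConfig` / `run_all`: one seeded, reproducible end-to-end run with CSV/ASCII-grid outputs |

The core statistics, in the field's notation: Hill numbers
`S = #{i : n_i > 0}`, `exp H′ = exp(−Σ p_i ln p_i)`, `1/D = 1/Σ p_i²`;
Bray-Curtis `d_ij = Σ_k |y_ik − y_jk| / Σ_k (y_ik + y_jk)` with
`y_ik = √(n_ik / A_i)`; PERMANOVA pseudo-F
`F = (SS_A/(a−1)) / (SS_W/(N−a))` with a permutation p-value; sample-based
rarefaction `E[S(t)] = S_obs − Σ_i C(T−Y_i, t)/C(T, t)` with Chao-type
extrapolation.

## Worked example

```python
from benthoscape.pipeline import RunConfig, run_all

res = run_all(RunConfig(seed=1))
print(res.composition_test.summary())
print(res.table.unit_density().groupby(res.table.groups).mean().round(3))
```

prints

```
PERMANOVA: pseudo-F = 2.206, R2 = 0.329, p = 0.002 (sampled, 999 permutations)
group_a group_b  pseudo_f       r2     p  p_adj
   Flat   Ridge  1.582796 0.208735 0.100  0.100
   Flat  Trough  2.358401 0.282159 0.030  0.072
  Ridge  Trough  2.577678 0.300510 0.024  0.072

area
Flat      0.429
Ridge     0.477
Trough    0.345
```

Reading this: the simulated survey (three landscape types, four standardized
~1320 m² photo-transect units each) detects a significant difference in
megafauna composition between landscape types (R² = 0.33 of the multivariate
variation, p = 0.002), driven mostly by the trough differing from the flat
and ridge — with mean metazoan densities of 0.43, 0.48 and 0.35 ind m⁻²
respectively. The `RunResult` also carries the per-area summary table,
rarefaction and K-dominance curves, nMDS coordinates, SIMPER decompositions,
and the sampling-unit-size curves; `res.save("out/")` writes everything as
CSV and ESRI ASCII grids.

The same run is available from a shell:

```bash
benthoscape run --seed 1 --outdir out/
```

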