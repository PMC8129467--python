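# phylospat

Spatial–phylogenetic analysis of diversity and endemism for occurrence-based
biogeography, built around the question of why alpine plant radiations (the
motivating system is a *Saussurea*-like genus centred on a high plateau)
concentrate their species richness and endemism where they do: on recent
orogeny, in topographically heterogeneous terrain, and in regions whose
climate stayed comparatively stable through glacial–interglacial cycles.

The package is aimed at macroecologists and phylogenetic comparative
biologists who have (a) cleaned or raw occurrence records, (b) modern and
Last Glacial Maximum (LGM) climate rasters, and (c) a dated phylogeny, and
who want the full chain — gridding, diversity metrics, climate-stability
predictors, phylogenetic signal, ancestral niches, spatially corrected
regression and correlation, variance partitioning — as tested, scriptable
functions. A synthetic world generator with known ground truth makes the
entire chain testable without any external data.

## What it computes

**Grid diversity.** Species richness `SR` and weighted endemism
`WE = Σ_s 1/R_s` per grid cell (sum over the species present; `R_s` = number
of cells species *s* occupies). Summed over all cells WE equals the species
count exactly — a conservation identity the tests exploit.

**Predictors.** Per cell: mean altitude `Alt`, altitude standard deviation
`Alt_SD`, modern `MAT`/`MAP`, LGM anomalies `MAT_ano`/`MAP_ano`
(modern − mean of two paleoclimate model layers), and climate-change
velocity `Vel = (|MAT_ano|/21000 yr) / max(‖∇MAT‖, ε)` in m/yr.

**Phylogenetic comparative layer.** Blomberg's
`K = (MSE0/MSE) / E_BM[MSE0/MSE]` with a tip-permutation test (K ≈ 1 under
Brownian motion, ≈ 0 without signal); ancestral character estimation by
independent contrasts (PIC) and by REML (BM rate σ² maximizing the
restricted likelihood, node states by GLS conditional expectation).

**Spatial regression.** SAR error models `y = Xβ + u, u = λWu + ε` fitted by
profile maximum likelihood with eigenvalue log-determinants; all-subsets AIC
model averaging (Akaike weights, per-predictor summed support `w`,
full-model-averaged `Coef_ave`, Nagelkerke pseudo-R²); Dutilleul's modified
t-test, which refers a Pearson correlation to an effective sample size
`M̂ = 1 + tr(BΣ̂x)tr(BΣ̂y)/tr(BΣ̂x BΣ̂y)` estimated from both variables'
spatial autocorrelation.

**Variance partitioning.** Three-group partial regression (geology / modern
climate / climate stability) decomposing R² into unique, pairwise-shared and
three-way-shared fractions by inclusion–exclusion.

## Worked example

```sh
phylospat run-all --seed 0 --outdir demo_run
```

runs the whole chain on the default synthetic world (a 60°×60° region with
a rough high plateau, 60 species with Brownian altitude niches, ~7500
records, 5% deliberately corrupt). Typical log:

```
stage simulate  done (n_records=7560, n_species=60)
stage clean     done (n_in=7560, n_retained=7139)
stage diversity done (n_cells=696, n_species=60)
stage phylo     done (root_pic=4142.8, root_reml=4142.8)
stage sar       done (n_models=8, n_cells=696)
stage varpart   done (n_fractions=16)
```

The 421 dropped records are the 360 seeded corrupt rows plus a handful of
robust-outlier flags. PIC and REML agree on the ancestral altitude (4142.8 m
for this seed, a high-elevation origin). `phylo_signal.csv` reports
K(Alt) = 0.53 at p = 0.001 — significant phylogenetic signal in the altitude
niche, in the moderate-conservatism band 0.5 < K < 1. `sar_models.csv` is
shaped like a standard model-averaging table; for richness in predictor
group (a) it shows `Alt_SD +0.187***` and `MAT_ano −0.612***`,
`Vel −0.086*` (standardized model-averaged coefficients): richness rises
with topographic heterogeneity and falls where glacial–interglacial change
was large or fast. `varpart.csv` shows geology with the largest unique
fraction (0.28 vs 0.25 for stability and 0.004 for modern climate), and
`modified_ttest.csv` gives ρ = 0.90 between trait-group and total richness
with the effective sample size shrunk from 313 cells to M̂ ≈ 155.

Every stage is also available as a separate subcommand (`simulate`, `clean`,
`grid`, `diversity`, `env`, `signal`, `ace`, `sar`, `ttest`, `varpart`) and
as plain library functions (`phylospat.clean_records`,
`phylospat.fit_sar_error`, ...), all reading and writing CSV / ESRI ASCII
grid / newick / JSON.

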