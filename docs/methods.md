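# Methods

This note documents the models implemented in `phylospat`, the choices made
where conventions differ between software packages, and what the synthetic
world generator does and does not emulate.

## Grids, cleaning and diversity metrics

Cells live on a global lon/lat lattice anchored at (−180, −90) with
half-open `[edge, edge + res)` intervals; latitude 90 and longitude 180 are
clamped into the last row/column so every legal coordinate maps to exactly
one cell. The anchoring and the half-open rule are conventions that had to
be fixed somewhere; they are documented here because boundary records (e.g.
a record exactly on the equator) land in the cell to the north/east of the
line.

Record cleaning attaches named flags instead of deleting rows: `invalid`
(non-numeric or out of range), `zero` (exactly (0, 0)), `equal`
(lat = lon within 1e-8), and `outlier`. The outlier rule is per species:
a record is flagged when its great-circle distance to the species' centroid
exceeds `median(d) + k·MAD(d)` with k = 5, the robust location-plus-scale
form used by the CoordinateCleaner family of tools; it is only applied to
species with at least 5 coordinate-valid records, since MAD is meaningless
below that. On clean synthetic data this rule still flags a fraction of a
percent of legitimate records (robust screens have false positives by
design); the tests therefore check exact recovery of the *seeded* corrupt
records and an upper bound on collateral flags, not zero flagging.

Weighted endemism uses the reciprocal-range-size form `WE = Σ_s 1/R_s`.
For trait-group subsets (greenhouse / woolly / cushion / stemless and the
pooled set), `R_s` is recounted **within the subset's own distribution**;
computing `1/R_s` against the full matrix would understate group endemism
wherever a group member has a wide total range but a narrow group context.

## Environmental predictors

`Alt` and `Alt_SD` are the per-cell mean and sample (n−1) SD of the altitude
pixels (the population SD is available via `ddof=0`; at ~16 pixels per cell
the difference is ~3%). Anomalies are `modern − mean(LGM models)`,
pixelwise, so the sign convention is "positive = warmer/wetter today".
Climate-change velocity divides the temporal rate `|MAT_ano|/21000 yr` by
the local spatial MAT gradient (3×3 central differences, east–west spacing
scaled by cos(latitude)), floored at ε = 1e-9 °C/m to keep the quotient
finite on perfectly flat terrain. Velocity uses MAT only; a precipitation
velocity is deliberately not computed. The 21 000-year window and ε are
explicit configuration. Per-cell anomaly and velocity are means of the
pixel-level fields (the mean commutes with the anomaly's linearity; any
transform of velocity, e.g. a log, is left to the regression configuration
rather than baked into the predictor).

## Phylogenetic signal and ancestral states

All comparative methods assume a rooted, strictly bifurcating tree with
positive branch lengths; polytomies are rejected rather than silently
zero-resolved, because contrast weights diverge as branch lengths go to 0
(`resolve_polytomies(tree, epsilon)` exists for users who accept that).
Tips lacking a trait value are pruned per variable.

Blomberg's K is computed from the BM covariance matrix V (shared
root-to-MRCA path lengths): with the GLS mean â, the ratio of the raw to
the phylogenetically corrected mean squared error is divided by its
analytical BM expectation `[tr(V) − n/(1ᵀV⁻¹1)]/(n−1)`. The permutation
test shuffles tip values; the statistic is the corrected MSE (lower = more
signal) with the (1 + hits)/(n_perm + 1) continuity correction and 999
permutations by default. Calibration: the mean K over 1000 BM simulations
on a 200-tip Yule tree is 1.00 (the acceptance script recomputes this).

PIC ancestral states follow Felsenstein's pruning exactly: each node is the
1/branch-weighted mean of its children's working values and the parent edge
is extended by `b₁b₂/(b₁+b₂)`, so each node estimate depends only on its
descendants. REML estimates σ² by numerically maximizing the restricted
log-likelihood (the optimum agrees with the closed form Q/(n−1), where Q is
the GLS residual quadratic form — note ape's `ace(method="REML")` reports
Q/n instead; node *states* agree between the two, and the frozen oracle
values in the tests come from ape and picante). Node states are the
conditional normal expectations `â + C V⁻¹(x − â1)` with C the node–tip
shared-path matrix; σ² cancels from this expression, so state estimates are
insensitive to the σ² convention.

Species niche values aggregate occurrences onto a 0.25° grid first and then
average over occupied cells, so heavily collected localities count once.

## Spatial regression and correlation

Neighbor weights are queen (8-cell) adjacency on the occupied-cell lattice,
row-standardized; cells without a lattice neighbor are linked to their k = 4
nearest occupied cells by great-circle distance, and links are symmetrized
first, which keeps W similar to a symmetric matrix and its eigenvalues real.
The scheme is configuration, recorded in the run manifest, since published
analyses rarely state it.

The SAR error model is fitted by profile maximum likelihood: for trial λ
the data are filtered by (I − λW), β and σ² drop out in closed form, and
`ln|I − λW| = Σ ln(1 − λeᵢ)` comes from the precomputed eigenvalues; λ is
then a bounded scalar optimization inside (1/e_min, 1/e_max). The fitted
log-likelihood reproduces a dense multivariate-normal density evaluation to
1e-8 (tested), and fixing λ = 0 reproduces OLS exactly. AIC uses
k = #β + 2 (σ² and λ), so OLS and SAR fits are ranked on the same scale;
AICc is available behind a flag but AIC is the default.

Model averaging fits every non-empty predictor subset (intercept always
included; the intercept-only fit serves as the Nagelkerke null). Akaike
weights are normalized over the subsets; per-predictor support `w` sums the
weights of models containing the predictor; `Coef_ave` is the *full*
average (a predictor absent from a model contributes 0), which is what
makes weakly supported predictors show near-zero averaged coefficients.
Responses and predictors are z-standardized before fitting so coefficients
are standardized effects. Predictor pairs with |r| ≥ 0.7 are refused with
an instruction to split them into separate candidate groups — the same
workflow decision published analyses make when Alt and Alt_SD (or Alt_SD
and Vel) are strongly collinear; the pipeline therefore carries the four
conventional groups (a) Alt_SD+MAT+MAP+MAT_ano+MAP_ano+Vel,
(b) Alt+MAT+MAP+MAT_ano+MAP_ano+Vel, (c) Alt_SD+Alt+MAT+MAP+MAT_ano+MAP_ano
and (d) = (b) for the trait-group dataset, and skips (with a logged
warning) any group the guard rejects on a particular dataset.

Dutilleul's modified t-test estimates each variable's spatial correlation
matrix from Moran-type autocorrelations in equal-width great-circle
distance classes (Sturges' rule on the pair count by default), clips class
autocorrelations to [−1, 1], and computes the effective sample size
`M̂ = 1 + tr(BΣ̂x)tr(BΣ̂y)/tr(BΣ̂x B Σ̂y)` (B the centering matrix),
capped at n. With Σ̂ = I this reduces algebraically to M̂ = n and the
classical test. Calibration at n = 400: M̂/n ≈ 0.99 and 3–7% type-I error
for iid fields; for strongly autocorrelated independent surfaces the naive
test rejects ~80% while the modified test stays near 5% (tested).

Significance stars in printed tables use coefficient z-scores at 0.05 /
0.01 / 0.001; they are presentational, not a multiple-testing procedure.

## Variance partitioning

Three OLS-based R² values per union of groups, fractions by
inclusion–exclusion; the sum of the seven fractions equals the full-model
R² to machine precision by construction, which is why negative shared
fractions (suppression) are reported rather than clipped. Adjusted R² is
the default (each model's R² penalized by its own predictor count); plain
R² is used where tests compare against a raw least-squares oracle. OLS
rather than SAR is used here because the decomposition needs seven
comparable R² values on one scale and tolerates within-group collinearity.

## The synthetic world

The generator emulates the data regime of a northern-hemisphere alpine
radiation, not any real topography:

* **Terrain** — smoothed Gaussian random fields (broad σ≈2°, sd 150 m;
  micro σ≈0.3°, sd 60 m) over a 400 m lowland baseline, plus a 3600 m
  plateau (logistic shoulders, ~1° wide) carrying rough relief 8× the
  lowland amplitude, clipped at 0. This gives within-1°-cell altitude SDs
  several-fold higher on the plateau — the Alt_SD contrast the analysis
  needs.
* **Climate** — MAT = 35 °C − 0.8 °C/°lat − 0.006 °C/m × altitude plus a
  smooth ±8 °C "continentality" field (without it, temperature at regional
  extent is an affine function of altitude and the collinearity guard would
  rightly refuse Alt and MAT in one model); MAP = monsoon-like eastward
  gradient + orographic term. LGM layers subtract a cooling/drying that
  grows with latitude **and** a latitude-independent smooth anomaly pattern
  (emulating ice-sheet geometry), each perturbed per paleo-model; the two
  model layers play the role of a two-member LGM ensemble.
* **Phylogeny and niches** — a Yule tree (unit birth rate, ultrametric,
  rescaled to root depth 17 time units) with altitude optima evolving by
  BM from a 3800 m root at σ² = 1.5e5 m²/unit; the high root makes the
  genus alpine-centred so richness increases ~monotonically with altitude.
  Whole-clade BM drift can relocate a simulated genus into the lowlands
  under some seeds — a real feature of BM, which is why the end-to-end
  regime tests run on the default seeded world rather than averaging over
  seeds.
* **Occurrences** — each species samples pixels with probability ∝
  Gaussian niche match (breadth 350 m) × logistic down-weights in pixel
  anomaly (midpoint = layer median, scale 0.2 SD) and velocity (midpoint =
  35th percentile, scale 0.1 SD); 120 records per species with within-pixel
  jitter. Corrupt records (zero / lat=lon / out-of-range, 5% by default)
  are appended after the clean rows and indexed in the truth object, so
  cleaning recall is exactly measurable. A 30% species subset biased toward
  high-altitude optima carries randomly assigned trait-group labels.
* **Determinism** — one global seed; every stage draws from
  `default_rng(seed + fixed offset)` (terrain +1, climate +2, tree +3,
  traits +4, occurrences +5, corruption +6, trait groups +7), so stages
  are independently reproducible and all outputs are bit-identical under a
  fixed seed.

What passing the end-to-end tests shows: the pipeline recovers the signs
and relative importance of effects that the generator encodes
(Alt, Alt_SD positive; MAT_ano, Vel negative; geology's unique variance
fraction largest). What it does not show: performance under real-world
sampling bias, taxonomic error, non-Gaussian niches, or climate layers
with realistic spatial covariance — none of which the generator emulates.

## Problem sizes

Default analysis sizes were chosen so the whole suite runs comfortably on a
laptop core: a 240×240-pixel world (0.25°) aggregated to ~700 occupied 1°
cells; 2⁶−1 = 63 SAR fits per model group sharing one eigendecomposition;
1000 BM replicates on 200 tips for the K calibration; 200 replicates for
SAR λ recovery (20×20 lattice); 1000/500 replicates for the Dutilleul
calibrations at n = 400.
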