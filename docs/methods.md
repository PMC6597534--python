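# Methods

`probrain` reproduces a complete comparative analysis of brain–body
evolution in Proboscidea (elephants and their extinct relatives): endocast
volumetrics, conversion of endocranial volumes to brain masses,
encephalization quotients (EQ), phylogenetic generalized least squares
(PGLS) of log brain mass on log body mass under five trait-evolution
models with AICc selection, residual diagnostics with outlier exclusion,
and maximum-likelihood ancestral state reconstruction on a calibrated
specimen-level phylogeny. This note records the models, the parameter
choices that matter, and the places where the design was genuinely open.

## Data and fixtures

The packaged trait table (`data/table1.csv`) holds 28 individuals — 26
proboscidean specimens spanning *Moeritherium* (late Eocene, ~0.8 t) to
*Zygolophodon borsoni* (Pliocene, 16 t), plus a basal sirenian
(*Prorastomus*) and hyracoid (*Seggeurius*) kept as outgroup comparators
and excluded from all regressions and reconstructions. Columns are the
published endocast volume (cm³), brain mass (g), body mass (g) and Manger
EQ; decimal commas in the source are normalized on load.

The phylogeny is a consensus reconstruction: *Moeritherium* basal, then
*Palaeomastodon*; Mammutida (*Mammut*, *Zygolophodon*) sister to the
elephantoid clade; *Stegodon* outside Elephantidae; and *Palaeoloxodon*
deliberately left as part of a trichotomy with *Mammuthus* and
(*Elephas*, *Loxodonta*) to reflect its contested position. Two node ages
anchor the tree — Elephantimorpha at 26 Ma and Elephantoidea at 20 Ma —
and every other node and fossil-tip age lives in an editable
`data/calibrations.txt` (key = clade or taxon, value = Ma). Those
remaining ages are literature-plausible defaults, not published values;
every tree-dependent result is therefore a tolerance reproduction, and the
numbers most sensitive to branch lengths (final-fit slope; the
*Palaeoloxodon* node state) are exactly where our values depart from the
published ones (see Limitations).

Conspecific specimens are attached as separate tips: a species sampled n>1
times becomes a shallow polytomy whose specimen tips hang ε = 0.01 Ma
below the species node (root-to-tip depths preserved). ε keeps the
covariance matrix nonsingular while making conspecifics statistically
near-exchangeable; within-species covariance equals the tip variance minus
ε. A species-mean analysis can be had by averaging the table before
attachment, but the specimen-tip layout matches the published sample sizes
(26 regression points; 19 after exclusions).

## Volumetrics

Two estimators mirror how fossil endocast volumes are actually measured:

* **Double graphic integration** — two orthogonal silhouette width
  profiles w₁(x), w₂(x) are resampled onto a common axis (endpoint
  alignment by default, 200 slices) and integrated under an elliptical
  cross-section model, V = ∫ (π/4) w₁ w₂ dx (trapezoidal). The ellipse
  convention is the classical one for this technique; the source drawings
  for the one taxon measured this way are not available, so that printed
  volume (771 cm³) is not a reproduction target.
* **Mesh volume** — divergence-theorem sum of signed tetrahedra over a
  closed triangle mesh (the photogrammetry surrogate), returned as an
  absolute value with the orientation logged. Open meshes are rejected
  with the boundary-edge count; degenerate triangles warn.
* **Hemi-endocast doubling** — a half cast measured at V is reported as
  2V (the *Stegodon* protocol: 1919 cm³ → 3838 cm³).

Units are cm/cm³ throughout.

## Endocast → brain mass

Proboscidean endocasts include unusually thick meninges, so brain mass is

  M = V · (1 − m(V)) · ρ,  ρ = 1.036 g cm⁻³,

with no meningeal term for the outgroups (M = V·ρ). The printed
volume/mass pairs imply a fraction that decreases mildly with size —
≈ 0.123 at 240 cm³ down to ≈ 0.113 for elephant-sized endocasts — so the
default correction is allometric, m(V) = c·Vᵈ with c = 0.13663,
d = −0.02245 fitted to the 26 printed pairs (log-space residual sd 0.007);
this reproduces every printed brain mass within 0.28%. A constant-fraction
mode (mean m = 0.1134) is provided but leaves the smallest endocast 1.2%
off. Note the prose summary "about 14%" refers to the volume fraction
before the density step; the printed pairs themselves encode ≈ 11–12%.

## Encephalization quotient

Manger's EQ is M_brain divided by the brain mass expected from body mass,
a·M_bodyᵇ (masses in g). The reference constants are not printed in the
source; they are recovered by least squares of log(M_brain/EQ) on
log(M_body) over the 26 proboscidean triples and frozen as package
defaults: **a = 0.053953, b = 0.72817** (residual sd 0.0037 in log space).
The two outgroup rows are excluded from this fit by default because their
printed brain masses are single-digit integers whose rounding alone
perturbs the constants visibly (the 5 g *Seggeurius* value is 5.18 g
before rounding). With these defaults every printed proboscidean EQ is
reproduced within ±0.012, comfortably inside the ±0.03 two-decimal
printing tolerance used by the tests.

## PGLS under five evolutionary models

The regression is log₁₀ brain mass on log₁₀ body mass (slope and R² are
base-invariant) with error covariance induced on the tree by one of:

* **BM** — C_ij = σ²·s_ij, s_ij the root-to-MRCA shared path length;
* **λ (Pagel)** — BM with off-diagonal entries multiplied by λ ∈ [0, 1],
  diagonal unchanged. On this non-ultrametric tree this differs slightly
  from the correlation-normalized corPagel structure in R's nlme/ape; we
  verified numerically that the two conventions give λ̂ and slopes within
  ~0.01 on these data, and that λ=0 matches OLS exactly only on
  ultrametric trees (the property tests check it there);
* **OU** — fixed root, single optimum:
  C_ij = σ²/(2α)·e^{−α·d_ij}(1 − e^{−2α·t_ij}) with d the patristic
  distance and t the root-to-MRCA time; α ∈ [10⁻⁶, 50] per Ma;
* **EB** — exponentially decaying rate: a shared path of length s
  contributes σ²(e^{rs} − 1)/r, r ∈ [−5, 5], series-evaluated for
  |r| < 10⁻⁸;
* **OLS** — σ²·I.

β and σ² are profiled analytically (ML: σ̂² = e'C₀⁻¹e/n); the single shape
parameter is maximized by a 20-point grid pre-scan plus bounded Brent
search, so fits are deterministic without seeds. ML (not REML) is used
throughout — checked to be immaterial here (REML shifts the final slope by
< 0.001). AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1) with k = 3 for BM/OLS and
k = 4 for the three-parameter-shape models. The printed AICc values
themselves depend on likelihood-constant conventions the source does not
state and are not used as targets.

**R².** The headline R² is the phylogenetic one: 1 − RSS/TSS computed in
the whitened (Cholesky-decorrelated) space with TSS taken about the GLS
phylogenetic mean. This is the standard generalized R² for PGLS and it
reproduces the published full-data value (0.601 vs 0.61). Two other
variants are carried on every fit for comparison: the squared Pearson
correlation of whitened observed vs fitted values (≈0.96 here — it is
dominated by the shared phylogenetic trend and cannot be what was
published) and the naive original-scale 1 − RSS/TSS.

Slope inference uses a t test with n − 2 df and standard errors on the
unbiased scale.

## Diagnostics and the exclusion refit

Residual normality is tested with a Monte-Carlo Lilliefors test:
D = sup|F̂ₙ − Φ((x−x̄)/s)|, p = proportion of 10⁴ standard-normal samples
of the same size with D* ≥ D (default seed 20190627; the null table is
cached per sample size, and the Dallal–Wilkinson closed form is available
as an option). Homoscedasticity is exported as residual-vs-fitted pairs
plus an auxiliary Spearman test of |residual| against fitted (reported,
not gating).

The published "graphical" outlier removal is operationalized as
|whitened residual| > 2, but on our tree that rule flags only the two
extreme *Loxodonta* specimens, not all seven published exclusions — the
whitened residuals of a strongly phylogenetic fit concentrate misfit
differently than an eyeballed residual plot. The packaged exclusion list
(`data/exclusions.txt`) therefore pins the three taxa excluded outright
(*Moeritherium lyonsi*, *Palaeomastodon beadnelli*, *Palaeoloxodon
falconeri*) and resolves the published per-species counts (one
*P. antiquus*, one *E. maximus*, two *L. africana*) to the
largest-|whitened-residual| conspecifics under the full-data λ fit — which
turn out to be each species' EQ extremes. Refitting prunes those tips
(covariances among retained tips are exact submatrices) and reruns the λ
model and diagnostics; the refit residuals are normal (Lilliefors
p ≈ 0.77) and show no |residual|-vs-fitted trend.

## Ancestral state reconstruction

For each internal node v the ML estimate under BM equals the GLS
phylogenetic mean with the tree re-rooted at v, computed through unrooted
path lengths: C_v[i,j] = (d(v,i) + d(v,j) − d(i,j))/2, â_v =
(1'C_v⁻¹1)⁻¹1'C_v⁻¹y. Estimates agree with phytools' `fastAnc` to 10⁻¹⁰
and with brute-force maximization of the joint Brownian likelihood to
10⁻⁶. Estimation variances are σ̂²_ML·(1'C_v⁻¹1)⁻¹ — `fastAnc` differs
only by its (n−1) rate denominator — and 95% intervals are ±1.96σ; their
empirical coverage over recorded Brownian histories is ~94%. Branch
lengths below 10⁻⁸ Ma (from polytomy resolution) are floored inside the
solver only.

Brain and body mass are reconstructed on log₁₀ (they span five orders of
magnitude) and back-transformed without bias correction; EQ is
reconstructed directly on the linear scale, matching a literal `fastAnc`
call on the EQ column. An EQ recomputed from the reconstructed log-masses
can be formed from the per-trait outputs; the node-change summary uses the
direct reconstruction.

**Pulse detection.** Node-to-node edges are flagged as encephalization
pulses when the EQ ratio is ≥ 1.4 while body mass grows by a smaller
factor. The 1.4 threshold was set from the published node values
themselves: the two published pulses correspond to ratios ≈ 2.4 and ≈ 1.49
while every other published node-to-node EQ ratio is ≤ ~1.2, so 1.5 would
cut the second pulse and anything ≤ 1.2 would admit noise. The threshold
is configurable.

## Synthetic data

* Trait simulation draws one multivariate normal from the model
  covariance, deliberately exercising the same covariance code the fitters
  use; an independent branch-by-branch Brownian recursion (which also
  records internal-node states) serves as the cross-check oracle and for
  coverage tests.
* The allometric-dataset generator mirrors the final-fit regime: 19 tips,
  slope 0.20, λ = 0.9, intercept 1.76, with per-Ma rates matched to the
  packaged data (body BM rate 0.003 log₁₀²/Ma reproduces the observed
  body-mass spread; λ-noise rate 4×10⁻⁴ log₁₀²/Ma matches the final fit's
  ML residual scale). Under this regime 200 replicate fits recover the
  slope with bias < 0.01 and a λ̂ median of ≈ 0.79.
* Synthetic endocasts are scaled icospheres, optionally radius-modulated
  by a smooth low-order angular polynomial with seeded coefficients;
  silhouettes are per-slice mesh extents, and the unperturbed case has the
  closed-form volume (4/3)πabc.
* Random trees come from a birth–death sampler; occasional zero-length
  branches are floored to 10⁻³ time units so covariances stay nonsingular.

What the simulations do *not* emulate: measurement error in body-mass
estimates (taken as given), fossilized birth–death tip sampling, and
within-species trait variance beyond the ε-polytomy structure. Passing
recovery tests therefore demonstrate correctness of the estimators under
the assumed model, not robustness to those real-data complications.

## Numerical choices

* Covariances are Cholesky-factorized; on failure a ridge of
  10⁻¹⁰·mean(diag) is added with a warning (this occurs for near-singular
  EB covariances at extreme negative r, where all entries approach a
  common constant).
* Polytomies are resolved left-to-right with zero-length branches, which
  provably leaves the tip covariance unchanged; ties in the grid pre-scan
  resolve to the first (lowest-parameter) grid point.
* Profile optimization tolerance is 10⁻⁸ in the shape parameter; AICc
  differences are consequently reproducible to ~10⁻³ across affine
  reparameterizations of the data (exactly invariant at fixed shape
  parameters).
* Degenerate inputs: zero-variance residual vectors, n < 4 normality
  samples, non-positive masses/volumes and over-pruning all raise typed
  errors rather than propagating NaNs.

## Known limitations

* The published supplementary tree is not machine-readable; with the
  stated topology and the two stated calibrations, the outlier-excluded
  slope converges to 0.28 (published: 0.20) and the excluded-fit R² to
  0.70 (published: 0.50) — cross-checked against R's nlme+corPagel on the
  same tree, which agrees with our fit to three decimals, so the gap is a
  branch-length property of the unpublished tree, not an implementation
  difference. λ̂ (0.96 full / 0.96 excluded vs published 0.90) and the
  full-data R² (0.601 vs 0.61) are insensitive to this.
* The reconstructed *Palaeoloxodon*-clade EQ is 3.49 on our tree
  (published: 1.51): with the dwarf *P. falconeri* only 0.5 Ma below a
  1 Ma crown node, the node estimate is dominated by the most aberrant tip
  in the dataset. This adds a third flagged pulse edge and pushes the
  Elephantoidea-node EQ slightly above the published band. The deeper
  nodes (root 0.27 vs 0.24; Elephantimorpha 0.87 vs 0.73) are robust.
* Back-transformed log-mass reconstructions carry no lognormal bias
  correction (consistent with standard practice for these figures).
* EQ is reconstructed as a trait in its own right; reconstructing masses
  and forming the quotient afterwards gives systematically different
  (Jensen-gap) values at nodes with high uncertainty.
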