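# Methods

This note records the statistical models implemented in `scorpsize`, the
choices made where the design was genuinely open, and what the synthetic
test bed does and does not establish.

## Trees and matrices

Trees are rooted, ultrametric phylogenies with branch lengths in million
years, parsed and written by dendropy. A single postorder traversal yields
tip depths and the MRCA-depth matrix, from which both the phylogenetic
covariance `C` (`C[i,i]` = tip depth, `C[i,j]` = MRCA depth) and the
cophenetic distance matrix (`d[i,j] = depth_i + depth_j − 2·MRCA_ij`) are
read off. Pagel's λ multiplies the off-diagonal of `C`; for an ultrametric
tree `C(λ)` stays positive semidefinite over the whole unit interval, so λ
is searched on [0, 1]. Ultrametricity is declared when the root-to-tip
spread is within a relative 1e−6 of tree depth. Pruning preserves tip-to-tip
path lengths exactly, collapsing unary nodes with branch lengths summed.

Principal coordinates of the cophenetic matrix are the eigenvectors of the
double-centred matrix −½ J (d∘d) J, scaled by the square root of their
eigenvalues. Axis signs are arbitrary under eigendecomposition, so each axis
is oriented to make its largest-magnitude coordinate positive — this keeps
output reproducible across linear-algebra backends. Axes with non-positive
eigenvalues (impossible for additive tree distances, possible for arbitrary
dissimilarities) are dropped with a warning rather than corrected.

Calibration priors: a lognormal node-age prior whose (p_lo, p_hi) quantiles
equal a given age interval has the closed form
`sdlog = (ln hi − ln lo)/(z(p_hi) − z(p_lo))`, `meanlog = ln lo − sdlog·z(p_lo)`,
because ln(age) is normal and the two constraints are linear in
(meanlog, sdlog). No numerical optimization is needed; round-trips are exact
to floating-point precision.

## Trait tables

The vocabulary is closed: toL, carL, cheL, cheW, met5L, met5W, teL, teW, all
in mm, one row per species × sex. Species means are unweighted arithmetic
means of raw mm values, computed before the natural-log transform (means of
raw values, then log — not means of logs); unknown trait columns are
rejected rather than passed through. The mm and log representations
interconvert exactly, and a scale flag guards against double transforms.

## Synthetic data

The generator emulates the structure the comparative analyses assume, with
defaults fixed at the study conditions: 195 species, two measured
individuals per species and sex, at most 13% missing data. Trees are
crown-start Yule (pure-birth) processes, birth rate 0.1/My, giving ~50 My
depths for ~195 tips — pure birth rather than birth–death because only the
covariance structure matters downstream. Latent log size is ln(toL) itself,
evolving by Brownian motion (rate 3e−3 per My around ln 50 mm, spanning
roughly 12–120 mm across a tree); every other trait obeys
`ln x_t = a_t + b_t ln(toL) + Brownian residual` with slopes near isometry
(0.90–1.05) and intercepts that give realistic part sizes for a 50 mm
scorpion (carapace ≈ 5.5 mm, metasomal segment V ≈ 7 mm). Sexual dimorphism
is an additive log-scale offset (default 0.06, females larger, matching the
few-percent size gap in the empirical means); individuals add i.i.d. normal
log-scale noise (sd 0.05). Missingness is injected completely at random on
the six predictor-only traits — the empirical missingness mechanism is
uncharacterized, and MCAR matches the validation protocol's random masking.

A second generator (`simulate_pmm_dataset`) draws records exactly under the
mixed model below, predictor observed without error, so the regression slope
equals the nominal value. Scenario-based data, by contrast, put Brownian
residuals and measurement noise on the *predictor* side too, which
attenuates slopes — the right test bed for the pipeline as a whole, but not
for calibrated parameter-recovery checks.

What passing tests on these data do *not* show: robustness to non-random
missingness, to literature measurement error correlated with taxonomy, to
non-Brownian trait evolution, or to empirical tree-shape features (clade
ages, diversification shifts). The generator makes no attempt to mimic
buthid taxonomy.

## Imputation

Missing cells are filled per sex on the log scale by the missForest scheme:
initialize with column means, sweep columns in order of increasing
missingness, regress each incomplete column on the other traits plus the
first 10 phylogenetic eigenvectors with a 100-tree random forest, refill,
and stop when the relative change in imputed values first increases (the
previous iterate is returned) or after 10 sweeps. Forests are seeded;
observed cells are returned bitwise untouched. Eigenvectors are computed
once from the pruned tree — they carry no trait information, so there is
nothing to re-estimate across masking replicates.

Accuracy is the normalized RMSE over masked cells,
`sqrt(mean((truth − imputed)²)/var(truth))`, with the population variance
(ddof = 0) taken over the masked cells; the statistic is zero for perfect
imputation and invariant to common rescaling. The validation protocol masks
13% of species per trait column within each sex, imputes, scores, and
repeats 10 times. Masking is per trait (not 13% of the whole matrix): the
described protocol assigns the fraction "in each trait", and per-trait
masking also keeps every trait represented in every replicate.

## Phylogenetic PCA

For a complete log matrix X (one sex), λ is estimated by maximizing the
joint multivariate Brownian likelihood with per-trait rates profiled out:
−2 logL = n p ln 2π + p ln|C(λ)| + n ln|R_ML| + n p, with
R_ML = (X−1a)' C⁻¹ (X−1a)/n and GLS mean a = (1'C⁻¹X)/(1'C⁻¹1). The PCA
itself eigendecomposes the (n−1)-denominator evolutionary covariance;
scores are the centred data on the eigenvectors, and loadings are
evolutionary correlations (eigenvector columns scaled by sqrt(eigenvalue)
over evolutionary SDs). The analysis runs in covariance mode on log traits —
logging already equalizes scales, and correlation mode would discard the
size signal the analysis is meant to display. Axis signs are fixed
(largest-|loading| trait positive), so comparisons against presentations
with the opposite orientation should use absolute loadings. On a star
phylogeny the whole construction reduces to ordinary PCA; this limit, and a
frozen run of an independent reference implementation on a 12-tip fixture,
anchor the tests.

## Bayesian phylogenetic mixed model

Records (one per species per sex) follow
`y = Xβ + Z u_phylo + Z u_species + e` with `u_phylo ~ N(0, σ²_p C)`,
`u_species ~ N(0, σ²_s I)`, `e ~ N(0, σ²_e I)`. Both species-level terms are
kept even though each species contributes only two records; the variance
split is weakly identified and deliberately not an acceptance surface —
only fixed effects and RMSE are. Priors: β ~ N(0, 1e10 I) and
inverse-gamma-equivalent (V = 1, ν = 0.002) on each variance, the documented
defaults of the reference MCMC implementation (the source analysis states
only "default priors"); a tenfold-ν sensitivity check is part of the test
suite. The sampler is blocked Gibbs with (β, u_phylo) drawn as one joint
block — the intercept and the mean of the phylogenetic effects are strongly
confounded, and separate updates mix an order of magnitude worse (ESS ~30
instead of ~500 per 700 retained draws in profiling). u_species has a
diagonal update; variances are conjugate inverse-gamma draws.

Defaults are a single chain of 50,000 iterations, burn-in 5,000, thinning
50 — exactly 900 retained draws. Summaries report posterior means, 95% HPD
intervals, bulk ESS, and pMCMC = 2·min(P(draw>0), P(draw<0)) (floored at
1/draws) for fixed effects, with 0.05 as the significance threshold for sex
interactions.

RMSE is computed from posterior-mean fixed effects only, back-transformed to
mm: `sqrt(mean((exp(Xβ̂) − exp(y))²))` over all records. No random-effect
BLUPs enter predictions (the published equation carries fixed effects only)
and no smearing correction is applied to the exponential back-transform —
the published equation is the plain exponential, and predictions must match
it exactly. Predictor ranking fits one single-predictor model per candidate
and sorts by RMSE, ties broken alphabetically. Single-predictor models carry
no sex main effect: the interaction analysis found sex terms largely
non-significant, and the published equations are sex-free.

`fit_pgls_ml` is the sampler's independent oracle: it marginalizes the
random effects into `V(θ) = σ²_p ZCZ' + σ²_s ZZ' + σ²_e I`, profiles β by
GLS, and maximizes the likelihood over log-variances by Nelder–Mead from
three starts. With weak priors and these data sizes, posterior means and ML
estimates agree well within posterior spread (worst observed deviation ~0.3
posterior SDs across 20 synthetic sets).

## Prediction equations

The 13 published single-predictor coefficient sets (7 for toL, 6 for carL)
are bundled at their printed 2-decimal precision — the only precision
published; fitted sets keep full precision. carL is a valid predictor of toL
but never of itself. Two-predictor coefficients were never published (only
the best models' RMSEs), so `predict_multi` and the multi CLI commands
require a fitted coefficient JSON rather than silently substituting
invented values; the primary predictor is fixed per response (met5L for toL,
teL for carL) to mirror the published function signatures. Deviance is the
signed difference predicted − actual, in mm. The credible-bound envelope
`[exp(a_lo + b_lo ln x), exp(a_hi + b_hi ln x)]` is offered as a
deliberately naive, non-calibrated interval: it brackets coefficient
uncertainty only and ignores residual variation.

## Numerical choices and problem sizes

λ searches use scipy's bounded scalar minimizer (tolerance 1e−6) with an
endpoint check, since the bounded method never evaluates 0 or 1 exactly.
Cholesky factorizations carry a 1e−10-scale jitter on `C`. Replicate studies
in the tests and the acceptance script use shortened chains (4,000
iterations, burn-in 500, thinning 5) and moderate tree sizes (80–195 tips,
20 replicates), sizes at which every checked property is comfortably
resolved; the full 50,000-iteration settings are exercised once per run.
Monte-Carlo checks of Brownian covariance use 2,000 replicates on small
fixed trees.

## Known limitations

- Variance components are weakly identified with two records per species;
  only their sum is well constrained.
- The imputation NRMSE of the empirical study (0.01, reported in mm for a
  normalized statistic) is not directly comparable to the unitless NRMSE
  computed here; synthetic scenarios at matched noise reach ~0.07.
- Predictions for taxa far outside the buthid size range, or for fossils,
  inherit the usual risks of extrapolating an allometry fitted to extant
  species of one family.
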