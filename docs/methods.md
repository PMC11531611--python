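# Methods

This note documents the statistical machinery, the synthetic-data model
behind the tests, and the design choices made where the design was
genuinely open.

## Morphometric similarity networks

Input is a complete grid of 7 morphometric features over the 68
Desikan–Killiany cortical regions per subject. Within each subject, every
feature is demeaned and scaled to unit SD *across the 68 regions* (sample
SD, n−1; the MSN is provably invariant to the population/sample choice
because Pearson correlation removes any common column scaling — a property
test asserts both paths agree to 1e-12). The network edge between two
regions is the Pearson correlation of their 7-element z-scored feature
vectors: a 68×68 symmetric matrix in [−1, 1] with zero diagonal.

Thresholding keeps exactly `round(d × 2278)` edges (2278 = 68·67/2) with
the largest |weight|, signed weights retained. Ties are broken by
ascending (row, column) region index so the retained set is a pure
function of the matrix; this also makes edge sets nested across densities.
A region whose z-scored vector is constant has undefined correlations; its
edges are set to 0 with a warning by default (strict mode raises), so one
degenerate region does not abort a cohort.

Nodal metrics: degree = number of surviving edges; normalized strength =
(Σ |w| over surviving edges)/degree, with 0 for isolated nodes (avoids
0/0). Strength sums *absolute* weights — strength is a magnitude of
similarity; the signed variant is available via `signed=True`. The global
measure is the unweighted mean of the 68 strengths.

## Group comparison

`metric ~ group + age + sex + age×sex + eTIV`, OLS, group coded
control = 0 / TBI = 1, sex F = 0 / M = 1. Age is mean-centered before the
interaction is formed (reduces collinearity; leaves the group coefficient
unchanged). Effect size: Hedge's g = t·√(1/n₁ + 1/n₂)·J with
J = 1 − 3/(4·df − 1) on the GLM residual df — the standard small-sample
correction for unequal group sizes. p-values are Benjamini–Hochberg
adjusted within one family at a time: across densities for the global
metric, across the 68 regions for nodal metrics. Demographics: Fisher's
exact test on sex×group (the odds ratio is reported as the conditional
MLE, with the sample cross-product ratio alongside; for the published
cohort counts 54/29 vs 20/13 both round to 1.21) and a one-way ANOVA on
age at scan. A constant metric is reported as β = 0, t = 0 rather than
0/0.

## PLS prediction

Predictors (68 nodal degrees or strengths at one density, or the 68
regional values of a single raw feature) are first residualized on
(intercept, eTIV, age, sex, age×sex) per column, with column means added
back so the native scale is preserved. PLS1 is NIPALS on column-
standardized X and centered y: w_a ∝ X_aᵀy, t_a = X_a w_a, X deflated by
t_a p_aᵀ. Standardization (center + unit SD) is the default, matching the
common R implementation's behaviour; center-only is a switch.

### Corrected degrees of freedom and component selection

A PLS fit is nonlinear in y (the weights themselves depend on y), so its
effective complexity exceeds the naive a + 1. The corrected DoF is the
trace of the Jacobian ∂ŷ/∂y of the full fitting map, computed *exactly*
by forward-mode differentiation of the NIPALS recursion (every
intermediate — weights, scores, loadings, the deflated X — is propagated
with its Jacobian; memory is one (n, p, n) tensor). Tests verify it
against a central-finite-difference trace oracle to 1e-3. DoF(0) = 1; a
naive mode (a + 1) is provided for comparison. In near-isotropic
high-dimensional settings DoF(1) can reach n/2 — the first weight vector
is then itself heavily y-dependent — which is precisely what disciplines
selection below.

The component count a\* is chosen on the Mallows-form information
criterion AIC(a) = RSS_a/n + 2·DoF(a)·σ̂_a²/n with σ̂_a² =
RSS_a/(n − DoF_a) estimated per model (infinite once DoF ≥ n − 1). This is
the form used by the established R implementations of corrected-DoF PLS
selection; a log-likelihood AIC with a linear DoF penalty cannot reject
overfit models once DoF approaches n, because n·log(RSS/n) falls faster
than any 2·DoF penalty grows. a\* is the first local minimum of the AIC
path that also improves on the running minimum of all smaller models —
the running-minimum guard exists because the high-a tail of the path is
noisy and can dip locally while sitting far above AIC(0). a\* = 0 means
"no model generated", which is a reportable outcome, not an error.

### Fit metrics, bootstrap, cross-validation

Predicted R² = 1 − MSE(ŷ, y)/MSE(y, ȳ) (negative = worse than predicting
the mean), Pearson r with two-sided p, and MAE in outcome units.

Predictor weights are bootstrapped (subjects resampled with replacement,
component count held fixed, B = 1000 by default). The replicate statistic
is the coefficient vector mapped back to the predictors' native scale,
sign-aligned to the point estimate because PLS component signs are
arbitrary. Intervals are BCa: bias z₀ from the bootstrap distribution's
position relative to the point estimate, acceleration from the jackknife
skewness; with zero bias and acceleration the endpoints reduce to plain
percentiles (tested to 1e-3). Degenerate resamples (a zero-variance
predictor column) are redrawn and counted.

Cross-validation: leave-one-out, and k-fold (default k = 20) reshuffled
over 100 repetitions, summarised as mean per-repetition predicted R² with
a normal-approximation 95% CI (mean ± 1.96·SE; undefined for a single
repetition) and the median. Per-repetition R² is computed on pooled
out-of-fold predictions — with folds of 2–3 subjects a per-fold R² would
be meaningless. Folds are seed-controlled uniform partitions, unstratified.

Two leakage regimes are explicit. `replicate` (default) fixes a\* from a
full-data AIC scan and residualizes confounds on the full sample before
splitting — the procedure a small-sample clinical analysis typically
reports, which admits mild leakage. `strict` refits residualization and
selection inside every training fold. A leakage-audit test asserts the two
regimes produce different out-of-fold predictions (and identical ones when
residualization is off and a is fixed). Null-calibration experiments use
strict mode: a no-signal claim should not ride on construction leakage.
Under strict mode on null cohorts the AIC retains 0 components in
essentially every fold, and LOO collapses to the mean predictor, whose
predicted R² is exactly −(2n−1)/(n−1)² (≈ −0.035 at n = 59).

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
not human neuroanatomy. Features are region-specific Gaussian profiles
(scale 1, shared by all subjects) plus per-subject Gaussian noise (SD 1 by
default) with compound-symmetric cross-feature correlation (ρ = 0.3)
within each region; patients may receive per-region/per-feature shifts in
standardized units. Demographics: age uniform on [6, 15.5] years, sex
Bernoulli(0.64), eTIV Gaussian(1.45×10⁶, 1.3×10⁵ mm³), plus injury fields
for patients. Default group sizes 83/33 mirror a realistic paediatric TBI
cohort. The outcome is planted linearly on nodal degree at one density
(0.35 by default; strength via a switch): y = intercept + Σ w_r·degree_r +
ε. `outcome_noise_for_r2` calibrates the noise SD so the generating
model's population R² hits a requested value, using the realized variance
of the linear predictor. Optional confound leakage into the outcome is off
by default so residualization tests can toggle it. A single master seed
fans out to stage seeds by fixed offsets; identical (spec, seed) give
bit-identical tables.

The canonical planted pattern (`example_outcome_weights`) puts mixed-sign
weights on 10 fronto-temporal regions — the regions this kind of analysis
plausibly implicates. What the generator deliberately lacks: spatial
covariance of real cortex, low-rank anatomical modes, measurement
artefacts, and non-Gaussian tails. Consequently its nodal-degree
covariance is near-isotropic, which is a *harder* setting for PLS than
real data (no dominant mode to latch onto); passing tests therefore show
the machinery is correct and calibrated, not that any particular empirical
effect size transfers to real cohorts.

## Evaluation scenarios and problem sizes

The packaged experiments (`msnpred.evaluation`) use sizes chosen to make
each question answerable on a single CPU in minutes: component-count
recovery uses 100 replicates of one-latent-component data at n = 200,
p = 68; weight recovery uses n = 300 patients, B = 500 bootstraps,
population R² = 0.4; null calibration uses 20 no-signal cohorts (LOO) and
500 reduced-size cohorts (20 regions, 30 + 30 subjects) for the FDR group
tests. The train/CV optimism-gap demonstration runs 11 replicate cohorts
at the study-scale n = 59, p = 68 and summarises medians over the cohorts
where a model was generated (mirroring how such results are tabulated:
feature sets whose AIC retains zero components have no performance to
report). Its planted signal is population R² = 0.5: at n ≈ p ≈ 60 the
best achievable out-of-sample R² under a 0.4-signal isotropic design is
only ≈ 0.05–0.1 with a seed-to-seed spread of similar magnitude, so a
weaker plant would make individual cohorts straddle zero by sampling noise
alone; 0.5 is the weakest level at which "LOO R² is positive but far below
the training R²" is a property of the method rather than of the seed.

## Known limitations

- The corrected DoF costs O(a·n²·p) time and O(n²·p) memory; fine up to a
  few hundred subjects, not designed for thousands.
- BCa acceleration uses the jackknife; for n in the tens the acceleration
  estimate is itself noisy (flagged degenerate intervals are marked).
- The generator's isotropy means AIC retains components less often at
  n ≈ p than on structured real data; "no model generated" is common and
  is surfaced, not hidden.
- No PLS2, sparse PLS, or logistic PLS; no permutation inference; no
  graph metrics beyond degree and normalized strength.
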