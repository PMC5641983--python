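# Methods

## Model representation

Every model is specified as a parameter table over named observed and
latent variables and compiled to RAM form: a directed-path matrix **A**, a
symmetric (co)variance matrix **S**, a mean vector **M**, and a selection
filter **F** picking the observed rows.  Implied moments over the observed
variables are

    Σ(θ) = F (I − A)⁻¹ S (I − A)⁻ᵀ Fᵀ,      μ(θ) = F (I − A)⁻¹ M.

One implied-moments routine therefore serves every model family.  Equality
constraints (cross-wave loadings/intercepts, multigroup equality) are
expressed by label sharing — rows with the same label consume one parameter
— which keeps degrees-of-freedom bookkeeping exact: df = p(p+3)/2 − k with
p observed variables (means always modeled) and k free parameters after
collapsing equality groups.

Latent change factors are realized the standard way: the wave-2 score
receives fixed unit paths from its wave-1 score and from the change factor
(Y₂ = 1·Y₁ + 1·ΔY), so the change factor carries the substantive intercept,
variance, self-feedback and coupling parameters.  Change-score intercepts
are substantive quantities here, hence the mean structure is mandatory.

### The three theory builders

* **Bivariate LCS** (`build_bivariate_lcs`): observed {age, voc1, mat1,
  voc2, mat2}, latent {Δvoc, Δmat}.  Free: age mean/variance; wave-1
  intercepts, age slopes, residual variances and covariance; change
  intercepts, variances and residual covariance; self-feedbacks; plus one γ
  per requested coupling.  Both couplings → 18 free, df = 2 (mutualism);
  reasoning→Δvocabulary only → 17 free, df = 3 (investment).
* **Common-factor model** (`build_g_model`): wave-specific g factors with
  the vocabulary loading fixed to 1 and the reasoning loading free, change
  at the factor level (g₂ = g₁ + Δg with self-feedback), same-indicator
  residual covariances across waves, age predicting g₁ only.  Under weak
  invariance (loadings equated across waves, the reference build): 17 free,
  df = 3.  The diagram-level description of this model does not enumerate
  every residual covariance; this parameterization is the documented
  structure that reproduces the published df under weak invariance.
  Configural and strong levels, and two alternative age placements
  (age → observed scores only; age → scores and factor), are config options.
* **Univariate LCS** (`build_univariate_lcs`): one domain, 8 free, df = 1;
  with the self-feedback fixed to zero its change intercept reduces to the
  paired-difference estimate (the t-test analogue).

Age is centered at its sample mean before entering any model; this
stabilizes intercepts and affects no fit statistic.  Wave-2 scores can be
annualized to the mean inter-test interval (1.48 years) by linear rescaling
y₂′ = y₁ + (y₂ − y₁)·(1.48/interval); the cited rescaling proposal gives no
formula, so this linear annualization is a declared stand-in, off by
default for generated data (whose change process is interval-free).

## Estimation

**FIML.**  Each subject contributes the multivariate-normal log-density of
the sub-vector actually observed, under the matching sub-moments; missing
entries are marginalized, never imputed.  Subjects are grouped by
missingness pattern so each pattern's covariance sub-matrix is factorized
once per evaluation — identical to per-row FIML at lower cost.

**Optimizer contract.**  Free variances are optimized on the log scale
(positivity by construction); covariances and paths are unconstrained, with
positive-definiteness checked at the implied level (non-admissible points
are rejected with a finite penalty).  The FIML gradient is analytic,
propagating the one-hot RAM derivatives through B = (I − A)⁻¹:
dΣ = B dA G + (B dA G)ᵀ + B dS Bᵀ restricted to observed rows, with the
per-pattern contractions using the pattern's sufficient statistics.
L-BFGS-B runs from moment-matched start values (sample means/variances for
observed intercepts/variances, zero for structural paths), with multi-start
(default 5, deterministic jitter, fixed seed) to guard against ridge
solutions; the best start is then polished by Newton steps using a
finite-difference Hessian of the analytic gradient.  A fit is flagged
converged when the final gradient max-norm is below 1e-6; fit indices are
sensitive to sloppy optima, hence the strict tolerance.  Non-convergence is
reported, never raised.

**Standard errors** come from the observed information matrix: the Hessian
of the FIML log-likelihood at the estimate, by central finite differences
of the analytic gradient with a fixed relative step (1e-5), inverted and
negated.  These are plain information-based SEs; robust (sandwich/scaled)
corrections are not implemented, a documented divergence from analyses that
pair FIML with robust corrections — consequently printed robust-scaled χ²
and CI values are matched only approximately (the RMSEA *points* agree at
printed precision; the interval bounds differ in the third decimal).

**Reference fits.**  The saturated model (all means/variances/covariances
free) is estimated by EM for the multivariate normal under missingness
(closed form when complete), iterated to a 1e-10 relative log-likelihood
change.  The CFI baseline frees all means and variances and fixes every
covariance to zero — closed form under any missingness pattern since the
variables are then independent; age is just another uncorrelated variable
in it.  The model χ² is T = 2(llₛₐₜ − llₘₒdₑₗ) clipped at zero.

## Fit indices and comparison

RMSEA uses the df·N denominator (with N = 785 the N vs N−1 conventions
agree to three decimals); its 90% interval inverts the noncentral-χ²
distribution of T in λ (lower: upper-tail 0.95; upper: 0.05), mapped via
√(λ/(df·N)).  CFI = 1 − max(T−df, 0)/max(T_b−df_b, T−df, 0), capped to
[0, 1].  SRMR averages squared standardized residuals over the p(p+1)/2
unique covariance cells, sample moments taken from the saturated FIML fit
(so it stays defined under missingness); mean residuals are excluded — the
most common covariance-only reading.  AIC/BIC count *all* free parameters
(means and variances included) with N = number of subjects in BIC; Akaike
weights are computed with max-subtraction for overflow safety.  The
measurement-invariance sequence fits configural → weak → strong with
cumulative constraints and flags a step as failing when the CFI drop
exceeds 0.01 (the conventional threshold; configurable).

## Synthetic cohort generator

The generator emulates a two-wave adolescent/young-adult cohort: ages
uniform on 14.10–24.99; intervals truncated-normal (mean 1.48, SD 0.33,
range 0.65–2.62 years); wave-1 scores linear in centered age with
correlated Gaussian residuals; latent changes from the structural equations
ΔY = α + β·own + γ·other + ζ with correlated change residuals; wave 2 =
wave 1 + change; the wave-2 pair jointly missing MCAR at 1 − 566/785 ≈ 28%
(an optional logistic age-dependent mechanism emulates the observed
completer-age gap; FIML is valid under both).  Scores are continuous;
optional ceiling censoring at the test maxima (35 reasoning, 80 vocabulary)
is off by default since the analysis model is linear-Gaussian — it is a
robustness knob, not part of the reference conditions.  One root seed is
split into per-variable substreams, so the first k subjects of a larger run
are bit-identical to a smaller run (and identical seed + parameters give
bit-identical datasets).

### Preset calibration

`nspn_like_preset` pins the generating values to published cohort
quantities:

* wave-1 means/SDs exactly (vocabulary 58.57/7.85, reasoning 29.04/3.18);
* the change equations solved in closed form, per domain in standardized
  terms, so that simultaneously (i) the fully standardized couplings are
  .203 (vocabulary→reasoning change) and .144 (reasoning→vocabulary
  change), (ii) the structural paths explain 30.8% / 11.7% of the
  change variance in reasoning / vocabulary, and (iii) each change
  equation's univariate projection reproduces the published univariate
  self-feedback estimates (−0.331 / −0.147).  The implied univariate change
  residual variances (≈2.9 / ≈11.9) then land close to the published 2.85 /
  11.67 without being imposed — a consistency check on the calibration;
* change intercepts reproducing the observed mean wave-1→wave-2 gains.

Three generating correlations are not pinned by any printed descriptive:
the vocabulary–age correlation, the reasoning–age correlation, and the
total wave-1 cross-domain correlation.  The first is set to .40, a
realistic magnitude for crystallized knowledge still accumulating at these
ages.  The other two (.0701 and .543) were solved once, by deterministic
population-misfit inversion, so that fitting the two mis-specified
competitor models to the preset's *implied moments* reproduces their
published misfit at the cohort's size and completer count (factor model
χ² = 30.078; one-way-coupling model χ² = 26.28).  The near-zero
reasoning–age slope this implies matches the well-known plateau of fluid
ability in late adolescence, and it locates the factor model's misfit where
the published age-placement analyses locate it: age relates to the two
domains discordantly with the factor-loading ratio.  The change residual
correlation is set to .20 (residual changes remain positively correlated,
as reported).

### What the generator does not emulate

Item-level responses, practice effects, score discreteness, skew/ceiling
compression (unless the censoring knob is on), and any non-MCAR attrition
beyond the optional age mechanism.  Passing tests therefore certify the
*estimation and comparison machinery* under the cohort's design — not
robustness of the substantive result to non-normality or informative
dropout.  Exact reproduction of the published robust-scaled statistics is
out of scope by design.

## Numerical choices and degenerate inputs

Optimizer tolerances: L-BFGS-B ftol 1e-11 / pgtol 1e-8, Newton polish to
gradient max-norm < 1e-6, at most 12 polish steps.  RMSEA noncentrality
roots are bracketed and solved by Brent's method to 1e-10.  Zero sample
variance raises a degenerate-variable error in SRMR/baseline; a singular
(I − A) raises a structural-cycle error; an information matrix with
non-positive diagonal marks the affected SEs NaN with a warning.  Ties in
model ordering are broken by AIC sort stability.  The mutualism-vs-
investment LRT requires strict nesting (positive delta-df) and clips
negative delta-T at zero (tolerance 1e-6, beyond which an optimizer
inconsistency is raised).

## Problem sizes used in the shipped studies

The test suite and acceptance script use: 120 replicate cohorts (N = 785)
for the model-selection study; 1000 replicates for the coupling-LRT type-I
calibration; 500 replicates for Wald coverage; 40 replicates of N = 100,000
for large-sample recovery (enough that the Monte-Carlo error of the mean
sits well inside a 2%-relative band even for the near-zero fluid-age
slope); N = 10⁶ for generator calibration checks.  These sizes keep
Monte-Carlo error well inside the asserted tolerances while remaining
single-CPU friendly.

## Known limitations

Two waves only (no dual-change-score lead–lag dynamics); continuous
indicators and plain FIML only (no categorical estimators, no robust
corrections); the g-model parameterization is one defensible realization of
the diagram, and whether the published factor fit used weak or strong
invariance is not stated — the reference build uses weak, which matches the
published df; the annualization formula is a stand-in; generating
covariances of the real cohort are unknowable from printed summaries, so
the preset is an emulation calibrated to them, not an estimate of them.
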