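# Methods

## Model

For child *k* in household *j*, survey cluster *i*, district *h*, the binary
outcome y (anaemia: altitude-adjusted Hb < 11 g/dl) follows

logit π = x'β + U_h + f_age(age) + f_spat(lon_i, lat_i)

* **x'β** — linear fixed effects. Categorical covariates are dummy-coded
  against fixed reference levels (male, RDT-negative, urban, no education,
  male household head, no toilet facilities, Malawi); the residence × country
  interaction uses products of the non-reference dummies. Continuous
  covariates enter linearly, with cluster altitude rescaled to 100 m units
  and EVI to thousands so coefficients are readable as odds ratios per
  practical step.
* **U_h** — i.i.d. district random intercept, U_h ~ N(0, σ²_U). Households
  are indexed but carry no random effect: the model treats within-household
  correlation as absorbed by the household-level covariates. The estimated
  U_h are BLUPs and drive the district appraisal.
* **f_age** — P-spline: cubic B-splines on 20 equal segments spanning the
  observed age range (23 basis functions), second-order difference penalty
  (order-2 penalties leave linear trends unpenalized; order-1 available).
* **f_spat** — tensor product of two marginal cubic B-spline bases over
  longitude and latitude. The penalty is the Kronecker sum of the marginal
  first-difference penalties, i.e. the sum of squared deviations of each
  coefficient from its four nearest neighbours on the coefficient grid; its
  null space is the constant sheet. The default marginal dimension is 20
  basis functions per axis; analyses on small synthetic datasets in the test
  suite use 6–11 per axis (see "Problem sizes").

### Knots and bases

Knot vectors are equally spaced and extended past the domain boundary by
repeating the *spacing* (not the boundary value). This keeps the Greville
abscissae equally spaced, so a coefficient vector linear in the basis index
reproduces a linear function — exactly the null space the second-order
penalty needs; with value-repeated (clamped) knots the λ→∞ limit would not
be a straight line. A knot count can be read as segments (default; basis =
segments + degree) or as total basis dimension; both conventions are
selectable.

### Identifiability and centering

Every smooth contains the constant function in its penalty null space and
would be confounded with the intercept. The mixed-model reparameterization
splits each penalized term into an orthonormalized polynomial null-space
part (constant first) and a penalized part scaled to carry an identity
penalty; the constant column is dropped (absorbed by the intercept) and the
remaining null-space columns (e.g. the linear age trend) join the fixed
effects. Reported smooths are additionally centered by subtracting the mean
of the fitted term over the observed data, so plotted curves and surfaces
have (weighted) mean zero over the sample; the pointwise bands apply the
same linear contrast to the coefficient covariance.

## Estimation

The penalties λ α'Kα translate to Gaussian random-effect variances
τ² = 1/λ under the reparameterization, making the model a GLMM. Fitting
alternates:

1. **Penalized IWLS (inner loop).** At fixed variance components θ, solve
   the penalized weighted normal equations on the working response
   z = η + (y − μ)/w, w = μ(1 − μ), with step-halving whenever a step would
   increase the penalized deviance. Convergence: relative coefficient change
   < 1e-6 (max 200 iterations). At the canonical logit link this is exactly
   Newton–Raphson on the penalized Bernoulli log-likelihood, which is what
   the oracle-equivalence tests check against a generic quasi-Newton
   optimizer.
2. **REML update (outer loop).** At the inner optimum, the working model is
   a linear mixed model; each variance component is updated by Schall's
   fixed-point rule θ_r ← b̂_r'b̂_r / (q_r − tr(A⁻¹)_rr/θ_r), whose
   stationary point solves the working-model REML score equations (for a
   Gaussian response this reproduces closed-form ANOVA REML on balanced
   one-way data, verified to 1e-6 in the tests, and the dispersion is
   updated as RSS over residual effective df). Convergence: relative change
   in log θ < 1e-5 (max 50 iterations). A direct Nelder–Mead optimization of
   the working REML criterion (`reml_method="optimize"`) is available and
   agrees with the fixed point.

**Boundary handling.** Variances are floored at 1e-8 during optimization. A
component whose REML path collapses toward zero — detected either by falling
below 1e-6 or by eight consecutive geometric decays while already below
1e-3 — is pinned at the floor and reported as exactly 0; with σ²_U at the
boundary all district BLUPs are returned as exact zeros with a warning. This
pinning is what lets the outer loop terminate on null data, where the REML
maximum sits on the boundary and the log-scale convergence test would
otherwise never fire.

**Numerical safety.** Fitted probabilities are clipped to
[1e-10, 1 − 1e-10] before forming weights (logged when triggered); an
apparent complete separation (a fixed-effect coefficient beyond ±30) raises
an error naming the covariate; a rank-deficient fixed design raises an error
listing the collinear columns.

**Uncertainty.** The coefficient covariance is the inverse penalized
information A⁻¹ at convergence (the empirical-Bayes/posterior covariance
standard for penalized spline models). Wald 95% intervals use
z = 1.959964; the same matrix supplies the district BLUP prediction SEs and
the smooth/surface bands. Odds-ratio tables report exp(β̂) with
exponentiated interval endpoints and a 5% significance flag.

**Determinism.** Fitting is deterministic given the data and starting
values; refits are bit-identical.

## District appraisal

BLUPs shrink each district's raw deviation toward zero in proportion to its
information (verified against the closed-form shrinkage factor on balanced
Gaussian data). Standardization divides each BLUP by its prediction SE
(default), giving a conditional z-like score; an across-district z-score is
available but can reorder districts, and the two are deliberately kept
distinct. Ranking is ascending (rank 1 = lowest standardized BLUP = best
performing district), per country by default or pooled, with deterministic
ties broken by district identifier. Top-k and bottom-k flags are disjoint
whenever a country has at least 2k districts. Districts without sampled
clusters receive no BLUP and appear as missing, never as zero.

Because the model contains country fixed effects and the district indicators
within a country sum to the country indicator, U_h is identified only
relative to its country mean; rank-recovery experiments therefore measure
concordance within country — the same scale on which the league table ranks.

## Synthetic data

The generator emulates the hierarchical geography of pooled DHS/MIS surveys:
four countries with per-country lon/lat bounding boxes, districts, clusters
with uniform coordinates and an urban/rural label, households of 1–3 sampled
children, and the full covariate set (gender, age 6–59 months uniform,
malaria RDT, mother's education with an explicit "unknown" level, household
size, wealth Z-score ~ N(0,1), toilet facility, head-of-household age and
gender, cluster altitude/EVI/LST constant within cluster). The full
survey-scale layout (370 districts, 1595 clusters: Kenya 47, Malawi 26,
Tanzania 176, Uganda 121 districts) is available via
`GeographyConfig.survey_scale()`; the default layout is scaled down
(4 × 10 districts, 4 clusters each) for fast iteration.

The default truth sets every fixed-effect coefficient to the log of a
published survey-scale adjusted odds ratio (e.g. malaria 4.315, female
0.876), σ²_U = 0.1516, a single-bump age effect peaking near 10 months and
declining to negative values past the early twenties, and a smooth spatial
surface made of one positive bump near Lake Victoria and one negative bump
over central Tanzania. The intercept (0.68) was calibrated once so the
pooled prevalence sits near the observed 52.5% under the default covariate
marginals. Outcomes can be drawn directly as Bernoulli(π) or via a latent
logistic haemoglobin draw thresholded at 11 g/dl; the latent construction
makes the two modes agree in distribution for every noise level, and the
stored raw Hb reproduces the simulated outcome exactly when pushed back
through altitude adjustment and classification.

What the generator does *not* emulate: survey sampling weights and
stratification, GPS displacement, the empirical covariate marginals of any
particular survey, or spatially clustered district footprints (cluster
coordinates are uniform within the country box, so district effects and the
spatial surface are nearly unconfounded — real districts are contiguous and
would confound them more). Recovery results on synthetic data therefore
validate the estimation machinery, not the epidemiology of any real survey.

## Covariate screening

Univariate screening fits a single-covariate logistic model and keeps the
covariate when p < 0.10; the likelihood-ratio test is the default (it covers
multi-level categoricals), with the Wald test exposed for single-column
terms since either convention is defensible. Head-of-household age is
screened out by the default pipeline configuration rather than hard-coded.
Two-way interactions are screened by likelihood-ratio comparison of the
main-effects model against the model plus one interaction; inestimable
augmented models are skipped with a logged warning.

## Problem sizes used in validation

Chosen as the package's own trade-off between Monte-Carlo precision and
turnaround: parameter recovery uses 25 replicates (tests; 12 in the
acceptance script) of n = 50,000 children across 200 districts at the
study-scale truth with an 8 × 8 spatial coefficient grid; rank recovery uses
25 (tests; 10 script) replicates of 40 districts × 400 children with
σ²_U = 2.0; the null-model check uses n = 20,000 with the spatial term fitted
against a flat truth. Outer REML tolerance is relaxed to 1e-3 in these
experiments (variance components are only needed to Monte-Carlo accuracy).

## Known limitations

* REML for the binary response is defined through the working linear mixed
  model at IWLS convergence (a PQL-style empirical Bayes bridge). Like every
  estimator in this family — including the standard R implementations of the
  same model class, with which the fit agrees to ~1e-4 on identical data —
  plug-in estimation of the smooth terms can attenuate the largest
  fixed-effect coefficients by a fraction of a percent at realistic sample
  sizes. Variance-component estimates show no such bias in the recovery
  experiments.
* Wald intervals are used throughout; no profile or bootstrap intervals.
* The spatial surface is a fixed-rank smoother: genuinely fine-scale spatial
  variation below the coefficient-grid resolution is absorbed by the
  district effect or the residual.
* Ranking uncertainty is reported only through prediction SEs; no posterior
  rank distributions.
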