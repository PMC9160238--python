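# Methods

## The model

`pathmed` fits a recursive linear path system for an exposure X (a
polygenic risk score), J parallel mediators M₁..M_J and an outcome Y:

    M_j = i_j + a_j X (+ γ_j' C) + e_j ,   j = 1..J
    Y   = i_Y + c' X + Σ_j b_j M_j (+ γ_Y' C) + e_Y

with jointly Gaussian errors, freely correlated mediator residuals
cov(e_j, e_k), and e_Y independent of the mediator residuals.  The
effect decomposition is the product-of-coefficients one: the indirect
effect through mediator j is a_j·b_j, the total effect is
c' + Σ_j a_j·b_j (an exact identity, preserved to machine precision in
every fit and bootstrap replicate), and the proportion mediated is
indirect/total (reported as NaN when |total| is numerically zero rather
than divided through).  Standardized coefficients rescale each slope by
the model-implied SD ratio of predictor to response.

Binary mediators (cannabis and tobacco case status) enter the linear
equations as numeric 0/1, i.e. their a-paths are linear-probability
slopes and their b-paths are per-category outcome differences.  This is
deliberate: it is what a linear ML path analysis (lavaan-style) of a 0/1
column estimates, and the arithmetic of the published effect tables this
package is calibrated against only makes sense on that scale.  No
probit/ordinal measurement model is offered.

By default the mediation model includes no covariates, matching the
published path tables, which print no covariate rows; age, gender and
genetic principal components can be added to every equation through the
`covariates` argument (the separate covariate-adjusted regression stage
always adjusts for age and gender).

## Estimation

**Complete data.** For this recursive system with identical regressors
within each block, joint Gaussian maximum likelihood factorizes, and the
ML solution is equation-wise least squares with residual (co)variances
from cross-products of residuals (divisor n).  Internally everything is
derived from the joint ML mean/covariance by partitioned regression;
a test verifies agreement with a brute-force numerical maximizer of the
joint likelihood on small instances.

**Missing data (case-wise / full-information ML).** The joint mean
vector and covariance matrix of all model variables are estimated by an
EM algorithm over observed-data patterns (starting values:
available-case moments, eigenvalue-floored to be positive definite;
convergence when the relative observed-data log-likelihood change falls
below 1e-8, cap 500 iterations; non-convergence is reported on the fit
object, never silently ignored).  Path coefficients then follow from the
ML moments by the same partitioned regressions.  On complete data this
reproduces the equation-wise solution to numerical precision.  Listwise
deletion is available as a robustness option.

## Bootstrap inference

Rows (individuals) are resampled with replacement; every replicate
refits the model and recomputes the effect decomposition.  For complete
data the refit needs only re-weighted first and second moments, so all
replicates are computed at once from multinomial resampling counts
(algebraically identical to resampling rows); with missing data each
replicate is an EM refit.  Intervals are bias-corrected accelerated
(BCa): z₀ = Φ⁻¹(share of replicates below the point estimate), the
acceleration constant comes from jackknife influence values
(leave-one-out by moment downdating on complete data; a delete-a-group
jackknife with ~50 groups under FIML, where n leave-one-out EM runs
would be disproportionate), and the interval endpoints are the
Φ(z₀ + (z₀+z_α)/(1−â(z₀+z_α))) replicate quantiles.  With z₀ = â = 0
this reduces exactly to the percentile interval (tested).  The
implementation was cross-checked against R's `boot::boot.ci` BCa bounds
on a fixed dataset.

Replicates whose resample is degenerate (e.g. a constant mediator
column) are skipped and counted.  The two-sided bootstrap p-value uses
the +1 convention, 2·min{(1+#{θ*≤0})/(B+1), (1+#{θ*≥0})/(B+1)}, capped
at 1 — the source analyses report bootstrap p-values without defining
them, so this standard convention is adopted.  Default replicates: 5000,
as in the published protocol.  BCa intervals for a product of
coefficients are known to be slightly anticonservative near the null
(empirically ≈7–8% two-sided exclusion of zero at nominal 5% in this
package's null simulations); this is a property of the estimator, not of
the implementation.

## Sensitivity analysis

An omitted confounder of the mediator–outcome relation induces a
correlation ρ between e_j and e_Y.  For the linear model, if the fit is
performed assuming ρ = 0, the outcome coefficient on the mediator
absorbs a bias ρ·σ_Y/σ_M, and the observed outcome residual SD shrinks
by √(1−ρ²); the mediated effect as a function of ρ is therefore

    ACME(ρ) = a · ( b̂ − ρ · σ̂_Y / (σ̂_M √(1−ρ²)) )

with σ̂_M, σ̂_Y the fitted residual SDs of the designated mediator's and
the outcome's equations.  With several mediators the analysis is run one
mediator at a time, the others remaining covariates of the outcome
equation.  ACME(0) equals the fitted a·b exactly; the curve is monotone
in ρ; the zero-crossing ρ₀ is located by bisection between the
bracketing grid points (tolerance 1e-6), and ρ₀² is reported as the
share of residual variance a confounder must explain to nullify the
mediated effect.  Two oracles validate the formula: data generated with
a known residual correlation and zero true mediation yield ρ₀ ≈ ρ*, and
the curve evaluated at the generating ρ recovers the generating a·b.

## Genetic threshold scan

To ask at which level of genetic risk mediation is statistically
detectable, the cohort is upscaled ten-fold by parametric simulation
from the fitted model's implied joint distribution (for this saturated
recursive model, its ML mean and covariance) — not by row duplication,
which would corrupt bootstrap variance.  The mediation model plus BCa
bootstrap is then refitted while removing the top 5-percentile slice of
the exposure distribution per step; cutoffs are computed once on the
original upscaled sample, so removed sets are nested.  The scan stops at
the first step whose interval for the designated indirect effect covers
zero and reports the cutoff of the last significant step; a scan void
already on the full sample reports "no mediation detected" rather than a
threshold.  Inside the scan the default is 1000 bootstrap replicates
(configurable to 5000): twenty steps at full replication add nothing at
desk scale.  No claim is made of reproducing any particular published
percentile, which depends on the original data.

## PRS threshold selection

The PRS is available at 13 GWAS p-value inclusion thresholds whose
columns are nearly collinear (default inter-threshold correlation 0.99).
Selection is two-stage: an L1-penalized regression of the outcome on all
standardized PRS columns with unpenalized covariates (implemented by
residualizing outcome and PRS columns on the covariates, equivalent by
Frisch–Waugh–Lovell), penalty chosen by seeded 10-fold cross-validation
(the source does not state its penalty rule; this is the reproducible
default), then one linear model per survivor with the largest full-model
R² winning; the incremental R² of the PRS term is reported alongside.
Exact ties break toward the less stringent (larger) threshold and are
logged.  At correlation 0.99 the nonzero set is inherently seed- and
fold-sensitive — the columns are statistically interchangeable — so the
result object records the penalty and per-column coefficients for audit,
and planted-signal recovery should only be expected at moderate
collinearity.

## Confounder screen

Step 1 correlates each candidate with the outcome and with the exposure
(Pearson, two-sided t-test p-values — the source does not state the
test); |r| > 0.7 or p < 0.05 for *either* variable passes (the source
wording covers both readings; "either" is implemented and logged here).
Step 2 adds each passer to the outcome-on-exposure regression and flags
a confounder when the exposure coefficient moves by more than 10%.  Both
steps are affine-invariant in the candidates.

## Synthetic-cohort generator

The generator emulates the study conditions of two young-adult cohorts:
a discovery sample (n=1262; CTQ 31.9 (8.4), CAPE 67.3 (13.9), cannabis
prevalence 0.32, tobacco 0.30, age 20.5 (2.5), 48% male) and a
replication sample (n=1740; CTQ 40.2 (6.5), CAPE 60.6 (11.4), cannabis
0.21, tobacco 0.34, age 19.4 (1.5), 47% male).  Structural slopes are
the published unstandardized path estimates (discovery: a_CM = 0.171,
a_cannabis = 0.015, c' = 0.190, b_CM = 0.575, b_cannabis = 2.71,
CM–cannabis residual covariance 0.489; replication: 0.603, 0.041,
0.489, 0.496, 1.79, 0.389).  Key calibration choices:

- **PRS scale.** The ratio of published standardized to unstandardized
  coefficients pins the PRS SD at ≈5.2 (discovery) and ≈0.93
  (replication); three independent ratios agree to within a few percent
  in each cohort.  The generator uses these as defaults — with a unit
  PRS SD the published significance pattern (e.g. a_CM = 0.171 with a
  CI of 0.072–0.270, PRS R² ≈ 0.014) would be unattainable.  PRS
  columns are drawn as an equicorrelated Gaussian block and scaled.
- **Binary mediators.** A latent N(0,1) propensity α·Z_std + u is
  thresholded at the quantile matching the configured prevalence, with α
  calibrated so the linear-probability OLS slope of the indicator on the
  PRS equals the configured path (α = slope·SD_PRS/φ(cut)).  Configured
  residual covariances are specified on the observed scale and converted
  to latent correlations (attenuation by φ(cut) for continuous–binary
  pairs; inversion of the bivariate-normal orthant probability for
  binary–binary pairs).  Positive semidefiniteness of the implied
  residual correlation matrix is checked at construction.
- **Residual SDs** are back-solved so the implied marginal SDs reproduce
  the cohort descriptives exactly (closed-form variance propagation,
  validated against Monte-Carlo samples).
- **Outcome truth.** The outcome is generated from the two-mediator
  equation; neuroticism and tobacco carry their published a-paths and
  mediator residual covariances (CM–neuroticism 80.89 etc.) but no
  direct outcome effect, so the two-mediator calibration and the
  four-mediator fit are mutually consistent.
- **CTQ subscales** partition the total exactly (weights 0.25/0.15/0.12/
  0.30/0.18 for emotional abuse/physical abuse/sexual abuse/emotional
  neglect/physical neglect, the neglect/emotional scales carrying the
  largest shares) with zero-sum noise, so total = Σ subscales wherever
  observed.
- **Missingness** defaults to MCAR at the observed per-variable rates
  (discovery: 341/1262 on CTQ; replication: 396/1740 on CTQ and
  234/1740 on cannabis); an MAR mechanism conditioned on a named
  covariate (logistic in its standardized value, intercept solved to
  preserve the marginal rate) is available, since the source states no
  mechanism.  Genetics, demographics and the outcome are never masked,
  mirroring the fully complete design of those fields.
- Scores are left continuous and unrounded by default (exact linear
  calibration takes precedence over instrument discreteness); integer
  rounding and range clipping are available behind a flag.

What the generator does **not** emulate: selective sampling of heavy
cannabis users, item-level questionnaire structure and floor effects
(real CTQ/CAPE scores are bounded counts with skew), site effects,
genuine LD-derived PRS structure, and any nonlinearity or interaction
(the paper's model is linear and so is the generator).  Passing tests
therefore demonstrate correctness of the estimation machinery under the
model's own assumptions, not robustness to their violation.

## Numerical and reproducibility conventions

- All randomness flows through `numpy.random.default_rng` seeds; the
  pipeline expands one master seed into per-stage seeds via
  `SeedSequence` spawning and records them in the run manifest.
  Identical (config, seed) gives byte-identical outputs.
- Singular designs raise; degenerate bootstrap resamples are skipped and
  counted; EM non-convergence is flagged on the fit object.
- Report formatting: 3 decimals for coefficients, 1 decimal for percent
  proportions.
- Simulation study sizes used by the test suite (the package's own
  choices, keeping the default run at desk scale): 200 cohorts of
  n=1262 for recovery/coverage and for the FIML-vs-listwise comparison
  (method-induced bias measured by pairing each incomplete-data fit with
  the complete-data fit of the same cohort — common random numbers);
  300 repetitions at 5000 replicates for null calibration of the BCa
  interval; a 4-point a-path grid with ten-fold upscaling, 5-percentile
  steps and 1000 replicates for the threshold scan.

## Limitations

- Binary mediators are modeled on the linear-probability scale;
  predicted probabilities are not constrained to [0,1].
- The sensitivity formula covers a single omitted confounder of one
  mediator–outcome pair at a time; no R²-parameterized version for
  nonlinear links.
- The FIML efficiency gain over listwise deletion is modest when the
  missing variable is the mediator itself (most of the information about
  a·b lives in the complete rows); unbiasedness, not efficiency, is the
  main benefit under MCAR.
- The per-variable missing-data fraction reported by `summarize` is the
  observed share of missing cells; "fraction of missing information" in
  the imputation-theoretic sense would require an imputation model and
  is not computed.
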