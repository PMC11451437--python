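# Methods

## The problem

Normative data turn a raw cognitive test score into a percentile relative
to demographically comparable healthy peers. The classical routes —
stratified means/SDs within age × sex × education cells, or z-scores from
the residuals of a demographic linear regression — both assume more than
web-collected cognitive data usually deliver: cell sizes large enough to
estimate every stratum, and Gaussian residuals. Error counts from tests
such as CANTAB's Paired Associate Learning or Spatial Working Memory are
heavily zero-inflated (many participants perform at ceiling), accuracy
indices pile up near their maximum, and scores are discrete, producing
ties.

`cognorm` implements a Bayesian alternative: fit a generalised linear
model with a response family that honestly represents the score's shape,
then simulate a large synthetic cohort from the posterior predictive
distribution at each age and read percentiles directly off it.

## Response families

Three families cover the six bundled outcomes:

- **beta** (mean–precision): scores on a bounded range rescaled to (0,1);
  mean `mu` with logit link, precision `phi > 0`. Used for RVP A′.
- **zero–one-inflated beta (zoib)**: point masses at the range
  boundaries — total boundary probability `zoi`, conditional probability
  `coi` that the boundary is the top — plus a beta interior. Used for
  PALTEA, PALFAMS, RVPPFA.
- **hurdle negative binomial**: point mass `hu` at zero plus a
  zero-truncated NB (mean `mu`, log link; dispersion `shape`) for positive
  counts. Used for SWMBE and SWMS (SWMS scores are the count plus its
  floor of 2).

Each subgroup model regresses only the location parameter on centred age,
`link(param) = b0 + b_age (age − 40)`, so `exp(b_age)` is a per-year odds
ratio (logit links) or incidence risk ratio (log link). Seven subgroup
models are fitted per outcome: all subjects, each sex, and each sex ×
education band. Auxiliary parameters (`phi`, `zoi`, `coi`, `shape`, `hu`)
are scalars by default. For the zoib family,
`NormativeGLM(..., inflation_on_age=True)` additionally places a
logit-linear age trend on `zoi`; this distributional-regression option is
what lets the probability of an exact ceiling score itself change with
age, which matters when analysing participants at ceiling (see
"Limitations").

Observed boundary values under the plain beta family (which has no
boundary mass) are nudged into the interior by 1e-6 with a warning;
posterior-predictive checks are computed against the un-nudged values so
boundary misfit remains detectable.

## Priors

- Age coefficients: normal(0, 5) on the link scale — proper and nearly
  flat over plausible per-year effects (|log ratio| < 0.1).
- Intercept: Student-t(3) centred on the link of the sample location
  (median of interior values, or mean positive count), scale 5.
- Positive auxiliary parameters (`phi`, `shape`): half Student-t with 3
  degrees of freedom, scale 10, the conventional weakly-informative
  default for positive scale-like parameters.
- Probability parameters (`zoi`, `coi`, `hu`): uniform Beta(1, 1).

All densities are evaluated on an unconstrained parameterisation (log for
positive, logit for probabilities) with the appropriate Jacobians.

## Sampling

Posteriors here have 3–6 parameters and, at cohort sizes in the hundreds,
are close to Gaussian, so the package ships a light-weight MCMC engine
rather than a full gradient-based sampler:

- **Independence Metropolis–Hastings (default)**: the posterior mode and
  inverse Hessian are found numerically (L-BFGS-B plus finite-difference
  Hessian); the proposal is a multivariate Student-t (df 7) at the mode
  with covariance inflated by 1.3. Acceptance rates are typically above
  0.7, giving an effective sample size close to half the nominal draw
  count.
- **Adaptive random-walk Metropolis (fallback)**: preconditioned by the
  same Laplace covariance, global scale adapted towards a 0.234
  acceptance rate during warmup. Used when the Laplace approximation is
  suspect.

The production configuration is 4 chains × 5,000 warmup + 5,000 sampling
iterations — 20,000 post-warmup draws. The test suite and the replicate
studies use a reduced 4 × 500/500 configuration; with the independence
sampler this still yields effective sample sizes in the hundreds, enough
for medians and 95% intervals at the precision those studies assert.
Convergence is gated on rank-normalised split R-hat (default threshold
1.01; 1.05 under the reduced configuration, reflecting the shorter
chains). Metropolis–Hastings kernels have no divergent transitions, so
the divergence count reported in diagnostics is structurally zero.

An ensemble-sampler cross-check (emcee) and a frequentist Laplace
calibration study are part of the development validation; the test suite
asserts that the engine reproduces the moments and tail quantiles of a
known Gaussian target and that 95% credible intervals cover generating
parameters at close to nominal rate.

## Model comparison

Pointwise log-likelihood matrices feed PSIS-smoothed leave-one-out
cross-validation (via ArviZ); observations with Pareto-k above 0.7 are
flagged, and an exact refit-LOO fallback is available (and serves as the
oracle in the test suite at n = 30). Comparing a count family against a
unit-interval family on the same integer-scored outcome is only coherent
on a common scale: `loo()` therefore also reports `elpd_common_scale`, in
which interior unit-interval densities are converted to approximate bin
masses (width 1/range). Boundary observations are point masses in both
candidates and need no adjustment.

## Norm tables

For each age 18–75, 20,000 posterior-predictive scores are simulated (one
per posterior draw, so parameter uncertainty and sampling noise both
enter) and inverted-CDF quantiles at 1% intervals become thresholds.
Percentile levels always report *goodness*: for error measures the k-th
level stores the (100−k)-th raw-score quantile. Inverted-CDF quantiles
are actual attainable sample values, which keeps tie bands meaningful for
discrete scores.

Tables are smoothed by recursive substitution across ages within each
level: any threshold moving against the expected age trend (performance
does not improve with age) is replaced by the previous age's value — a
running maximum for error measures, a running minimum for accuracy
measures. This is idempotent and only ever moves values with the trend.

Score lookup finds the contiguous band of levels whose threshold equals
the observed score (discrete ties) and reports the band midpoint rounded
up — a score tied across the 88th–99th levels reports the 94th
percentile. Scores beyond the extreme thresholds collapse to the 1st or
99th. No extrapolation outside the fitted age grid and no fractional
ages.

## Classical baselines

- **Stratified**: means and sample SDs (n−1) within the 6 age bands
  (18–24, 25–34, 35–44, 45–54, 55–64, 65–75) × sex × education band;
  z = (score − mean)/SD. Strata with fewer than 5 members or zero SD are
  flagged and refuse to norm.
- **Regression**: OLS of score on raw age, sex (male 0 / female 1) and
  education band (low 0 / high 1); one Cook's-distance screening pass at
  a 4/n default threshold (the reference procedure relied on visual
  inspection; 4/n is the standard rule of thumb and is configurable),
  removals logged, model refitted once; z = residual / residual SD.

Both convert to percentiles via the exact standard normal CDF after
flipping the sign of z for error measures, rounded and clipped to 1–99.

## Method comparison

A seeded random subsample (default 200) is scored under all three
methods; percentiles are cut at <25 / 25–75 / >75 (25 and 75 belong to
the middle range), and method × category tables are compared per
stratified age band with the Freeman–Halton (r × c) Fisher exact test:
complete enumeration while the number of margin-compatible tables is
below a budget (200,000), otherwise seeded Monte Carlo (100,000 tables
from the fixed-margin distribution). All-zero rows/columns are collapsed
first. Participants whose stratum cannot norm them, or whose age is
outside the table grid, are dropped from all three methods to keep the
design paired.

## Synthetic cohorts

The generator reproduces the *described* structure of the reference
sample, not its raw data (which are not deposited): n = 728, ages 18–75
from a truncated-geometric distribution whose decay is solved so that
P(age ≤ 40) = 0.63, sex ~51/49, 86% in the high education band (the low
band is education level 1 under the default mapping), education levels
within the high band skewed towards degrees. Scores are drawn from the
outcome's own family with a linear predictor on the link scale; per-year
age ratios default to the all-subjects point estimates of the reference
models (e.g. OR 1.015 for PALTEA errors, IRR 1.011 for SWM between
errors). Intercepts and auxiliary parameters are not published; the
bundled values were chosen once to reproduce the described score
distributions — a heavy skew towards zero PAL errors with mean ~13/70 at
age 40, SWM between-errors mean ~8, RVP A′ ~0.91 — and are frozen as the
package's reference fixtures.

Unit-interval draws for integer-scored outcomes are rescaled by the score
range and rounded half-away-from-zero; hurdle counts are shifted by the
outcome's floor and clipped to its ceiling. The original analysis never
states how integer scores were mapped to the unit interval;
division-by-maximum is this package's convention.

What the generator does *not* emulate: measurement-level dependence
between outcomes within a participant (scores are drawn independently
given demographics), device or attention effects, missingness patterns,
and cross-regional composition. Passing tests therefore demonstrate that
the machinery recovers known structure of this synthetic form, not that
the bundled fixtures describe any real population.

## Recovery studies and problem sizes

`cognorm.validation` runs the replicate studies used by the tests and the
acceptance script: 20 seeded replicates of n = 728 cohorts per family,
fitted with the reduced sampler; the zoib study targets the PALTEA
all-subjects odds ratio (1.015), the hurdle study the SWM between-errors
incidence risk ratio (1.011), and the OLS study the linear-model age
slope (0.20, residual sd 11.3 chosen to reproduce the reported
standard-error scale of 0.03 at n = 728). All randomness flows from one
master seed through named substreams.

The zoib recovery fixture stays on the continuous unit interval: pushing
draws through an integer grid and back contaminates the boundary masses
(interior values rounding to exact zeros) and would test the rounding
convention rather than the estimator. The integer pipeline is exercised
separately by the generator and norm-table tests.

## Numerical choices

- Tie convention in posterior-predictive p-values:
  p = (#{rep > obs} + 0.5·#{rep = obs})/R, so an exact tie reports 0.5.
- Age centring at 40 years (near the sample mean age of ~38) makes
  intercepts interpretable mid-sample; recorded in fit metadata.
- Hessians are symmetrised and checked for positive definiteness via
  Cholesky, with a diagonal-curvature fallback.
- `log(1 − exp(v))` uses the split `log1p(−exp v)` / `log(−expm1 v)` form.
- Fisher enumeration treats tables whose probability is within a 1e-9
  relative tolerance of the observed table's as ties (included in p).

## Limitations

- With age-constant inflation parameters (the default), the percentile of
  a score exactly at a range boundary cannot vary with age; analyses of
  ceiling performers should enable `inflation_on_age`.
- The independence sampler presumes a roughly unimodal, light-tailed
  posterior; genuinely multimodal posteriors would need the random-walk
  fallback or an external sampler.
- Norm tables carry Monte Carlo noise of order 1/sqrt(20,000) per
  threshold; extreme levels (1st, 99th) are the noisiest.
- The three families are the package's full repertoire by design; no
  Gaussian or zero-inflated Poisson alternatives are offered.
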