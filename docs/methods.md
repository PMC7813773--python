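# Methods

## The estimation problem

Mortality surveillance asks whether the death count observed in a recent
month is compatible with "normal" conditions. The package answers this
with a counterfactual baseline: a regression model fitted only to
pre-crisis months predicts what each post-cutoff month would have looked
like, and the observed count is compared with a *prediction* interval —
an interval for a future observation, not for its mean — so both
parameter uncertainty and count-level noise enter the width.

The motivating application is monthly suicide counts in Japan around the
early COVID-19 period: training on January 2013 – February 2020 (86
months) and predicting March – June 2020, stratified by sex, sex × age
band, and prefecture, with the national unemployment rate (current and
one-month lag) carrying short-run economic conditions.

## Model and fitting

For one stratum, counts are overdispersed Poisson:

    log mu_t = b0 + bY*(year_t - c) + bM(month_t) + bU1*u_t + bU2*u_{t-1}
               + log(pop_t),          Var(y_t) = psi * mu_t

- **Month effects.** Eleven indicators (February–December); January is the
  reference and its effect is fixed at zero.
- **Year trend.** `year_t` is the calendar year centered at the training
  start (`c` = 2013 by default). Centering only relabels the intercept —
  fitted means and predictions are invariant — but avoids a poorly scaled
  column (~2016) under the log link.
- **Offset.** `log(pop_t)` converts the model to a per-person rate. Units
  (persons or ×10,000) shift only the intercept and are recorded in panel
  metadata.
- **Unemployment.** Treated as an opaque covariate in percent; whether a
  seasonally adjusted series is used is the caller's choice. Prefecture
  strata share the national series. The covariate file must include one
  month before the first count month so the lag exists at t = 1 (December
  2012 for a January 2013 start); this preserves the full 86-month
  training window instead of dropping its first observation.

Coefficients are Poisson maximum likelihood, computed by IRLS. Since the
quasi-likelihood score equations coincide with the Poisson ones, the
point estimates are identical under either family; only the covariance
changes. Numerical choices:

- convergence when the relative change in Poisson deviance is below
  1e-10, capped at 100 iterations;
- steps that would increase the deviance are halved (up to 30 times), so
  the recorded deviance path is non-increasing;
- rank is checked by SVD with a relative threshold of 1e-8; a deficient
  design raises an error naming the collinear columns (a constant
  unemployment path is the common cause: `u_t`, `u_{t-1}` and the
  intercept become collinear).

Dispersion is the Pearson moment estimator
`psi_hat = sum (y - mu_hat)^2 / mu_hat / (n - p)` with p = 15. The
coefficient covariance is `psi_used * (X'WX)^{-1}`, W = diag(mu_hat).
When `psi_hat < 1` (strictly — exactly 1 stays quasi-Poisson) the
classical Poisson model is used: `psi_used = 1`. Underdispersion is not
modelled.

## Prediction intervals

The interval follows the simulation approach of Gelman and Hill:

1. draw `n_draws` coefficient vectors from `N(b_hat, psi*(X'WX)^{-1})`
   (flat-prior normal approximation; no MCMC);
2. for each draw and held-out month, form `mu = exp(x'b + offset)` and
   draw one count: Poisson(mu) if `psi_used = 1`, otherwise gamma-Poisson
   with gamma shape `mu/(psi-1)` and scale `psi-1`, whose marginal
   variance is exactly `psi*mu` (the NB1 parameterization);
3. the equal-tailed interval takes the k-th smallest draw with
   `k = ceil((1∓level)/2 * N)` (a 1e-9 epsilon inside the ceiling guards
   against float noise in `(1-level)/2`). Bounds are integers because
   draws are counts.

Choices made where the procedure was genuinely open:

- **NB1, not NB2**, is the predictive noise: it reproduces the assumed
  variance `psi*mu` exactly and yields integer draws. NB2
  (`Var = mu + mu^2/k`) would tie the variance ratio to the mean level.
- **Per-month intervals from one shared set of joint coefficient draws.**
  A family-wise (max-t style) simultaneous band over the four months is
  deliberately not implemented; published tables of this kind report
  per-month bounds.
- Defaults: `n_draws = 10,000`, level 0.95, seed mandatory. At 10,000
  draws the Monte-Carlo jitter on a bound is a few counts at mu ≈ 1,000.

The point prediction `y_tilde = exp(x'b_hat + offset)` uses the
estimates, not the draw mean, so it need not sit at the interval center.

## Excess metrics

`excess = y - y_tilde`, `relative difference = 100*(y - y_tilde)/y_tilde`.
Flags: `below` iff `y < lower`, `above` iff `y > upper`, else `within` —
**ties at a bound count as within** (strict inequality; the convention is
documented here because published tables mark only strict exceedances and
do not reveal their tie rule). `exceedance_beyond_bound` returns how far
outside the interval an observation lies (0 when within), so flag and
exceedance are mutually consistent by construction. Table output rounds
predicted/excess/relative difference to one decimal for display only;
all comparisons use unrounded values.

## Sensitivity to the covariate path

Crisis-era unemployment is itself affected by the crisis, so the
prediction-time covariates can smuggle the shock into the baseline. The
sensitivity analysis replaces `u_t` with a fixed pre-crisis value (2.4%,
the February 2020 national rate, is the motivating case) for every month
from a cutoff onward — read as "from March 2020 onward"; an April-onward
reading is available through the cutoff parameter. The lag term of the
cutoff month still reads the actual prior-month value, and only months at
or after the cutoff are substituted (substituting the cutoff month's lag
is a defensible alternative; it is not done here). Training is never
re-run: a cutoff at or before the training end raises an error. Both arms
share the simulation seed, so reported deltas reflect the covariate path
alone.

## Synthetic data

The generator forward-simulates the fitted model's exact structure —
log-linear year trend, 11 month effects, unemployment at lags 0 and 1, a
population offset, NB1 noise — plus a stationary AR(1) unemployment path
(clipped to [0, 100]; clips are counted) and an optional multiplicative
"pandemic" shift on mu from a cutoff month, used to test detection power.

Defaults (arbitrary, chosen once so synthetic tables resemble national
male suicide totals of the 2010s): constant population 6.13e7 persons,
`b0 = -10.62` (≈1,500 deaths/month at the 2013 level), `bY = -0.02`/year
(declining trend), spring-peaked month effects within ±0.10,
`bU1 = 0.05`, `bU2 = 0.02` per percentage point, `psi = 1.5`,
unemployment AR(1) with mean 2.7%, coefficient 0.8, innovation sd 0.15%.
The companion female stratum uses `b0 = -11.83` at 6.46e7 persons
(≈470/month).

What the generator does *not* emulate: real Japanese demography or
prefecture heterogeneity, calendar artifacts (working days, holidays),
autocorrelated count residuals beyond what the covariates induce, reporting
delays, or structural breaks in seasonality. Passing tests therefore show
the method is correct and calibrated *under its own assumptions*; they do
not show the baseline model is adequate for any particular real series.

## Validation results the code computes

`recovery_experiment` repeatedly generates a panel, fits on the first 86
months, and predicts the next 4 with fresh simulation seeds spawned per
replicate. With the defaults above (500 replicates, 10,000 draws,
psi = 1.5) the held-out coverage of the nominal 95% interval lands within
a percentage point of 95%, coefficient biases for the trend and
unemployment effects are within two Monte-Carlo standard errors of zero,
and the Pearson dispersion concentrates near truth. A 30% drop imposed on
the held-out months is flagged `below` in essentially every replicate at
the ~1,500-count level. These problem sizes (500 replicates × 10,000
draws) are the package's validation defaults and run in seconds.

## Known limitations

- The normal approximation to the coefficient posterior can be optimistic
  at much shorter training windows or very small counts (rural
  prefecture × age cells); coverage there should be re-checked with the
  recovery harness at the intended n.
- One dispersion parameter per stratum, constant over time.
- No autocorrelation in the count process given covariates; no
  alternative families (negative-binomial ML, zero inflation), splines,
  or shrinkage across strata — strata are fitted independently.
- The order-statistic interval is equal-tailed per month; no joint
  multiple-comparison control across months or strata.
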