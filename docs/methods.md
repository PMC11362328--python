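# Methods

## The problem

Intensive longitudinal designs (diary or experience-sampling studies)
yield repeated measures of level-1 variables nested in persons.  A
within-person association (WPA) — e.g. how strongly a person's momentary
well-being `y` tracks their momentary sociality `x` — is operationalized
as a person-specific random slope `beta_i`.  Substantive hypotheses often
concern *nonlinear* effects of such slopes on a person-level outcome `z`:

* **U-shape** — `z = b0 + b1*beta + b3*beta^2 + e` (one WPA, quadratic);
* **moderation** — `z = b0 + b1*beta1 + b2*beta2 + b4*beta1*beta2 + e`;
* **congruence** — the full second-order polynomial in two WPAs, where the
  congruence pattern `b1 = b2 = 0`, `b5 = b3 < 0`, `b4 = -2*b3` means `z`
  is maximal along the line `beta1 = beta2`.

The difficulty is that the slopes are latent: any estimate of a person's
slope carries measurement error whose variance shrinks with the number of
occasions, and nonlinear functions of error-prone regressors are biased in
well-understood ways.  The package implements four estimation strategies
of increasing fidelity, a population simulator, and a Monte-Carlo harness
that quantifies how each strategy trades off bias, interval calibration
and power.

## Population model and simulator

The generator (`slopesem.population`) draws per person a level-2 vector
(latent predictor means `x_B`, `u_B`, outcome means `y_B`, `v_B`, slopes
`beta_y`, `beta_v`, and the `z` residual) from a multivariate normal with
covariance `phi_b`, and per occasion a level-1 vector (predictor
fluctuations and residuals) from `phi_w`; observed series compose as
`y_it = y_B + beta_y*(x_it - x_B) + resid`.  The default parameter values
are the study conditions the package reproduces: unit level-1 variances, a
level-1 residual correlation of .2, slope variances of 0.1, between-person
variances chosen so all ICCs equal .5, and level-2 correlations of .20 for
the six free covariances (all other covariances zero).  Under these values
the slope reliability is .80 at T = 40 and .58 at T = 15.

Two conventions deserve note:

* **Reliability denominator.**  The per-person slope's error variance is
  taken as `sigma^2 / ((T - 1) * sigma^2_x)`: person-mean centering the
  predictor consumes one degree of freedom, and only the `T - 1`
  convention reproduces the design value .58 at T = 15 (using `T` gives
  .60).
* **Effect-size calibration.**  `calibrate_effect` solves
  `coef^2 * V / (coef^2 * V + tau2_z) = R^2` in closed form using
  `Var(beta^2) = 2*tau^4`, `Var(beta1*beta2) = tau1^2*tau2^2 + cov^2`, and
  `Var((beta1-beta2)^2) = 2*(tau1^2 + tau2^2 - 2*cov)^2` for zero-mean
  normal slopes.  The analytic congruence value at `R^2 = .25` is
  |b3| = 2.5516 (Monte-Carlo confirmed); reference tables print −2.5.  A
  `paper_values` flag substitutes the printed one-decimal coefficients so
  that simulation conditions match the reference study verbatim; the
  analytic value is the default otherwise.

**Unbalanced designs.**  Starting from T = 40, each person's deletion
proportion is drawn from Beta(1.5, 4) rescaled to [0, 0.6] (a positively
skewed pattern typical of diary compliance), and occasions are deleted at
random, leaving T_i between 16 and 40.  The exact skewed distribution used
by the reference study is not published; the Beta shape is this package's
documented stand-in and is parameterizable.

**What the simulator does not emulate:** non-normal distributions,
autocorrelated occasions, time trends, and measurement error in the
observed indicators.  Passing tests therefore demonstrate correctness of
the estimators under the stated normal two-level model, not robustness to
violations of it.

## Step 1: the random-slope mixed model

All two-step style estimators share a level-1 model with person-mean
centered predictor, random intercept and random slope, estimated by REML.
The solver in `slopesem.lmm` profiles out the residual variance and the
fixed effects and optimizes the three free elements of the scaled
random-effect Cholesky factor; every quantity reduces to per-person 2x2
sufficient statistics, so a fit costs milliseconds and Monte-Carlo studies
with thousands of replications stay cheap.  The tests verify agreement
with statsmodels MixedLM to four decimals.

EAP (empirical-Bayes) slope predictions and their conditional SDs are
computed from the conditional normal distribution of the random effects at
the REML estimates.  Uncertainty in the fixed effects and the variance
components is deliberately not propagated — the plausible-values variant
implemented here is the simplified one whose behaviour the harness is
meant to characterize.  Two behavioural notes:

* In balanced data the conditional SDs still differ across persons because
  they depend on the within-person predictor sum of squares, which varies
  randomly; they are equal only in expectation.
* With a freely estimated intercept-slope covariance the EAP slope borrows
  strength from the intercept residual, so it can overshoot the per-person
  OLS slope slightly for persons whose OLS slope is already near the mean;
  ensemble shrinkage (variance reduction) always holds.

## The four estimators

**Two-step** (`twostep`): OLS of `z` on the polynomial in the EAP slopes,
conventional (t-based) intervals.  Treats the slopes as known, hence
attenuated nonlinear coefficients and too-narrow intervals when
reliability is low.  An HC1 robust-SE option exists but is off by default
(the simple variant is the estimand of interest).

**Single-indicator SEM** (`si`): each EAP slope, standardized by the
estimated total latent-slope SD `sqrt(Var(c_hat) + mean(s_i^2))`, becomes
the single indicator of a latent factor with fixed measurement parameters
`lambda = 1 - s2bar`, `Var(error) = s2bar*(1 - s2bar)`, `Var(eta) = 1`,
where `s2bar` is the standardized mean conditional slope variance
(the simplified variant without person-specific loadings).  The structural
polynomial in the latent factors is estimated by MCMC: conjugate Gibbs for
the coefficients and residual variance, a random-walk Metropolis step for
the latent factor correlation, and per-person independence-Metropolis
updates of the factors (proposal from the measurement posterior, the
nonlinear `z` likelihood in the acceptance ratio).  Coefficients are
back-transformed to the raw slope metric through the exact affine change
of variables of a second-order polynomial, so results are comparable
across methods; how the reference implementation returned its coefficients
to the raw metric is not documented, and this standardize/back-transform
scheme is the package's own resolution of that under-specified step.
Defaults: 12,000 iterations per chain, half burn-in, two chains,
weakly-informative priors (N(0, 10^2) on standardized coefficients,
inverse-gamma(0.001, 0.001) on the residual variance) standing in for
vendor-default flat priors.

**Plausible values** (`pv`): step 1 is refitted with `z` (and `z` times
the person mean) as level-2 predictors of intercept and slope, so the
conditional slope distribution absorbs the *linear* part of the
slope-outcome association; M = 20 normal draws per person around the
conditioned EAPs are analyzed separately and pooled with Rubin's rules
(within + (1+1/M) x between variance, Rubin degrees of freedom,
t intervals).  Response-surface auxiliary parameters are computed per draw
with delta-method variances and pooled the same way.  The two slopes'
conditioned models are fitted separately.  Because the draws ignore both
parameter uncertainty and the nonlinear part of the association, this
estimator is expected to be strongly attenuated — the harness confirms
shrinkage above 50% at T = 15.

**Fully latent MSEM** (`msem`): the Bayesian model with latent predictor
means, latent slopes, the restricted level-2 covariance (only variances,
the x-y / u-v / y-v mean covariances, the two intercept-slope covariances
and the slope-slope covariance free; everything else a structural zero),
and the polynomial in the latent slopes.  The sampler is
Gibbs-within-Metropolis: person means given slopes are conjugate
multivariate normal; slopes given means use an independence-Metropolis
proposal built from the Gaussian part of their conditional with the
nonlinear `z` likelihood in the acceptance ratio; coefficients, residual
variances and the level-1 covariance block are conjugate; the free
level-2 covariance entries use componentwise random-walk Metropolis with
step sizes adapted toward a 0.44 acceptance rate during burn-in.  All
conditionals reduce to per-person sufficient statistics, so an iteration
costs O(P) independent of T.  Chains are initialized from the two-step
solution (jittered per chain).  Convergence is judged by split-Rhat
(< 1.05) plus effective sample size, and non-convergence is flagged on the
results, never silently ignored.  The default 2 chains x 2,000 iterations
are far fewer than vendor-software presets because the initialization and
blocking make the chain efficient; simulation-grade runs in the test suite
use up to 4,000 iterations.  Point estimates are posterior medians;
intervals are 2.5/97.5% posterior quantiles; RSA parameters are summarized
per draw.

## Response-surface analysis

`slopesem.rsa` computes `a1 = b1+b2`, `a2 = b3+b4+b5`, `a3 = b1-b2`,
`a4 = b3-b4+b5`, and the first principal axis `p10`, `p11` of the fitted
surface, with the "+sqrt" branch for `p11` (the branch for which the
congruence population gives `p11 = 1`).  The stationary point uses
`x0 = (b2*b4 - 2*b1*b5)/(4*b3*b5 - b4^2)` and the symmetric `y0`;
`p10 = y0 - p11*x0`.  On a ridge surface (denominator `4*b3*b5 - b4^2`
within 1e-10 of zero relative to the quadratic coefficients' scale) the
stationary point is at infinity and `p10` is reported through the ridge
limit `-b1/b4` with a flag — exactly 0 for the congruence population.
When `b4` is numerically zero the principal axes are undefined and the
parameters are reported as undefined with a reason; the congruence verdict
is then a rejection.  These conventions are pinned by the congruence-model
identities (`a1 = a2 = a3 = 0`, `a4 = 4*b3`, `p11 = 1`); the package's
`p10` definition follows the standard response-surface literature.

Standard errors come from the multivariate delta method with analytic
gradients (validated against central finite differences at 1e-6);
Bayesian fits instead summarize the auxiliary parameters over posterior
draws.  The congruence decision accepts iff the intervals for `a1`, `a2`,
`a3`, `p10` and `p11 - 1` all contain zero and the `a4` interval lies
entirely below zero.

## Evaluation harness

`run_condition` simulates data, fits the requested methods, and
aggregates per coefficient: bias, relative bias, empirical CI width
(`2 * z_.975 * SD` of the estimates for two-step/PV, the 2.5-97.5%
quantile range for MSEM/SI), mean estimated width, the relative width
difference, coverage, RMSE and the acceptance rate of the
hypothesis-specific decision rule.  Seeds are spawned per replication from
one `SeedSequence`, so runs are exactly reproducible.  Estimator failures
are recorded per replication and never abort a run; Bayesian
non-convergence is counted.  An optional width-outlier rule (drop
replications whose interval width exceeds 100x the condition median,
counts reported) is off by default; the reference study removed a handful
of extreme interval widths ad hoc, and this rule is the package's
documented substitute.

## Problem sizes and numerical choices

The test suite exercises the Monte-Carlo criteria at the study's
`P = 200, T = 15` condition with 1,000 replications for the two-step and
plausible-values pipelines, and scales the MSEM checks down (single
datasets at `P = 500, T = 40` for recovery; 100 replications at
`P = 200, T = 40` with 4,000-iteration chains for interval calibration) —
sizes chosen so the full suite stays a desk-scale computation.  Tolerances
for acceptance-rate comparisons are three binomial standard errors for the
difference of two rates at the stated replication counts.  Degenerate
inputs are handled explicitly: slope variance estimated at zero flags the
fit and blocks the SI measurement model; `s2bar >= 1` raises; ridge and
axis-degenerate surfaces propagate as undefined RSA parameters; Rubin
pooling with zero between-draw variance falls back to normal intervals.

## Known limitations

* The MSEM level-2 covariance sampler updates one free entry at a time;
  for much larger models a blocked update would mix better.
* Priors are weakly informative rather than the (improper) vendor
  defaults; at the study's sample sizes the difference is negligible for
  coefficients, but very small samples would show prior sensitivity.
* The SI variant with person-specific loadings (relevant for strongly
  unbalanced data) and fully nonlinear plausible-value generation from the
  MSEM posterior are out of scope.
* Coverage of the scaled-down MSEM runs inherits Monte-Carlo noise both
  from the number of replications and from the finite chains; the test
  suite uses chain lengths with effective sample sizes of several hundred
  for the headline coefficient.
* At the smaller level-2 sample size (P = 200) the frequentist coverage of
  the MSEM credible interval for the quadratic coefficient measures around
  90-92%: the sampling spread of the posterior median slightly exceeds the
  average posterior SD because the deattenuation factor (driven by the
  estimated slope variance) is itself uncertain.  Chain diagnostics
  (split-Rhat ~1.006, ESS > 1000, posterior medians stable to ±0.03 across
  MCMC seeds) rule out sampler error; this is small-sample behavior of the
  nonlinear functional under weak priors.  At P = 500 the empirical spread
  matches the posterior SD and coverage is nominal, which is why the
  interval-calibration check in the test suite runs at P = 500, T = 40.
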