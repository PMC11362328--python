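# slopesem

Estimating **nonlinear effects of latent random slopes** on person-level
outcomes: a simulator, four estimators, and a Monte-Carlo evaluation
harness for intensive longitudinal (diary / experience-sampling) designs.

## The problem

A within-person association (WPA) — say, how strongly person *i*'s
momentary well-being `y_it` responds to fluctuations in their sociality
`x_it` — is a person-specific random slope `β_i` in the two-level model

    x_it = x_Bi + x_Wit
    y_it = y_Bi + β_i · x_Wit + ζ_it .

Psychological hypotheses frequently concern *nonlinear* effects of such
slopes on a person-level outcome `z_i` (life satisfaction, adjustment):

| hypothesis | level-2 structural model |
|---|---|
| U-shape | `z = b0 + b1·β + b3·β² + ε` |
| moderation | `z = b0 + b1·β₁ + b2·β₂ + b4·β₁β₂ + ε` |
| congruence | `z = b0 + b1·β₁ + b2·β₂ + b3·β₁² + b4·β₁β₂ + b5·β₂² + ε`, with `b1=b2=0`, `b5=b3<0`, `b4=−2b3` |

Because the slopes are latent and estimated with person-specific error,
plugging slope estimates into a polynomial regression attenuates the
nonlinear coefficients and understates uncertainty.  The package
implements four strategies:

* **`TwoStepModel`** — EAP (empirical-Bayes) slopes from a REML mixed
  model, then OLS; simple, biased toward zero, too-narrow intervals.
* **`SingleIndicatorSEM`** — each slope estimate becomes the single
  indicator of a latent factor with reliability-derived loading
  `λ = 1 − s̄²` and error variance `s̄²(1 − s̄²)`; the polynomial is
  estimated in the latent metric by MCMC and back-transformed.
* **`PlausibleValuesModel`** — slope draws from the outcome-conditioned
  mixed model, per-draw polynomial fits, Rubin's-rules pooling.
* **`LatentSlopeMSEM`** — the fully latent Bayesian multilevel SEM with
  restricted level-2 covariance, estimated by a Gibbs-within-Metropolis
  sampler written for this model.

Congruence hypotheses are judged by response-surface analysis
(`slopesem.rsa`): auxiliary parameters `a1…a4`, principal axis
`p10`, `p11`, delta-method or posterior intervals, and the six-condition
decision rule (`a1=a2=a3=p10=p11−1=0`, `a4<0`).

## Worked example

Simulate the large U-shape condition (500 persons, 40 occasions,
quadratic effect explaining 25% of the outcome variance, i.e. `b3 = −4.1`)
and compare the naive two-step fit with the latent MSEM:

```python
import slopesem as ss

spec = ss.PopulationSpec(P=500, T=40, hypothesis="ushape",
                         r2_target=0.25, paper_values=True, seed=7)
data = ss.simulate(spec)

print(ss.TwoStepModel(data, "ushape").fit().summary())
print(ss.LatentSlopeMSEM(data, "ushape", iterations=2000).fit(seed=3).summary())
```

prints

```
Level-2 polynomial (quadratic), method=twostep, n=500
  b0  -0.1665  [-0.2778, -0.0551]
  b1  -0.4186  [-0.7556, -0.0816]
  b3  -3.7002  [-4.4756, -2.9247]
r_squared=0.1545972679709029, step1_converged=True

Level-2 polynomial (quadratic), method=msem, n=500
  b0  -0.0411  [-0.1628,  0.0721]
  b1  -0.4828  [-0.8411, -0.1278]
  b3  -4.1377  [-5.0276, -3.2874]
rhat_max=1.0172571733706381, converged=True, accept_beta=0.875459

MCMC: max Rhat 1.017, converged=True, accept(beta)=0.88
              tau2_x  median  0.9811  [ 0.8744,  1.1217]
              tau2_y  median  1.0424  [ 0.9165,  1.1716]
         tau2_beta_y  median  0.1005  [ 0.0863,  0.1158]
              tau_xy  median  0.2098  [ 0.1210,  0.2957]
        tau_y_beta_y  median  0.0800  [ 0.0498,  0.1133]
              tau2_z  median  0.9883  [ 0.8567,  1.1312]
            sigma2_x  median  0.9855  [ 0.9657,  1.0050]
            sigma2_y  median  0.9980  [ 0.9776,  1.0189]
```

Reading the output: the two-step estimate of the curvature (`b3 = −3.70`)
is attenuated by about 10% relative to the generating value −4.1 — the
slope reliability at T = 40 is .80 — while the latent MSEM recovers it
(`−4.14`, credible interval covering −4.1) together with the population
variance components (slope variance 0.1, between-person variances, unit
level-1 variances).  At T = 15 (reliability .58) the two-step attenuation
roughly doubles and the plausible-values estimator loses about two thirds
of the effect; `slopesem.evaluate.run_condition` reproduces those
patterns, with power, false-positive rates, coverage and interval-width
calibration per method.

A thin CLI covers the same workflows:

```bash
slopesem simulate --hypothesis congruence -P 200 -T 15 --seed 1 --out demo/
slopesem fit --method twostep --model congruence --data-dir demo/
slopesem evaluate --hypothesis ushape --r2 0.25 -P 200 -T 15 \
         --methods twostep,pv --reps 200 --seed 1 --out metrics.csv
```

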