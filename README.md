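# wl2reg

Regression modelling for **positive, right-skewed response variables** —
house prices, medical costs, insurance claims, concentrations — built on a
mean parametrization of the weighted Lindley distribution (here called
**WL2**). The package provides the distribution itself (density, cdf,
quantiles, random variates), maximum-likelihood regression on the mean with a
log link, a gamma-regression baseline, residual and model-comparison
diagnostics, and a Monte-Carlo study of estimator quality. It is aimed at
applied statisticians who would otherwise reach for a gamma GLM and want a
more flexible two-parameter alternative on the same workflow.

## The model

The weighted Lindley distribution has density

```
f(y; θ, α) = θ^(α+1) / ((θ + α) Γ(α)) · y^(α−1) (1 + y) e^(−θy),   y > 0,
```

with rate θ > 0 and shape α > 0; it reduces to the Lindley distribution at
α = 1 and is the two-component gamma mixture
`p·Gamma(α, θ) + (1−p)·Gamma(α+1, θ)` with `p = θ/(θ+α)`. Its mean is
`μ = α(θ+α+1) / (θ(θ+α))`. Solving that equation for α,

```
α(θ, μ) = ( θ(μ−1) + sqrt(θ²(μ+1)² − 2θ(μ−1) + 1) − 1 ) / 2,
```

re-parametrizes the family by (θ, μ) — the WL2 distribution — so the mean can
be regressed on covariates through a log link:

```
Y_i ~ WL2(θ, μ_i),     log μ_i = x_iᵀ β.
```

(β, θ) are estimated by maximizing the log-likelihood (Nelder–Mead over
(β, log θ)); standard errors come from the numerically differentiated
observed information. Model adequacy is checked with Cox–Snell residuals
`ê_i = −log(1 − F(y_i; θ̂, μ̂_i))`, which are unit-exponential when the model
is right; non-nested comparison against the gamma baseline uses the Vuong
statistic, and overall covariate significance a deviance-based F test.

## Worked example

Everything is reproducible from a seed; no external data is needed. Generate
a 414-row synthetic dataset (two uniform covariates, log-linear mean,
WL2 noise), fit, and compare models:

```sh
wl2reg fixture --n 414 --seed 11 --out demo.csv
wl2reg fit --data demo.csv --response y --covariates x1,x2 --model wl2
```

prints

```
WL2 regression  (n = 414, log-likelihood = -639.7278)
AIC = 1287.4556   BIC = 1303.5591   converged = True
parameter         estimate     std.err         z     p-value
(intercept)        0.49452     0.05840     8.467    2.51e-17
x1                 0.49244     0.07326     6.722    1.79e-11
x2                 0.51046     0.07352     6.943   3.837e-12
theta              1.85663     0.12480    14.876   4.695e-50
```

The generating truth was β = (0.5, 0.5, 0.5), θ = 2: every estimate is within
about one standard error of it, and each coefficient's Wald z/p-value shows
the covariates are (correctly) highly significant. `wl2reg compare` runs the
full pipeline — both models, Cox–Snell/KS diagnostics, Vuong, F test — and on
the same data reports WL2 ahead of the gamma baseline (AIC 1287.5 vs 1298.3;
Vuong statistic 1.816 in WL2's favour, one-sided p = 0.035), a healthy
residual KS p-value of 0.795, and F = 13.67 for the joint significance of the
two covariates.

The same machinery is available as scikit-learn estimators:

```python
from wl2reg import WL2Regressor
est = WL2Regressor().fit(X, y)      # X without intercept column
est.coef_, est.intercept_, est.theta_, est.se_, est.aic_
mu_hat = est.predict(X_new)
```

## Monte-Carlo study

`wl2reg simulate` re-runs the estimator-quality experiment: for each sample
size it repeatedly draws x1, x2 ~ U(0,1), sets μ_i = exp(0.5 + 0.5x1 + 0.5x2),
samples y ~ WL2(2, μ_i), refits, and tabulates the average estimate, bias and
MSE per parameter (default 250 replications; `--full` for 1000).

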