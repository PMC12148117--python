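# Methods

## The WL2 distribution

The weighted Lindley family `f(y; θ, α) ∝ y^(α−1)(1+y)e^(−θy)` is handled
exclusively through its two-gamma mixture representation: with
`p = θ/(θ+α)`, the density is `p·Gamma(α, θ) + (1−p)·Gamma(α+1, θ)` (rate
parametrization). This gives the cdf for free in terms of the regularized
lower incomplete gamma function `P(a, θy)` — no quadrature is ever needed —
and an exact, fast sampler by composition (draw the component, then a gamma
variate). Inverse-transform sampling is retained as a second path
(`method="inverse"`) and is used in tests as a distributional cross-check of
the default sampler.

The mean parametrization replaces α by the mean μ through

    α(θ, μ) = ½ ( θ(μ−1) + √(θ²(μ+1)² − 2θ(μ−1) + 1) − 1 ).

The discriminant is strictly positive for every θ, μ > 0 (as a quadratic in θ
its own discriminant is −16μ < 0), so α(θ, μ) is well defined and smooth on
the whole parameter space; property tests assert this together with the exact
mutual inversion of the mean equation and α(θ, μ).

Numerical choices:

* All density evaluation is in log space via `gammaln`; Γ(α) is never formed
  (it overflows near α ≈ 170).
* `logpdf` has a `strict` flag: strict mode raises on y ≤ 0 (user-facing),
  non-strict mode returns −∞ (used inside likelihoods so that optimizer
  proposals at the boundary are rejected by value rather than by exception).
* Quantiles solve `F(y) = u` by Brent's method on the bracket
  `[0, μ + 20σ]`, doubled geometrically until it straddles the root;
  tolerance 1e−14 on y, which holds |F(result) − u| well below 1e−10.
* For extremely small θμ the implied α can underflow; it is clamped at 1e−12
  with a `RuntimeWarning`. The distribution is essentially degenerate there
  and no supported workflow reaches that corner.

## Regression and estimation

Both regressions use a log link, `μ_i = exp(x_iᵀβ)`, with one global
auxiliary parameter: the WL2 rate θ, or the gamma shape ν (density
`Gamma(ν, ν/μ_i)`, so Var = μ²/ν). The WL2 log-likelihood is the sum of WL2
log-densities; written out,

    ℓ(θ, β) = Σ_i [ (α_i+1)log θ − log(θ+α_i) − log Γ(α_i)
                    + (α_i−1)log y_i + log(1+y_i) ] − nθȳ,

with α_i = α(θ, μ_i). The sign of the log Γ term is negative — it comes from
the log of the density — and the single-observation spot value
ℓ(θ=1, μ=1.5; y=1) = −1 pins it down in the tests.

Optimization is Nelder–Mead over (β, log θ): the auxiliary parameter is kept
on the log scale so the simplex can never leave the parameter space
(unconstrained NM on a positivity-constrained coordinate is fragile).
Function/parameter tolerance 1e−8, at most 5000 iterations, and one automatic
restart from the incumbent; a perturbed-start test verifies the optimum is
re-found to 1e−4 in log-likelihood from ±50% displaced initial values.
Initial values: gamma coefficients from an OLS fit to log y, refined by the
gamma ML fit; WL2 coefficients from that gamma fit; log θ from the Lindley
(α = 1) method-of-moments solution of ȳ = (θ+2)/(θ(θ+1)). Non-finite
likelihood values are returned to the optimizer as −∞ (never raised).

Standard errors: the observed information is the negative Hessian of ℓ at the
optimum, computed by central finite differences on the internal (β, log θ)
scale with step `eps^(1/3)·max(1, |param|)` (statsmodels' `approx_hess3`
kernel); its inverse is mapped to the natural θ scale by the delta method,
so the reported SE(θ̂) is on the natural scale. Wald z statistics use the
standard normal reference. AIC = 2(k+2) − 2ℓ and
BIC = (k+2)log n − 2ℓ count the k+1 coefficients plus the auxiliary
parameter.

The gamma fit's coefficients coincide with the GLM/IRLS solution (the gamma
score equations for β do not involve ν); the test suite exploits this by
checking the full-ML fit against statsmodels' GLM plus a one-dimensional
profile over ν.

## Diagnostics

* **Cox–Snell residuals** `ê_i = −log(1 − F(y_i))` under the fitted model,
  tested against the fully specified Exp(1) with a one-sample KS test — no
  correction for parameter estimation is applied, which makes the test
  slightly conservative (estimation pulls the residuals toward Exp(1)); the
  calibration test bounds the empirical size at n = 300 by 7% at the 5%
  level. PP coordinates are `i/(n+1)` versus `1 − exp(−ê_(i))`. Fitted
  probabilities at the numerical upper tail (F ≥ 1 − eps) are clamped with a
  warning.
* **Vuong test** for non-nested models: `m_i` is the per-observation
  log-density difference (model 1 minus model 2), `v = √n·m̄/s_m` with the
  n−1 standard deviation, standard normal reference. v > 0 favours model 1;
  both one-sided (H1: model 1 better) and two-sided p-values are reported.
  Identical per-observation densities define v = 0, p = 1.
* **Deviance F test** of the fitted model against the intercept-only null,
  with deviance M = −2ℓ, `F = ((M1−M2)/(p2−p1)) / (M2/(n−p2−1))`, where p
  counts regression coefficients. M1 − M2 is then exactly the likelihood-
  ratio statistic. **Limitation:** because M2 = −2ℓ carries the absolute
  scale of the likelihood rather than a dispersion estimate, the F reference
  is only an approximation and in practice conservative — under pure-noise
  covariates the empirical size is far below the nominal 5%, while power
  against real effects remains essentially 1. The test is kept in this form
  because the applied workflow it mirrors uses it this way; a
  likelihood-ratio χ² test is the better-calibrated alternative when size
  matters.

## The synthetic-data generator

`generate_dataset` / `make_fixture` emulate the estimator-quality study's
conditions: covariates drawn i.i.d. U(0,1), mean `μ_i = exp(x_iᵀβ)` with
β = (0.5, 0.5, 0.5), response WL2(θ = 2, μ_i); sample sizes
{100, 300, 500, 1000} and 1000 replications are the study defaults (the CLI
runs 250 by default — the Monte-Carlo averages are stable well below 1000 —
with `--full` restoring 1000). Covariates are redrawn every replication.
Per-replication RNG streams derive from the root seed as
`SeedSequence(seed, spawn_key=(n, rep))`, so any single cell is reproducible
in isolation and all runs are byte-identical under a fixed seed.

What the generator does **not** emulate: real covariate scales and
dependence (house ages, store counts), heteroscedastic dispersion (θ varying
with covariates), outliers, measurement error, or model misspecification
beyond the specific constant-mean scenario used in the power tests. Passing
tests therefore demonstrate correctness of the estimators and calibration of
the diagnostics *under the assumed model*, not robustness on arbitrary real
data.

## Monte-Carlo summaries and the acceptance comparison

`run_study` reports, per sample size and parameter, the average estimate
(AE), bias = AE − truth, and MSE across replications; non-converged fits are
excluded and counted, and any cell with more than 5% failures flags the
summary. The acceptance test compares our AEs at n = 1000 with previously
tabulated Monte-Carlo averages of the same design; since both sides are
Monte-Carlo means, the tolerance is three standard errors of the
*difference*, `3·√(s²_ours/R_ours + s²_ref/R_ref)`, with the reference
dispersion taken from the tabulated MSE minus squared bias at R_ref = 1000.
The tabulated MSE magnitudes themselves are not a target: they imply a
replication dispersion far above the observed information at those sample
sizes, which this implementation does not reproduce (our MSEs are an order
of magnitude smaller and shrink like 1/n, as theory predicts).

Problem sizes used by the default test run and `scripts/acceptance.py`:
250 replications per sample size (n = 500 and n = 1000), one CPU, under a
minute for the script and a few minutes for the full suite — the package's
own desk-scale defaults.

## Known limitations

* θ is constant across observations; dispersion does not follow covariates.
* The Vuong test is used in its basic (non-corrected) form — no AIC/BIC
  correction term for the difference in parameter counts (both models here
  have the same count, so the correction would cancel anyway).
* The KS test on Cox–Snell residuals ignores parameter estimation
  (no Lilliefors-type correction); its p-values are conservative.
* Censoring, weights, and offsets are not supported.
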