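"""Maximum-likelihood regression on the mean of positive responses.

Two estimators with a log link on the mean, mu_i = exp(x_i' beta):

* :class:`WL2Regressor` — the response follows the mean-parametrized
  weighted Lindley distribution WL2(theta, mu_i) with a common rate theta.
* :class:`GammaRegressor` — the gamma baseline, Gamma(shape nu, rate nu/mu_i),
  fitted by full maximum likelihood.  It serves both as the non-nested
  comparator in the Vuong test and as the initializer for the WL2 fit.

Both maximize the log-likelihood over (beta, log theta) — the auxiliary
parameter is optimized on the log scale so the simplex can never leave the
parameter space — with Nelder-Mead (function tolerance 1e-8, at most 5000
iterations, one automatic restart from the incumbent).  Standard errors come
from the inverse of the observed information, obtained by central finite
differences at the optimum and mapped back to the natural theta scale by the
delta method.  Wald z statistics use the standard normal reference.

The WL2 log-likelihood is the sum of the WL2 log-densities,

    l(theta, beta) = sum_i [ (a_i + 1) log theta - log(theta + a_i)
                             - log Gamma(a_i) + (a_i - 1) log y_i
                             + log(1 + y_i) ] - n * theta * ybar,

with a_i = alpha(theta, mu_i).  Note the minus sign on log Gamma: it is
dictated by the log of the WL2 density.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y
from statsmodels.tools.numdiff import approx_hess3

from . import distribution
from .data import RegressionData

__all__ = [
    "RegressionFit",
    "WL2Regressor",
    "GammaRegressor",
    "fit_wl2",
    "fit_gamma",
    "wl2_loglik",
    "gamma_loglik",
    "predict_mean",
    "per_obs_loglik",
]


@dataclass
class RegressionFit:
    """Container for a fitted mean regression.

    ``beta`` holds the k+1 regression coefficients (intercept first);
    ``theta`` is the auxiliary parameter on its natural scale (the WL2 rate
    theta, or the gamma shape nu).  ``vcov`` is the (k+2) x (k+2) sampling
    covariance of (beta, theta) from the observed information, already
    delta-method adjusted for theta.
    """

    model: str
    names: list[str]
    beta: np.ndarray
    theta: float
    loglik: float
    vcov: np.ndarray
    se: np.ndarray
    z_values: np.ndarray
    p_values: np.ndarray
    aic: float
    bic: float
    converged: bool
    n_obs: int
    n_iter: int = 0

    @property
    def params(self) -> np.ndarray:
        """(beta..., theta) on the natural scale."""
        return np.append(self.beta, self.theta)

    def summary(self) -> str:
        lines = [
            f"{self.model.upper()} regression  (n = {self.n_obs}, "
            f"log-likelihood = {self.loglik:.4f})",
            f"AIC = {self.aic:.4f}   BIC = {self.bic:.4f}   "
            f"converged = {self.converged}",
            f"{'parameter':<14}{'estimate':>12}{'std.err':>12}"
            f"{'z':>10}{'p-value':>12}",
        ]
        for name, est, se, z, p in zip(
            self.names, self.params, self.se, self.z_values, self.p_values
        ):
            lines.append(f"{name:<14}{est:>12.5f}{se:>12.5f}{z:>10.3f}{p:>12.4g}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "names": list(self.names),
            "estimates": self.params.tolist(),
            "se": self.se.tolist(),
            "z_values": self.z_values.tolist(),
            "p_values": self.p_values.tolist(),
            "loglik": self.loglik,
            "aic": self.aic,
            "bic": self.bic,
            "converged": bool(self.converged),
            "n_obs": int(self.n_obs),
        }


def _wl2_loglik_vec(y, mu, theta, ybar_n):
    alpha = distribution.alpha_from_mean(theta, mu)
    return float(
        np.sum(
            (alpha + 1.0) * np.log(theta)
            - np.log(theta + alpha)
            - special.gammaln(alpha)
            + (alpha - 1.0) * np.log(y)
            + np.log1p(y)
        )
        - theta * ybar_n
    )


def wl2_loglik(beta, theta, data: RegressionData) -> float:
    """WL2 regression log-likelihood at (beta, theta) on the given data."""
    if theta <= 0:
        raise ValueError("theta must be positive")
    mu = np.exp(data.X @ np.asarray(beta, dtype=float))
    return _wl2_loglik_vec(data.y, mu, float(theta), float(np.sum(data.y)))


def gamma_loglik(beta, nu, data: RegressionData) -> float:
    """Log-likelihood of the mean-parametrized gamma regression."""
    if nu <= 0:
        raise ValueError("nu must be positive")
    mu = np.exp(data.X @ np.asarray(beta, dtype=float))
    y = data.y
    return float(
        np.sum(
            nu * (np.log(nu) - np.log(mu))
            - special.gammaln(nu)
            + (nu - 1.0) * np.log(y)
            - nu * y / mu
        )
    )


def _lindley_moment_theta(ybar: float) -> float:
    """Method-of-moments theta of the Lindley distribution (alpha = 1).

    Solves ybar = (theta + 2) / (theta * (theta + 1)) for theta > 0.
    """
    return float((-(ybar - 1.0) + np.sqrt((ybar - 1.0) ** 2 + 8.0 * ybar)) / (2.0 * ybar))


class _MLLinkRegressor(RegressorMixin, BaseEstimator):
    """Shared Nelder-Mead machinery for log-link ML regressions."""

    _model_label = ""
    _aux_name = ""

    def __init__(self, fit_intercept=True, maxiter=5000, tol=1e-8, restarts=1):
        self.fit_intercept = fit_intercept
        self.maxiter = maxiter
        self.tol = tol
        self.restarts = restarts

    # subclasses provide the per-observation mechanics
    def _loglik(self, y, mu, aux, ysum):  # pragma: no cover - abstract
        raise NotImplementedError

    def _initial_params(self, Xd, y):  # pragma: no cover - abstract
        raise NotImplementedError

    def _design(self, X):
        if self.fit_intercept:
            return np.column_stack([np.ones(X.shape[0]), X])
        return np.asarray(X, dtype=float)

    def fit(self, X, y):
        X, y = check_X_y(X, y, y_numeric=True)
        if np.any(y <= 0):
            raise ValueError("response must be strictly positive")
        Xd = self._design(X)
        if np.linalg.matrix_rank(Xd) < Xd.shape[1]:
            raise ValueError("design matrix is rank deficient")
        n, p = Xd.shape
        if n <= p + 1:
            raise ValueError("need more observations than parameters")
        ysum = float(np.sum(y))

        def negll(params):
            beta, log_aux = params[:-1], params[-1]
            if abs(log_aux) > 50.0:
                return np.inf
            eta = Xd @ beta
            if np.any(np.abs(eta) > 500.0):
                return np.inf
            with np.errstate(all="ignore"):
                ll = self._loglik(y, np.exp(eta), np.exp(log_aux), ysum)
            return -ll if np.isfinite(ll) else np.inf

        x0 = self._initial_params(Xd, y)
        best = None
        n_iter = 0
        for _ in range(1 + max(0, int(self.restarts))):
            res = optimize.minimize(
                negll,
                x0,
                method="Nelder-Mead",
                options={
                    "maxiter": self.maxiter,
                    "fatol": self.tol,
                    "xatol": self.tol,
                },
            )
            n_iter += res.nit
            if best is None or res.fun < best.fun:
                best = res
            x0 = best.x  # restart from the incumbent
        converged = bool(best.success) and np.isfinite(best.fun)

        internal = best.x
        beta_hat = internal[:-1]
        aux_hat = float(np.exp(internal[-1]))
        loglik = -float(best.fun)

        # observed information on the internal (beta, log aux) scale
        eps3 = np.finfo(float).eps ** (1.0 / 3.0)
        step = eps3 * np.maximum(1.0, np.abs(internal))
        try:
            hess = approx_hess3(internal, negll, epsilon=step)
            vcov_int = np.linalg.inv(hess)
        except np.linalg.LinAlgError:
            vcov_int = np.full((p + 1, p + 1), np.nan)
            converged = False
        # delta method: d(aux)/d(log aux) = aux
        jac = np.ones(p + 1)
        jac[-1] = aux_hat
        vcov = vcov_int * np.outer(jac, jac)
        with np.errstate(invalid="ignore"):
            se = np.sqrt(np.diag(vcov))

        self.n_features_in_ = X.shape[1]
        self.coef_ = beta_hat[1:] if self.fit_intercept else beta_hat
        self.intercept_ = float(beta_hat[0]) if self.fit_intercept else 0.0
        self.beta_ = beta_hat
        self.theta_ = aux_hat
        self.loglik_ = loglik
        self.vcov_ = vcov
        self.se_ = se
        self.converged_ = converged
        self.n_obs_ = n
        self.n_iter_ = int(n_iter)
        est = np.append(beta_hat, aux_hat)
        with np.errstate(invalid="ignore", divide="ignore"):
            self.z_values_ = est / se
            self.p_values_ = 2.0 * stats.norm.sf(np.abs(self.z_values_))
        k_params = p + 1
        self.aic_ = 2.0 * k_params - 2.0 * loglik
        self.bic_ = k_params * np.log(n) - 2.0 * loglik
        return self

    def predict(self, X):
        check_is_fitted(self, "beta_")
        X = check_array(X)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, expected {self.n_features_in_}"
            )
        return np.exp(self._design(X) @ self.beta_)

    def result_(self, names=None) -> RegressionFit:
        """Package the fitted state as a :class:`RegressionFit`."""
        check_is_fitted(self, "beta_")
        if names is None:
            names = [f"x{j}" for j in range(1, len(self.beta_))]
        full_names = (["(intercept)"] if self.fit_intercept else []) + list(names)
        full_names.append(self._aux_name)
        return RegressionFit(
            model=self._model_label,
            names=full_names,
            beta=self.beta_.copy(),
            theta=self.theta_,
            loglik=self.loglik_,
            vcov=self.vcov_.copy(),
            se=self.se_.copy(),
            z_values=self.z_values_.copy(),
            p_values=self.p_values_.copy(),
            aic=self.aic_,
            bic=self.bic_,
            converged=self.converged_,
            n_obs=self.n_obs_,
            n_iter=self.n_iter_,
        )


class GammaRegressor(_MLLinkRegressor):
    """Gamma regression with log link, fitted by full maximum likelihood.

    Parametrized by the mean: Y_i ~ Gamma(shape nu, rate nu / mu_i), so
    E(Y_i) = mu_i = exp(x_i' beta) and Var(Y_i) = mu_i^2 / nu.  The
    coefficient estimates coincide with the GLM/IRLS solution (the gamma
    score equations for beta do not involve nu); nu itself is estimated by
    ML jointly, not by moments.
    """

    _model_label = "gamma"
    _aux_name = "nu"

    def _loglik(self, y, mu, nu, ysum):
        return float(
            np.sum(
                nu * (np.log(nu) - np.log(mu))
                - special.gammaln(nu)
                + (nu - 1.0) * np.log(y)
                - nu * y / mu
            )
        )

    def _initial_params(self, Xd, y):
        # OLS on log y is consistent for beta up to the intercept offset
        beta0, *_ = np.linalg.lstsq(Xd, np.log(y), rcond=None)
        resid = np.log(y) - Xd @ beta0
        nu0 = max(1.0 / max(np.var(resid), 1e-3), 0.1)
        return np.append(beta0, np.log(nu0))


class WL2Regressor(_MLLinkRegressor):
    """Mean-parametrized weighted Lindley (WL2) regression with log link.

    Y_i ~ WL2(theta, mu_i) with mu_i = exp(x_i' beta); theta > 0 is a common
    rate parameter controlling the dispersion.  beta is initialized from the
    gamma-regression fit and log theta from the Lindley method-of-moments
    estimate at the sample mean.
    """

    _model_label = "wl2"
    _aux_name = "theta"

    def _loglik(self, y, mu, theta, ysum):
        alpha = distribution.alpha_from_mean(theta, mu)
        return float(
            np.sum(
                (alpha + 1.0) * np.log(theta)
                - np.log(theta + alpha)
                - special.gammaln(alpha)
                + (alpha - 1.0) * np.log(y)
                + np.log1p(y)
            )
            - theta * ysum
        )

    def _initial_params(self, Xd, y):
        gamma = GammaRegressor(
            fit_intercept=False, maxiter=self.maxiter, tol=self.tol, restarts=0
        )
        try:
            gamma.fit(Xd, y)
            beta0 = gamma.beta_
        except Exception:
            beta0, *_ = np.linalg.lstsq(Xd, np.log(y), rcond=None)
        theta0 = _lindley_moment_theta(float(np.mean(y)))
        return np.append(beta0, np.log(theta0))


def _fit_from_data(estimator_cls, data: RegressionData, **kwargs) -> RegressionFit:
    est = estimator_cls(fit_intercept=False, **kwargs)
    est.fit(data.X, data.y)
    return est.result_(names=list(data.covariate_names))


def fit_wl2(data: RegressionData, **kwargs) -> RegressionFit:
    """Fit the WL2 regression on a prepared :class:`RegressionData`."""
    return _fit_from_data(WL2Regressor, data, **kwargs)


def fit_gamma(data: RegressionData, **kwargs) -> RegressionFit:
    """Fit the gamma baseline regression on a prepared RegressionData."""
    return _fit_from_data(GammaRegressor, data, **kwargs)


def predict_mean(fit: RegressionFit, X_new) -> np.ndarray:
    """Fitted means exp(X_new beta-hat) for a design matrix X_new.

    X_new must carry the same columns (including the leading intercept
    column) as the training design.
    """
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim != 2 or X_new.shape[1] != len(fit.beta):
        raise ValueError(
            f"X_new must have {len(fit.beta)} columns to match the fit"
        )
    return np.exp(X_new @ fit.beta)


def per_obs_loglik(fit: RegressionFit, data: RegressionData) -> np.ndarray:
    """Per-observation log-density under a fitted model (Vuong ingredient)."""
    mu = predict_mean(fit, data.X)
    if fit.model == "wl2":
        return np.asarray(distribution.logpdf(data.y, fit.theta, mu, strict=False))
    if fit.model == "gamma":
        nu = fit.theta
        return stats.gamma.logpdf(data.y, nu, scale=mu / nu)
    raise ValueError(f"unknown model label: {fit.model!r}")


def fitted_cdf(fit: RegressionFit, data: RegressionData) -> np.ndarray:
    """F(y_i) under the fitted model, used by the Cox-Snell residuals."""
    mu = predict_mean(fit, data.X)
    if fit.model == "wl2":
        return np.asarray(distribution.cdf(data.y, fit.theta, mu))
    if fit.model == "gamma":
        nu = fit.theta
        return stats.gamma.cdf(data.y, nu, scale=mu / nu)
    raise ValueError(f"unknown model label: {fit.model!r}")
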