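"""Mean-parametrized weighted Lindley (WL2) distribution.

The weighted Lindley (WL) distribution has density

    f(y; theta, alpha) = theta^(alpha+1) / ((theta + alpha) * Gamma(alpha))
                         * y^(alpha-1) * (1 + y) * exp(-theta * y),   y > 0,

with scale/rate parameter ``theta > 0`` and shape parameter ``alpha > 0``.
It reduces to the Lindley distribution at ``alpha = 1`` and is a two-component
gamma mixture,

    f = p * Gamma(alpha, theta) + (1 - p) * Gamma(alpha + 1, theta),
    p = theta / (theta + alpha),

where ``Gamma(a, theta)`` denotes the gamma density with shape ``a`` and rate
``theta``.  The WL2 parametrization replaces ``alpha`` by the distribution
mean ``mu``: solving the mean equation

    mu = alpha * (theta + alpha + 1) / (theta * (theta + alpha))

for ``alpha`` gives

    alpha(theta, mu) = ( theta*(mu - 1)
                         + sqrt(theta^2*(mu+1)^2 - 2*theta*(mu-1) + 1) - 1 ) / 2,

which is strictly positive for all theta, mu > 0 (the discriminant, viewed as
a quadratic in theta, has discriminant -16*mu < 0 and is therefore never
zero).  Parametrizing by the mean is what makes a regression on ``mu``
through a log link possible.

All density work happens in log space through ``gammaln``; the gamma function
itself is never evaluated (it overflows for moderate ``alpha``).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import special, stats

__all__ = [
    "alpha_from_mean",
    "mean_from_shape",
    "variance_from_shape",
    "variance_from_mean",
    "logpdf",
    "pdf",
    "cdf",
    "ppf",
    "rvs",
]

# alpha below this is numerically indistinguishable from the boundary of the
# parameter space; clamp and warn rather than return 0/NaN.
_ALPHA_FLOOR = 1e-12


def _validate_positive(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)) or np.any(arr <= 0.0):
        raise ValueError(f"{name} must be finite and strictly positive")
    return arr


def alpha_from_mean(theta, mu):
    """Shape parameter ``alpha`` implied by rate ``theta`` and mean ``mu``.

    Inverts the WL mean equation; see the module docstring.  Vectorized over
    both arguments.  Raises ``ValueError`` on non-positive input.
    """
    theta = _validate_positive("theta", theta)
    mu = _validate_positive("mu", mu)
    disc = theta**2 * (mu + 1.0) ** 2 - 2.0 * theta * (mu - 1.0) + 1.0
    alpha = 0.5 * (theta * (mu - 1.0) + np.sqrt(disc) - 1.0)
    if np.any(alpha < _ALPHA_FLOOR):
        warnings.warn(
            "alpha(theta, mu) fell below 1e-12 and was clamped; the "
            "distribution is essentially degenerate in this corner",
            RuntimeWarning,
            stacklevel=2,
        )
        alpha = np.maximum(alpha, _ALPHA_FLOOR)
    return alpha if alpha.ndim else float(alpha)


def mean_from_shape(theta, alpha):
    """Mean of the WL distribution in the classical (theta, alpha) form."""
    theta = _validate_positive("theta", theta)
    alpha = _validate_positive("alpha", alpha)
    out = alpha * (theta + alpha + 1.0) / (theta * (theta + alpha))
    return out if out.ndim else float(out)


def variance_from_shape(theta, alpha):
    """Variance of the WL distribution in the classical form."""
    theta = _validate_positive("theta", theta)
    alpha = _validate_positive("alpha", alpha)
    out = ((alpha + 1.0) * (theta + alpha) ** 2 - theta**2) / (
        theta**2 * (theta + alpha) ** 2
    )
    return out if out.ndim else float(out)


def variance_from_mean(theta, mu):
    """Variance of WL2(theta, mu)."""
    return variance_from_shape(theta, alpha_from_mean(theta, mu))


def logpdf(y, theta, mu, strict: bool = True):
    """Log-density of WL2(theta, mu) at ``y``.

    Parameters
    ----------
    y : array_like
        Evaluation points.
    theta, mu : array_like
        Rate and mean parameters (broadcast against ``y``).
    strict : bool
        If True (default), ``y <= 0`` raises ``ValueError``.  If False,
        non-positive points get log-density ``-inf`` — the behaviour the
        likelihood code relies on so that boundary proposals from the
        optimizer never raise mid-fit.
    """
    y = np.asarray(y, dtype=float)
    alpha = np.asarray(alpha_from_mean(theta, mu), dtype=float)
    theta = np.asarray(theta, dtype=float)
    bad = ~(y > 0.0)
    if strict and np.any(bad):
        raise ValueError("y must be strictly positive (strict mode)")
    with np.errstate(divide="ignore", invalid="ignore"):
        ysafe = np.where(bad, 1.0, y)
        out = (
            (alpha + 1.0) * np.log(theta)
            - np.log(theta + alpha)
            - special.gammaln(alpha)
            + (alpha - 1.0) * np.log(ysafe)
            + np.log1p(ysafe)
            - theta * ysafe
        )
        out = np.where(bad, -np.inf, out)
    return out if out.ndim else float(out)


def pdf(y, theta, mu, strict: bool = True):
    """Density of WL2(theta, mu) at ``y``."""
    out = np.exp(logpdf(y, theta, mu, strict=strict))
    return out if np.ndim(out) else float(out)


def cdf(y, theta, mu):
    """Distribution function of WL2(theta, mu).

    Evaluated through the gamma-mixture representation:

        F(y) = p * P(alpha, theta*y) + (1 - p) * P(alpha + 1, theta*y),

    with ``P`` the regularized lower incomplete gamma function and
    ``p = theta / (theta + alpha)``.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y < 0.0):
        raise ValueError("y must be nonnegative")
    alpha = np.asarray(alpha_from_mean(theta, mu), dtype=float)
    theta = np.asarray(theta, dtype=float)
    p = theta / (theta + alpha)
    x = theta * y
    out = p * special.gammainc(alpha, x) + (1.0 - p) * special.gammainc(alpha + 1.0, x)
    return out if out.ndim else float(out)


def ppf(u, theta, mu):
    """Quantile function of WL2(theta, mu) by safeguarded root bracketing.

    Solves ``cdf(y) = u`` on a bracket ``[0, mu + 20*sigma]`` expanded
    geometrically until it straddles the root, then Brent's method to an
    absolute tolerance of 1e-10 on the probability scale.
    """
    from scipy.optimize import brentq

    u_arr = np.atleast_1d(np.asarray(u, dtype=float))
    if np.any((u_arr <= 0.0) | (u_arr >= 1.0)):
        raise ValueError("u must lie strictly inside (0, 1)")
    theta_f = float(np.asarray(theta, dtype=float))
    mu_arr = np.broadcast_to(np.asarray(mu, dtype=float), u_arr.shape)

    out = np.empty_like(u_arr)
    for i, (ui, mui) in enumerate(zip(u_arr.ravel(), mu_arr.ravel())):
        sigma = np.sqrt(variance_from_mean(theta_f, mui))
        hi = mui + 20.0 * sigma
        while cdf(hi, theta_f, mui) < ui:
            hi *= 2.0
        out.ravel()[i] = brentq(
            lambda yy: cdf(yy, theta_f, mui) - ui, 0.0, hi, xtol=1e-14, rtol=1e-14
        )
    return out if np.ndim(u) else float(out[0])


def rvs(n, theta, mu, rng=None, method: str = "mixture"):
    """Draw ``n`` i.i.d. variates from WL2(theta, mu).

    ``mu`` may be a scalar or a length-``n`` vector (one mean per draw, as
    needed when simulating regression responses).

    method = "mixture" (default): exact composition sampling from the
    two-gamma mixture — pick the Gamma(alpha, theta) component with
    probability p = theta/(theta+alpha), else Gamma(alpha+1, theta).
    method = "inverse": inverse-transform sampling through ``ppf``; equal in
    distribution to the mixture path and kept as a cross-check (it is much
    slower).
    """
    n = int(n)
    if n < 1:
        raise ValueError("n must be a positive integer")
    rng = np.random.default_rng(rng)
    mu_arr = np.broadcast_to(np.asarray(mu, dtype=float), (n,))
    theta_f = float(np.asarray(theta, dtype=float))

    if method == "inverse":
        return ppf(rng.uniform(size=n), theta_f, mu_arr)
    if method != "mixture":
        raise ValueError(f"unknown sampling method: {method!r}")

    alpha = np.asarray(alpha_from_mean(theta_f, mu_arr), dtype=float)
    p = theta_f / (theta_f + alpha)
    shape = np.where(rng.uniform(size=n) < p, alpha, alpha + 1.0)
    return rng.gamma(shape=shape, scale=1.0 / theta_f, size=n)


def mixture_logpdf(y, theta, mu):
    """Log-density via the explicit two-gamma mixture (cross-check path)."""
    alpha = np.asarray(alpha_from_mean(theta, mu), dtype=float)
    p = theta / (theta + alpha)
    a = stats.gamma.logpdf(y, alpha, scale=1.0 / theta) + np.log(p)
    b = stats.gamma.logpdf(y, alpha + 1.0, scale=1.0 / theta) + np.log1p(-p)
    return np.logaddexp(a, b)
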