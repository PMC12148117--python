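"""Distribution kernel: parametrizations, density, cdf, quantiles, sampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.integrate import quad
from scipy.optimize import brentq

from wl2reg import distribution as d

positive = st.floats(min_value=0.05, max_value=50.0)


@pytest.mark.parametrize(
    "theta, mu, expected",
    [
        (1.0, 1.5, 1.0),  # Lindley case: alpha = 1
        (2.0, 1.0, (np.sqrt(17.0) - 1.0) / 2.0),
    ],
)
def test_alpha_from_mean_closed_form(theta, mu, expected):
    assert d.alpha_from_mean(theta, mu) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize(
    "theta, alpha, expected",
    [(1.0, 1.0, 1.5), (2.0, 1.0, 2.0 / 3.0)],
)
def test_mean_from_shape_closed_form(theta, alpha, expected):
    assert d.mean_from_shape(theta, alpha) == pytest.approx(expected, rel=1e-12)


def test_variance_lindley_case():
    # Lindley variance (theta^2 + 4 theta + 2) / (theta^2 (theta+1)^2) at theta=1
    assert d.variance_from_shape(1.0, 1.0) == pytest.approx(7.0 / 4.0, rel=1e-12)


def test_variance_matches_quadrature():
    theta, alpha = 2.0, 3.0
    mu = d.mean_from_shape(theta, alpha)
    integrand = lambda y: (y - mu) ** 2 * d.pdf(y, theta, mu)
    var_quad, _ = quad(integrand, 0, np.inf)
    assert d.variance_from_shape(theta, alpha) == pytest.approx(var_quad, abs=1e-6)


def test_parametrizations_round_trip_on_grid():
    grid = [0.1, 0.5, 1.0, 2.0, 10.0]
    for theta in grid:
        for alpha in grid:
            mu = d.mean_from_shape(theta, alpha)
            assert d.alpha_from_mean(theta, mu) == pytest.approx(alpha, rel=1e-10)


@settings(derandomize=True, max_examples=200)
@given(theta=positive, mu=positive)
def test_mean_alpha_mutual_inverses(theta, mu):
    alpha = d.alpha_from_mean(theta, mu)
    assert alpha > 0
    assert d.mean_from_shape(theta, alpha) == pytest.approx(mu, rel=1e-10)


@settings(derandomize=True, max_examples=200)
@given(theta=positive, mu=positive)
def test_discriminant_strictly_positive(theta, mu):
    disc = theta**2 * (mu + 1.0) ** 2 - 2.0 * theta * (mu - 1.0) + 1.0
    assert disc > 0.0


def test_logpdf_spot_value():
    # y=1 at the Lindley corner theta=1, mu=1.5: exact analytic value -1
    assert d.logpdf(1.0, 1.0, 1.5) == pytest.approx(-1.0, abs=1e-14)


@pytest.mark.parametrize("theta, mu", [(1.0, 1.5), (2.0, 0.8), (0.5, 3.0), (5.0, 0.3)])
def test_pdf_normalizes(theta, mu):
    integral, _ = quad(lambda y: d.pdf(y, theta, mu), 0, np.inf, limit=200)
    assert integral == pytest.approx(1.0, abs=1e-8)


@pytest.mark.parametrize("theta, mu", [(2.0, 0.8), (0.7, 4.0), (10.0, 0.5)])
def test_pdf_equals_two_gamma_mixture(theta, mu):
    y = np.linspace(0.01, 12.0, 80)
    alpha = d.alpha_from_mean(theta, mu)
    p = theta / (theta + alpha)
    mix = p * stats.gamma.pdf(y, alpha, scale=1 / theta) + (1 - p) * stats.gamma.pdf(
        y, alpha + 1, scale=1 / theta
    )
    np.testing.assert_allclose(d.pdf(y, theta, mu), mix, rtol=0, atol=1e-12)


@pytest.mark.parametrize("theta, mu", [(2.0, 0.8), (0.7, 4.0)])
def test_cdf_equals_two_gamma_mixture(theta, mu):
    y = np.linspace(0.0, 12.0, 50)
    alpha = d.alpha_from_mean(theta, mu)
    p = theta / (theta + alpha)
    mix = p * stats.gamma.cdf(y, alpha, scale=1 / theta) + (1 - p) * stats.gamma.cdf(
        y, alpha + 1, scale=1 / theta
    )
    np.testing.assert_allclose(d.cdf(y, theta, mu), mix, rtol=0, atol=1e-12)


def test_lindley_reduction_at_alpha_one():
    # at alpha = 1 (mu = mean of Lindley(theta)) the density is the Lindley pdf
    for theta in (0.5, 1.0, 3.0):
        mu = d.mean_from_shape(theta, 1.0)
        y = np.linspace(0.01, 10.0, 60)
        lindley = theta**2 / (theta + 1.0) * (1.0 + y) * np.exp(-theta * y)
        np.testing.assert_allclose(d.pdf(y, theta, mu), lindley, rtol=0, atol=1e-12)


@pytest.mark.parametrize("theta, mu", [(1.0, 1.5), (2.0, 0.8), (0.5, 3.0)])
def test_cdf_matches_quadrature(theta, mu):
    for y in (0.2, 0.8, 1.5, 4.0):
        integral, _ = quad(lambda t: d.pdf(t, theta, mu), 0, y, limit=200)
        assert d.cdf(y, theta, mu) == pytest.approx(integral, abs=1e-8)


def test_cdf_boundaries_and_monotonicity():
    theta, mu = 2.0, 1.2
    assert d.cdf(0.0, theta, mu) == 0.0
    y = np.linspace(0, 30, 200)
    F = d.cdf(y, theta, mu)
    assert np.all(np.diff(F) >= 0)
    assert F[-1] == pytest.approx(1.0, abs=1e-10)


def test_quantile_cdf_round_trip():
    theta, mu = 1.3, 2.1
    for y0 in (0.1, 1.0, 5.0):
        u = d.cdf(y0, theta, mu)
        assert d.ppf(u, theta, mu) == pytest.approx(y0, abs=1e-8)
    # inverse consistency at the median
    q = d.ppf(0.5, theta, mu)
    assert d.cdf(q, theta, mu) == pytest.approx(0.5, abs=1e-9)


def test_quantile_monotone():
    u = np.linspace(0.05, 0.95, 19)
    q = d.ppf(u, 2.0, 0.8)
    assert np.all(np.diff(q) > 0)


def test_median_matches_lindley_oracle():
    # at theta=1, mu=1.5 the distribution is Lindley(1); its median solves
    # 1 - (1 + theta*y/(theta+1)) exp(-theta*y) = 1/2 — an independent root-find
    theta = 1.0
    lindley_cdf = lambda y: 1.0 - (1.0 + theta * y / (theta + 1.0)) * np.exp(-theta * y)
    median_oracle = brentq(lambda y: lindley_cdf(y) - 0.5, 1e-9, 50.0, xtol=1e-13)
    assert d.ppf(0.5, 1.0, 1.5) == pytest.approx(median_oracle, abs=1e-9)


def test_sampling_reproducible_and_consistent():
    x1 = d.rvs(1000, 2.0, 3.0, rng=123)
    x2 = d.rvs(1000, 2.0, 3.0, rng=123)
    np.testing.assert_array_equal(x1, x2)
    assert np.all(x1 > 0)

    big = d.rvs(10**6, 2.0, 3.0, rng=5)
    sigma = np.sqrt(d.variance_from_mean(2.0, 3.0))
    assert abs(big.mean() - 3.0) < 3.0 * sigma / 1000.0

    ks = stats.kstest(d.rvs(10**5, 2.0, 3.0, rng=11), lambda y: d.cdf(y, 2.0, 3.0))
    assert ks.pvalue > 0.001


def test_inverse_transform_path_agrees_in_distribution():
    mix = d.rvs(5000, 1.5, 2.0, rng=21, method="mixture")
    inv = d.rvs(2000, 1.5, 2.0, rng=22, method="inverse")
    assert stats.ks_2samp(mix, inv).pvalue > 0.001


def test_domain_errors():
    with pytest.raises(ValueError):
        d.alpha_from_mean(-1.0, 1.0)
    with pytest.raises(ValueError):
        d.mean_from_shape(1.0, 0.0)
    with pytest.raises(ValueError):
        d.logpdf(-0.5, 1.0, 1.0)  # strict mode
    assert d.logpdf(-0.5, 1.0, 1.0, strict=False) == -np.inf
    with pytest.raises(ValueError):
        d.cdf(-0.1, 1.0, 1.0)
    with pytest.raises(ValueError):
        d.ppf(1.2, 1.0, 1.0)
    with pytest.raises(ValueError):
        d.rvs(0, 1.0, 1.0)
    with pytest.raises(ValueError):
        d.rvs(5, 1.0, 1.0, method="bogus")
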