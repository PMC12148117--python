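"""Model adequacy and model comparison.

* Cox-Snell residuals ``e_i = -log(1 - F(y_i))`` under the fitted model,
  which are unit-exponential when the model is correct; checked with a
  one-sample Kolmogorov-Smirnov test against Exp(1) (fully specified null)
  and summarized as PP-plot coordinates.
* The Vuong test for non-nested models: with per-observation log-density
  differences m_i = log f1(y_i) - log f2(y_i), the statistic
  v = sqrt(n) * mbar / s_m is asymptotically standard normal under the null
  of equivalent models; v > 0 favours model 1.
* A deviance F test of the fitted model against the intercept-only null,
  with deviance taken as -2 * loglik so that M1 - M2 is the likelihood-ratio
  statistic; the F reference with (p2 - p1, n - p2 - 1) degrees of freedom is
  an approximation for ML deviances.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import RegressionData
from .regression import RegressionFit, fitted_cdf, per_obs_loglik

__all__ = [
    "ResidualReport",
    "VuongResult",
    "FTestResult",
    "cox_snell",
    "vuong_test",
    "f_test",
    "model_table",
]


@dataclass
class ResidualReport:
    residuals: np.ndarray
    ks_statistic: float
    ks_pvalue: float
    pp_points: np.ndarray  # columns: empirical i/(n+1), theoretical 1-exp(-e_(i))

    def pp_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pp_points, columns=["empirical", "theoretical"])


@dataclass
class VuongResult:
    statistic: float
    pvalue: float  # two-sided
    pvalue_one_sided: float  # H1: model 1 better than model 2
    m_bar: float
    s_m: float
    model1_label: str
    model2_label: str


@dataclass
class FTestResult:
    f_statistic: float
    df1: int
    df2: int
    pvalue: float
    M1: float
    M2: float


def cox_snell(fit: RegressionFit, data: RegressionData) -> ResidualReport:
    """Cox-Snell residuals of a fitted model with a KS check against Exp(1)."""
    F = fitted_cdf(fit, data)
    eps = np.finfo(float).eps
    clip = F >= 1.0 - eps
    if np.any(clip):
        import warnings

        warnings.warn(
            f"{int(clip.sum())} residual(s) at the numerical upper tail were "
            "clamped",
            RuntimeWarning,
            stacklevel=2,
        )
        F = np.minimum(F, 1.0 - eps)
    resid = -np.log1p(-F)
    ks = stats.kstest(resid, "expon")
    n = len(resid)
    emp = np.arange(1, n + 1) / (n + 1.0)
    theo = 1.0 - np.exp(-np.sort(resid))
    return ResidualReport(
        residuals=resid,
        ks_statistic=float(ks.statistic),
        ks_pvalue=float(ks.pvalue),
        pp_points=np.column_stack([emp, theo]),
    )


def vuong_test(
    fit1: RegressionFit, fit2: RegressionFit, data: RegressionData
) -> VuongResult:
    """Vuong closeness test of two non-nested fits on the same data.

    Positive statistic favours ``fit1``.  When the two models produce
    identical per-observation densities the statistic is defined as 0 with
    p-value 1.
    """
    if fit1.n_obs != fit2.n_obs or fit1.n_obs != data.n_obs:
        raise ValueError("both fits must be on the same data")
    m = per_obs_loglik(fit1, data) - per_obs_loglik(fit2, data)
    n = len(m)
    m_bar = float(np.mean(m))
    s_m = float(np.std(m, ddof=1))
    if s_m == 0.0:
        v = 0.0
        p_two, p_one = 1.0, 1.0
    else:
        v = float(np.sqrt(n) * m_bar / s_m)
        p_two = float(2.0 * stats.norm.sf(abs(v)))
        p_one = float(stats.norm.sf(v))
    return VuongResult(
        statistic=v,
        pvalue=p_two,
        pvalue_one_sided=p_one,
        m_bar=m_bar,
        s_m=s_m,
        model1_label=fit1.model,
        model2_label=fit2.model,
    )


def f_test(fit_full: RegressionFit, fit_null: RegressionFit) -> FTestResult:
    """Deviance F test of a fitted model against its intercept-only null.

    ``p1`` and ``p2`` count regression coefficients (including the
    intercept); deviance is -2 * loglik.  Identical specifications yield
    F = 0 by convention.
    """
    if fit_full.n_obs != fit_null.n_obs:
        raise ValueError("fits must share the data")
    p1 = len(fit_null.beta)
    p2 = len(fit_full.beta)
    n = fit_full.n_obs
    M1 = -2.0 * fit_null.loglik
    M2 = -2.0 * fit_full.loglik
    if p2 == p1:
        if abs(M1 - M2) > 1e-6 * max(1.0, abs(M1)):
            raise ValueError("models of equal size with different deviances")
        return FTestResult(0.0, 0, n - p2 - 1, 1.0, M1, M2)
    if p2 < p1:
        raise ValueError("fit_full must nest fit_null")
    if M1 < M2 - 1e-8 * max(1.0, abs(M1)):
        raise ValueError("null model cannot fit better than the full model at the MLE")
    df1 = p2 - p1
    df2 = n - p2 - 1
    f = max(0.0, ((M1 - M2) / df1) / (M2 / df2))
    p = float(stats.f.sf(f, df1, df2))
    return FTestResult(f, df1, df2, p, M1, M2)


def model_table(fits: list[RegressionFit]) -> pd.DataFrame:
    """Model-selection table: one row per fit, sorted by AIC (then BIC, label)."""
    if not fits:
        raise ValueError("need at least one fit")
    n_set = {f.n_obs for f in fits}
    if len(n_set) > 1:
        raise ValueError("fits are on different sample sizes")
    rows = [
        {"model": f.model, "neg_loglik": -f.loglik, "aic": f.aic, "bic": f.bic}
        for f in fits
    ]
    return (
        pd.DataFrame(rows)
        .sort_values(["aic", "bic", "model"], kind="mergesort")
        .reset_index(drop=True)
    )
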