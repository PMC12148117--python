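"""Monte-Carlo study of the WL2 regression maximum-likelihood estimators.

Each replication draws covariates x1, x2 ~ U(0,1), sets the mean through the
log link mu_i = exp(beta0 + beta1*x1 + beta2*x2), samples the response from
WL2(theta, mu_i), and refits by ML.  Across replications the study reports,
per parameter and sample size, the average estimate (AE), the bias (AE minus
truth), and the mean squared error — the standard consistency picture for a
regression estimator.

Defaults mirror the study design: n in {100, 300, 500, 1000}, 1000
replications, beta = (0.5, 0.5, 0.5), theta = 2.  Covariates are redrawn in
every replication.  Per-replication random streams are derived from the root
seed as ``SeedSequence(seed, spawn_key=(n, rep))`` so any single cell is
reproducible in isolation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import distribution
from .data import RegressionData
from .regression import fit_wl2

logger = logging.getLogger("wl2reg")

__all__ = ["SimDesign", "SimulationSummary", "generate_dataset", "run_study"]


@dataclass
class SimDesign:
    """Configuration of the Monte-Carlo experiment."""

    n_values: tuple = (100, 300, 500, 1000)
    n_reps: int = 1000
    beta_true: tuple = (0.5, 0.5, 0.5)
    theta_true: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.n_reps < 1 or any(n < 1 for n in self.n_values):
            raise ValueError("sample sizes and replication count must be positive")
        if self.theta_true <= 0:
            raise ValueError("theta_true must be positive")


@dataclass
class SimulationSummary:
    """AE / bias / MSE per sample size and parameter, plus fit failures."""

    table: pd.DataFrame  # index (n, metric), one column per parameter
    n_failed: dict = field(default_factory=dict)
    estimates: dict = field(default_factory=dict)  # n -> (reps, p) array
    flagged: bool = False

    def to_csv(self, path) -> None:
        self.table.reset_index().to_csv(path, index=False)


def generate_dataset(n, beta_true, theta_true, seed=None) -> RegressionData:
    """One synthetic dataset from the study's generating process.

    ``seed`` may be an int, a ``SeedSequence`` or a ``Generator``.
    """
    rng = np.random.default_rng(seed)
    beta = np.asarray(beta_true, dtype=float)
    k = len(beta) - 1
    X = np.column_stack([np.ones(n), rng.uniform(size=(n, k))])
    mu = np.exp(X @ beta)
    y = distribution.rvs(n, theta_true, mu, rng=rng)
    names = ["(intercept)"] + [f"x{j}" for j in range(1, k + 1)]
    return RegressionData(y=y, X=X, covariate_names=names)


def _replication_rng(seed: int, n: int, rep: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(n, rep)))


def run_study(design: SimDesign) -> SimulationSummary:
    """Run the full generate-fit-summarize loop for every (n, replication).

    Fits that fail to converge are excluded from the summaries; their count
    is reported, and a cell with more than 5% failures flags the summary.
    """
    truth = np.append(np.asarray(design.beta_true, dtype=float), design.theta_true)
    p = len(truth)
    param_names = [f"beta{j}" for j in range(p - 1)] + ["theta"]

    rows = []
    n_failed: dict[int, int] = {}
    estimates: dict[int, np.ndarray] = {}
    flagged = False
    for n in design.n_values:
        ests = []
        failed = 0
        for rep in range(design.n_reps):
            rng = _replication_rng(design.seed, n, rep)
            data = generate_dataset(n, design.beta_true, design.theta_true, seed=rng)
            try:
                fit = fit_wl2(data)
            except Exception:  # noqa: BLE001 - a failed fit is data, not a bug
                failed += 1
                continue
            if not fit.converged:
                failed += 1
                continue
            ests.append(fit.params)
        ests = np.asarray(ests)
        n_failed[n] = failed
        estimates[n] = ests
        if failed > 0.05 * design.n_reps:
            flagged = True
            logger.warning("more than 5%% failed fits at n=%d (%d)", n, failed)
        ae = ests.mean(axis=0)
        bias = ae - truth
        mse = np.mean((ests - truth) ** 2, axis=0)
        for metric, vals in (("AE", ae), ("Bias", bias), ("MSE", mse)):
            rows.append({"n": n, "metric": metric, **dict(zip(param_names, vals))})

    table = pd.DataFrame(rows).set_index(["n", "metric"])
    return SimulationSummary(
        table=table, n_failed=n_failed, estimates=estimates, flagged=flagged
    )
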