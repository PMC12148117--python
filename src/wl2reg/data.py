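"""Tabular ingestion and fixture generation.

A :class:`RegressionData` bundles a strictly positive response vector with a
design matrix whose first column is the intercept.  ``read_table`` builds one
from a CSV file; ``make_fixture`` writes synthetic CSVs with known generating
parameters (recorded in a sidecar JSON) so the test suite and worked examples
never require a download.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("wl2reg")

__all__ = ["RegressionData", "read_table", "make_fixture"]


@dataclass
class RegressionData:
    """Response and design matrix for a mean regression.

    ``X`` has shape (n, k+1) with a leading all-ones intercept column;
    ``covariate_names`` names its columns ("(intercept)" first).
    """

    y: np.ndarray
    X: np.ndarray
    covariate_names: list[str] = field(default_factory=list)
    response_name: str = "y"

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.asarray(self.X, dtype=float)
        n, p = self.X.shape
        if self.y.shape[0] != n:
            raise ValueError("y and X have inconsistent lengths")
        if np.any(self.y <= 0) or not np.all(np.isfinite(self.y)):
            bad = np.flatnonzero(~(self.y > 0)).tolist()
            raise ValueError(f"response must be strictly positive; offending rows: {bad}")
        if not np.allclose(self.X[:, 0], 1.0):
            raise ValueError("first design column must be the intercept (all ones)")
        if np.linalg.matrix_rank(self.X) < p:
            raise ValueError("design matrix is rank deficient")
        if not self.covariate_names:
            self.covariate_names = ["(intercept)"] + [f"x{j}" for j in range(1, p)]

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    @property
    def n_covariates(self) -> int:
        return self.X.shape[1] - 1

    def intercept_only(self) -> "RegressionData":
        """The nested null design (intercept column only)."""
        return RegressionData(
            y=self.y,
            X=self.X[:, :1],
            covariate_names=["(intercept)"],
            response_name=self.response_name,
        )


def read_table(path, response: str, covariates: list[str]) -> RegressionData:
    """Read a CSV file into a validated :class:`RegressionData`.

    Rows with missing values in any used column are dropped (the count is
    logged).  Non-positive responses and unknown columns raise ``ValueError``.
    """
    df = pd.read_csv(path)
    missing_cols = [c for c in [response, *covariates] if c not in df.columns]
    if missing_cols:
        raise ValueError(f"unknown columns: {missing_cols}; available: {list(df.columns)}")
    used = df[[response, *covariates]].apply(pd.to_numeric, errors="coerce")
    keep = used.notna().all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning("dropped %d rows with missing values", n_dropped)
    used = used[keep]
    y = used[response].to_numpy(dtype=float)
    if np.any(y <= 0):
        bad = used.index[y <= 0].tolist()
        raise ValueError(f"non-positive response values at rows {bad}")
    X = np.column_stack([np.ones(len(used)), used[covariates].to_numpy(dtype=float)])
    return RegressionData(
        y=y,
        X=X,
        covariate_names=["(intercept)", *covariates],
        response_name=response,
    )


def make_fixture(
    kind: str,
    path,
    n: int = 414,
    beta=(0.5, 0.5, 0.5),
    theta: float = 2.0,
    seed: int = 0,
) -> Path:
    """Write a synthetic regression CSV plus a sidecar JSON of its truth.

    kind = "wl2_regression": y ~ WL2(theta, exp(X beta)), x_j ~ U(0,1).
    kind = "gamma_regression": y ~ Gamma(shape theta, rate theta/mu).
    kind = "intercept_only": y ~ WL2(theta, exp(beta[0])), covariates drawn
    but unrelated to y (for size studies of covariate tests).
    """
    from . import distribution

    kinds = {"wl2_regression", "gamma_regression", "intercept_only"}
    if kind not in kinds:
        raise ValueError(f"kind must be one of {sorted(kinds)}")
    beta = np.asarray(beta, dtype=float)
    k = len(beta) - 1
    rng = np.random.default_rng(seed)
    X = rng.uniform(size=(n, k))
    if kind == "intercept_only":
        mu = np.full(n, np.exp(beta[0]))
    else:
        mu = np.exp(beta[0] + X @ beta[1:])
    if kind == "gamma_regression":
        y = rng.gamma(shape=theta, scale=mu / theta, size=n)
    else:
        y = distribution.rvs(n, theta, mu, rng=rng)

    path = Path(path)
    cols = {"y": y}
    cols.update({f"x{j+1}": X[:, j] for j in range(k)})
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.12g")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "kind": kind,
                "n": int(n),
                "beta": beta.tolist(),
                "theta": float(theta),
                "seed": int(seed),
            },
            indent=1,
        )
    )
    return path
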