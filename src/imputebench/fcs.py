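"""Fully conditional specification (chained-equations) multiple imputation.

Each incomplete variable gets its own conditional model given all other
variables (covariates and the current working values of the other incomplete
variables): predictive mean matching for continuous/semicontinuous targets
and Bayesian logistic regression for binary targets. The sampler initializes
missing cells by draws from the observed marginal, then sweeps the variables
in schema order for a fixed number of iterations, independently per chain;
the m chains' final states are the m completed datasets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .core import ImputationError, ImputationResult, design_for_imputation, two_step_wrap
from .estimation import fit_logistic_full
from .schema import MixedDataset


@dataclass(frozen=True)
class FcsParams:
    """m completed datasets, sweeps per chain, and the pmm donor-pool size."""

    m: int = 10
    iterations: int = 20
    k_donors: int = 5

    def __post_init__(self) -> None:
        if self.m < 1 or self.iterations < 1 or self.k_donors < 1:
            raise ImputationError("m, iterations and k_donors must all be >= 1")


def _bayes_linear_draw(
    y: np.ndarray, X: np.ndarray, rng: np.random.Generator, ridge: float = 1e-10
) -> tuple[np.ndarray, np.ndarray]:
    """Normal-inverse-gamma posterior draw for a linear regression.

    Returns (beta_hat, beta_star): the least-squares fit and one posterior
    draw of the coefficients. A tiny ridge keeps near-collinear working
    designs (common mid-chain) invertible.
    """
    n, p = X.shape
    XtX = X.T @ X + ridge * np.eye(p)
    try:
        XtX_inv = np.linalg.inv(XtX)
    except np.linalg.LinAlgError:
        XtX_inv = np.linalg.inv(XtX + 1e-6 * np.eye(p))
    beta_hat = XtX_inv @ (X.T @ y)
    resid = y - X @ beta_hat
    df = max(n - p, 1)
    sigma2 = float(resid @ resid) / rng.chisquare(df)
    try:
        chol = np.linalg.cholesky(sigma2 * XtX_inv)
    except np.linalg.LinAlgError:
        chol = np.linalg.cholesky(sigma2 * XtX_inv + 1e-10 * np.eye(p))
    beta_star = beta_hat + chol @ rng.standard_normal(p)
    return beta_hat, beta_star


def pmm_impute(
    y_obs: np.ndarray,
    X_obs: np.ndarray,
    X_mis: np.ndarray,
    k_donors: int,
    rng: np.random.Generator,
    posterior_draw: bool = True,
) -> np.ndarray:
    """Predictive mean matching (type-1).

    Fit a Bayesian linear regression on the observed rows; predict means for
    observed rows under the least-squares fit and for missing rows under a
    posterior coefficient draw; for each missing row copy the observed y of
    one of its ``k_donors`` nearest-predicted-mean donors, chosen uniformly.
    ``posterior_draw=False`` suppresses the parameter draw (test mode): both
    sets of predictions use the least-squares fit.
    """
    y_obs = np.asarray(y_obs, dtype=float)
    Xo = np.column_stack([np.ones(len(y_obs)), X_obs])
    Xm = np.column_stack([np.ones(len(X_mis)), X_mis])
    beta_hat, beta_star = _bayes_linear_draw(y_obs, Xo, rng)
    if not posterior_draw:
        beta_star = beta_hat
    yhat_obs = Xo @ beta_hat
    yhat_mis = Xm @ beta_star
    k = min(k_donors, len(y_obs))
    out = np.empty(len(yhat_mis))
    # chunk the distance matrix to bound memory at large n
    chunk = max(1, int(2e6 // max(len(y_obs), 1)))
    for start in range(0, len(yhat_mis), chunk):
        block = yhat_mis[start:start + chunk]
        d = np.abs(yhat_obs[None, :] - block[:, None])
        if k < len(y_obs):
            donor_pool = np.argpartition(d, k - 1, axis=1)[:, :k]
        else:
            donor_pool = np.broadcast_to(np.arange(len(y_obs)), (len(block), len(y_obs)))
        pick = rng.integers(0, k, size=len(block))
        out[start:start + chunk] = y_obs[donor_pool[np.arange(len(block)), pick]]
    return out


def logistic_impute(
    y_obs: np.ndarray,
    X_obs: np.ndarray,
    X_mis: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Bayesian logistic-regression imputation for a 0/1 target.

    Fit by IRLS, draw coefficients from the asymptotic normal approximation
    N(beta_hat, inverse Fisher information), and impute each missing row as
    Bernoulli(expit(x . beta_star)). A single observed class imputes that
    constant class.
    """
    y_obs = np.asarray(y_obs, dtype=float)
    classes = np.unique(y_obs)
    if len(classes) == 1:
        return np.full(len(X_mis), classes[0])
    beta_hat, cov, _ = fit_logistic_full(y_obs, X_obs, intercept=True)
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        chol = np.linalg.cholesky(cov + 1e-8 * np.eye(len(cov)))
    beta_star = beta_hat + chol @ rng.standard_normal(len(beta_hat))
    Xm = np.column_stack([np.ones(len(X_mis)), X_mis])
    p = expit(Xm @ beta_star)
    return (rng.random(len(p)) < p).astype(float)


def fcs_run(
    data: MixedDataset,
    seed: int,
    params: FcsParams | None = None,
) -> ImputationResult:
    """Run m independent chained-equations chains and return their endpoints.

    Incomplete variables must be binary, continuous, or semicontinuous
    (semicontinuous targets are imputed by pmm on the raw column; use
    :func:`fcs_two_step` for the two-part treatment).
    """
    params = params or FcsParams()
    incomplete = [v for v in data.schema if data.data[v.name].isna().any()]
    for v in incomplete:
        if v.vtype not in ("continuous", "semicontinuous", "binary"):
            raise ImputationError(
                f"{v.name}: FCS conditional models support binary/continuous/"
                f"semicontinuous targets, not {v.vtype}"
            )
    if not incomplete:
        return ImputationResult(
            kind="multiple", method="fcs",
            completed=[data.copy() for _ in range(params.m)],
            diagnostics={"iterations": 0, "incomplete": []},
        )

    streams = np.random.SeedSequence(seed).spawn(params.m)
    completed = []
    for ss in streams:
        rng = np.random.default_rng(ss)
        working = data.data.copy()
        # initialize by marginal draws from the observed values
        for v in incomplete:
            col = working[v.name]
            miss = col.isna()
            obs_vals = col.dropna().to_numpy()
            fill = rng.choice(obs_vals, size=int(miss.sum()), replace=True)
            working.loc[miss, v.name] = fill
        for _ in range(params.iterations):
            for v in incomplete:
                preds = [name for name in data.names if name != v.name]
                y_obs, X_obs, X_mis, mis_idx = design_for_imputation(
                    data, v.name, preds, working
                )
                if len(X_mis) == 0:
                    continue
                if v.vtype == "binary":
                    imp = logistic_impute(y_obs, X_obs, X_mis, rng)
                    labels = np.asarray(data.var(v.name).levels, dtype=object)
                    working.iloc[mis_idx, working.columns.get_loc(v.name)] = (
                        labels[imp.astype(int)]
                    )
                else:
                    imp = pmm_impute(y_obs, X_obs, X_mis, params.k_donors, rng)
                    working.iloc[mis_idx, working.columns.get_loc(v.name)] = imp
        completed.append(MixedDataset(working, data.schema))
    return ImputationResult(
        kind="multiple", method="fcs", completed=completed,
        diagnostics={"iterations": params.iterations,
                     "incomplete": [v.name for v in incomplete]},
    )


def fcs_two_step(
    data: MixedDataset, seed: int, params: FcsParams | None = None
) -> ImputationResult:
    """FCS with the two-part semicontinuous procedure (indicator by logistic
    regression, positive part by pmm on observed-positive rows)."""
    return two_step_wrap(fcs_run)(data, seed=seed, params=params)
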