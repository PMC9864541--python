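"""Estimands and estimators: means, proportions, regression coefficients.

Supports four data situations: fully observed data, complete-case (listwise
deleted) data, multiply imputed data (m completed datasets pooled by the
arithmetic mean of per-dataset estimates — Rubin's rule for the point
estimate), and fractionally imputed data (recipients expanded into their
fractional records, estimators weighted by the fractional weights).

Regression fits are ordinary least squares (via a numerically stable
least-squares solve) and logistic regression by iteratively reweighted least
squares run to a gradient max-norm below 1e-8, with a ridge-stabilized
fallback under separation or rank deficiency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .core import FractionalAssignment, ImputationResult
from .design import DesignError, encode_columns
from .schema import MixedDataset, VariableSchema


class EstimationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Model fits
# ---------------------------------------------------------------------------

def fit_linear(
    y: np.ndarray,
    X: np.ndarray,
    weights: np.ndarray | None = None,
    intercept: bool = True,
) -> np.ndarray:
    """Weighted least squares. Returns coefficients (intercept first if added).

    Rank-deficient designs fall back to the minimum-norm solution with a
    warning.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if intercept:
        X = np.column_stack([np.ones(len(y)), X])
    if weights is not None:
        sw = np.sqrt(np.asarray(weights, dtype=float))
        X = X * sw[:, None]
        y = y * sw
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        warnings.warn("rank-deficient linear design; minimum-norm solution used",
                      stacklevel=2)
    return beta


def fit_logistic(
    y: np.ndarray,
    X: np.ndarray,
    weights: np.ndarray | None = None,
    intercept: bool = True,
    tol: float = 1e-8,
    max_iter: int = 100,
    ridge: float = 0.0,
) -> np.ndarray:
    """Logistic regression by IRLS to gradient max-norm < ``tol``.

    Under complete separation or ill conditioning the fit is retried with a
    small ridge penalty and a warning. Returns coefficients only; see
    :func:`fit_logistic_full` for the covariance.
    """
    return fit_logistic_full(y, X, weights=weights, intercept=intercept,
                             tol=tol, max_iter=max_iter, ridge=ridge)[0]


def fit_logistic_full(
    y: np.ndarray,
    X: np.ndarray,
    weights: np.ndarray | None = None,
    intercept: bool = True,
    tol: float = 1e-8,
    max_iter: int = 100,
    ridge: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """IRLS logistic fit returning (beta, covariance, stabilized_flag).

    The covariance is the inverse (penalized) Fisher information at the
    optimum — the asymptotic normal approximation used for posterior draws.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if intercept:
        X = np.column_stack([np.ones(len(y)), X])
    w = np.ones(len(y)) if weights is None else np.asarray(weights, dtype=float)

    def irls(lam: float) -> tuple[np.ndarray, np.ndarray, bool]:
        p = X.shape[1]
        beta = np.zeros(p)
        pen = lam * np.eye(p)
        for _ in range(max_iter):
            eta = np.clip(X @ beta, -30, 30)
            mu = expit(eta)
            grad = X.T @ (w * (y - mu)) - lam * beta
            if np.max(np.abs(grad)) < tol:
                H = X.T @ ((w * mu * (1 - mu))[:, None] * X) + pen
                return beta, np.linalg.inv(H), True
            H = X.T @ ((w * mu * (1 - mu))[:, None] * X) + pen
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                return beta, np.full((p, p), np.nan), False
            if not np.isfinite(step).all() or np.max(np.abs(beta + step)) > 1e4:
                return beta, np.full((p, p), np.nan), False
            beta = beta + step
        return beta, np.linalg.inv(X.T @ ((w * expit(np.clip(X @ beta, -30, 30))
                                           * (1 - expit(np.clip(X @ beta, -30, 30))))[:, None]
                                          * X) + pen), True

    beta, cov, ok = irls(ridge)
    if not ok or not np.isfinite(cov).all():
        warnings.warn("logistic fit unstable (separation?); ridge-stabilized fit used",
                      stacklevel=2)
        beta, cov, ok = irls(max(ridge, 1e-3))
        if not ok:
            raise EstimationError("logistic fit failed even with ridge stabilization")
        return beta, cov, True
    return beta, cov, False


# ---------------------------------------------------------------------------
# Analysis plans
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DescriptiveEstimand:
    """Mean of a numeric variable or proportion of a categorical level."""

    variable: str
    statistic: str = "mean"          # "mean" or "proportion"
    level: str | None = None

    @property
    def id(self) -> str:
        if self.statistic == "proportion":
            return f"prop({self.variable}={self.level})"
        return f"mean({self.variable})"

    @property
    def variables(self) -> tuple[str, ...]:
        return (self.variable,)


@dataclass(frozen=True)
class RegressionEstimand:
    """One coefficient of a linear or logistic regression model.

    ``coefficient`` names a design column: ``var`` for a numeric predictor or
    ``var=level`` for a categorical indicator.
    """

    outcome: str
    predictors: tuple[str, ...]
    family: str                      # "linear" or "logistic"
    coefficient: str

    @property
    def id(self) -> str:
        return f"{self.family}({self.outcome})[{self.coefficient}]"

    @property
    def variables(self) -> tuple[str, ...]:
        return (self.outcome,) + tuple(self.predictors)


Estimand = DescriptiveEstimand | RegressionEstimand


@dataclass(frozen=True)
class AnalysisPlan:
    estimands: tuple[Estimand, ...]

    def __post_init__(self) -> None:
        ids = [e.id for e in self.estimands]
        if len(set(ids)) != len(ids):
            raise EstimationError("duplicate estimand ids in plan")

    @property
    def ids(self) -> list[str]:
        return [e.id for e in self.estimands]


@dataclass(frozen=True)
class PointEstimate:
    estimand: str
    value: float
    n: int
    method: str


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

def _compute_estimand(
    df: pd.DataFrame,
    by_name: dict[str, VariableSchema],
    e: Estimand,
    weights: np.ndarray | None = None,
) -> float:
    for name in e.variables:
        if name not in by_name:
            raise EstimationError(f"estimand references unknown column {name!r}")
    w = np.ones(len(df)) if weights is None else np.asarray(weights, dtype=float)
    if len(df) == 0 or w.sum() == 0:
        return np.nan
    if isinstance(e, DescriptiveEstimand):
        v = by_name[e.variable]
        if e.statistic == "mean":
            x = df[e.variable].to_numpy(dtype=float)
        elif e.statistic == "proportion":
            if e.level is None:
                raise EstimationError(f"{e.id}: proportion estimand needs a level")
            x = (df[e.variable].to_numpy() == e.level).astype(float)
        else:
            raise EstimationError(f"unknown statistic {e.statistic!r}")
        return float(np.sum(w * x) / np.sum(w))
    # regression
    v_out = by_name[e.outcome]
    if v_out.is_categorical:
        levels = list(v_out.levels)
        y = pd.Categorical(df[e.outcome], categories=levels).codes.astype(float)
    else:
        y = df[e.outcome].to_numpy(dtype=float)
    X, names = encode_columns(df, [by_name[p] for p in e.predictors], standardize=False)
    if e.coefficient not in names:
        raise EstimationError(f"{e.id}: coefficient {e.coefficient!r} not in design {names}")
    j = names.index(e.coefficient) + 1  # +1 for intercept
    try:
        if e.family == "linear":
            beta = fit_linear(y, X, weights=w)
        elif e.family == "logistic":
            if len(np.unique(y)) < 2:
                return np.nan
            beta = fit_logistic(y, X, weights=w)
        else:
            raise EstimationError(f"unknown family {e.family!r}")
    except (EstimationError, DesignError, np.linalg.LinAlgError):
        return np.nan
    return float(beta[j])


def estimate_all(
    df: pd.DataFrame,
    schema: Sequence[VariableSchema],
    plan: AnalysisPlan,
    weights: np.ndarray | None = None,
) -> dict[str, float]:
    """All plan estimands on a complete (or completed) data frame."""
    by_name = {v.name: v for v in schema}
    return {e.id: _compute_estimand(df, by_name, e, weights) for e in plan.estimands}


def complete_case(data: MixedDataset, plan: AnalysisPlan) -> dict[str, PointEstimate]:
    """Listwise-deletion estimates: each estimand drops rows missing ANY of
    the variables it references. Zero surviving rows yield an undefined (NaN)
    estimate, surfaced rather than dropped."""
    by_name = {v.name: v for v in data.schema}
    out = {}
    for e in plan.estimands:
        sub = data.data.dropna(subset=list(e.variables))
        value = _compute_estimand(sub, by_name, e) if len(sub) else np.nan
        out[e.id] = PointEstimate(e.id, value, n=len(sub), method="complete_case")
    return out


def pool_multiple(values: Sequence[float]) -> float:
    """Rubin's rule for the point estimate: the mean of per-dataset estimates.
    Any undefined component makes the pooled estimate undefined."""
    arr = np.asarray(list(values), dtype=float)
    if len(arr) == 0:
        raise EstimationError("nothing to pool")
    if np.isnan(arr).any():
        return np.nan
    return float(arr.mean())


def estimate_multiple(result: ImputationResult, plan: AnalysisPlan) -> dict[str, float]:
    """Per-dataset estimates pooled across the m completed datasets."""
    if result.kind != "multiple":
        raise EstimationError("estimate_multiple requires a multiple-imputation result")
    per = [estimate_all(c.data, c.schema, plan) for c in result.completed]
    return {eid: pool_multiple([p[eid] for p in per]) for eid in plan.ids}


def expand_fractional(
    data: MixedDataset, assignment: FractionalAssignment
) -> tuple[pd.DataFrame, np.ndarray]:
    """Expand recipients into fractional records.

    Non-recipient rows carry weight 1. Each recipient is replaced by its M
    fractional records; within one record every missing cell is filled from
    the SAME donor row, and the record carries that donor's fractional weight.
    """
    recipients = sorted(assignment.donors)
    base_idx = data.data.index.difference(recipients)
    frames = [data.data.loc[base_idx]]
    weights = [np.ones(len(base_idx))]
    if recipients:
        M = max(len(assignment.donors[r]) for r in recipients)
        for k in range(M):
            rows = [r for r in recipients if len(assignment.donors[r]) > k]
            if not rows:
                continue
            donor_rows = [assignment.donors[r][k] for r in rows]
            recip = data.data.loc[rows]
            donor = data.data.loc[donor_rows]
            donor.index = recip.index
            filled = recip.where(recip.notna(), other=donor)
            frames.append(filled)
            weights.append(np.array(
                [float(assignment.weights[r][k]) for r in rows]))
    df = pd.concat(frames, ignore_index=True)
    return df, np.concatenate(weights)


def fractional_estimate(result: ImputationResult, plan: AnalysisPlan) -> dict[str, float]:
    """Weighted estimates on the fractional expansion of a hot-deck result."""
    if result.kind != "fractional" or result.fractional is None:
        raise EstimationError("fractional_estimate requires a fractional result")
    data = result.completed[0]
    df, w = expand_fractional(data, result.fractional)
    if df.isna().any().any():
        raise EstimationError("fractional expansion left missing cells")
    return estimate_all(df, data.schema, plan, weights=w)
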