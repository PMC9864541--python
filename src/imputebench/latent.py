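"""Joint-model imputation via a latent multivariate normal.

Every variable is linked to one coordinate of a latent Gaussian vector:
continuous variables by standardization (after a log transform for
``exp``-linked, right-skewed columns), categorical variables by probit
thresholds fixed at the standard-normal quantiles of their observed
cumulative frequencies. The joint distribution is parameterized by a
sequential (triangular) regression factorization in schema order — variable j
regressed on variables 1..j-1 on the latent scale — which guarantees a
positive-definite implied covariance.

The sampler alternates (a) conjugate Bayesian draws of the triangular
regression coefficients and residual variances given the current latent
matrix with (b) redraws of the latent values: missing cells from their
conditional normal given the rest of the row, observed categorical cells from
the normal truncated to their category's threshold interval. After burn-in,
m imputation draws are taken from consecutive refreshes and back-transformed
through the links.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import ImputationError, ImputationResult, two_step_wrap
from .schema import MixedDataset, VariableSchema


@dataclass(frozen=True)
class LatentParams:
    iterations: int = 10
    m: int = 10
    ridge: float = 1e-8

    def __post_init__(self) -> None:
        if self.iterations < 1 or self.m < 1:
            raise ImputationError("iterations and m must be >= 1")


class _Link:
    """Per-variable latent link: transform parameters and thresholds."""

    def __init__(self, v: VariableSchema, observed: pd.Series):
        self.v = v
        obs = observed.dropna()
        if v.is_categorical:
            freqs = obs.value_counts(normalize=True)
            probs = np.array([freqs.get(level, 0.0) for level in v.levels])
            # guard absent levels so thresholds stay strictly increasing
            probs = np.clip(probs, 1e-6, None)
            probs = probs / probs.sum()
            cum = np.cumsum(probs)[:-1]
            self.thresholds = stats.norm.ppf(cum)
            self.log = False
        else:
            x = obs.to_numpy(dtype=float)
            self.log = v.transform == "exp" and (x > 0).all() and len(x) > 0
            t = np.log(x) if self.log else x
            self.mu = float(np.mean(t))
            self.sd = float(np.std(t)) or 1.0
            self.thresholds = None

    def to_latent_obs(self, x: np.ndarray) -> np.ndarray:
        """Deterministic map for observed continuous values."""
        t = np.log(np.maximum(x, 1e-300)) if self.log else x
        return (t - self.mu) / self.sd

    def category_interval(self, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        edges = np.concatenate([[-np.inf], self.thresholds, [np.inf]])
        return edges[codes], edges[codes + 1]

    def from_latent(self, z: np.ndarray) -> np.ndarray:
        if self.v.is_categorical:
            idx = np.searchsorted(self.thresholds, z, side="right")
            return np.asarray(self.v.levels, dtype=object)[idx]
        x = z * self.sd + self.mu
        if self.log:
            x = np.exp(x)
        if self.v.vtype == "semicontinuous":
            x = np.maximum(x, 0.0)
        return x


def _truncated_normal_draw(
    mean: np.ndarray, sd: float, lo: np.ndarray, hi: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Inverse-CDF draws from N(mean, sd) truncated to (lo, hi)."""
    a = stats.norm.cdf((lo - mean) / sd)
    b = stats.norm.cdf((hi - mean) / sd)
    u = a + (b - a) * rng.random(len(mean))
    u = np.clip(u, 1e-12, 1 - 1e-12)
    return mean + sd * stats.norm.ppf(u)


def latent_run(
    data: MixedDataset,
    seed: int,
    params: LatentParams | None = None,
) -> ImputationResult:
    """Fit the latent joint model and emit m imputation draws.

    Incomplete variables must be continuous, semicontinuous or binary
    (ordinal/nominal covariates are handled through ordered probit
    thresholds; unordered incomplete variables are not supported).
    """
    params = params or LatentParams()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n, p = len(data), len(data.schema)
    links = [_Link(v, data.data[v.name]) for v in data.schema]

    miss = ~data.mask.to_numpy()                    # (n, p) True = missing
    cat = np.array([v.is_categorical for v in data.schema])
    cat_codes = np.full((n, p), -1, dtype=np.int64)
    for j, v in enumerate(data.schema):
        if cat[j]:
            codes = pd.Categorical(
                data.data[v.name], categories=list(v.levels)
            ).codes.astype(np.int64)
            cat_codes[:, j] = codes

    # --- initialize latent matrix -----------------------------------------
    Z = np.empty((n, p))
    for j, (v, link) in enumerate(zip(data.schema, links)):
        obs = ~miss[:, j]
        if cat[j]:
            lo, hi = link.category_interval(np.maximum(cat_codes[obs, j], 0))
            Z[obs, j] = _truncated_normal_draw(np.zeros(obs.sum()), 1.0, lo, hi, rng)
        else:
            Z[obs, j] = link.to_latent_obs(data.data[v.name].to_numpy(dtype=float)[obs])
        Z[miss[:, j], j] = rng.standard_normal(int(miss[:, j].sum()))

    trace: list[list[float]] = []

    def draw_parameters() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Triangular Bayesian regression draws: intercepts b0, strictly
        lower-triangular B, residual sds."""
        b0 = np.zeros(p)
        B = np.zeros((p, p))
        sds = np.ones(p)
        for j in range(p):
            D = np.column_stack([np.ones(n), Z[:, :j]]) if j else np.ones((n, 1))
            q = D.shape[1]
            DtD = D.T @ D + params.ridge * np.eye(q)
            DtD_inv = np.linalg.inv(DtD)
            beta_hat = DtD_inv @ (D.T @ Z[:, j])
            resid = Z[:, j] - D @ beta_hat
            df = max(n - q, 1)
            sigma2 = float(resid @ resid) / rng.chisquare(df)
            sigma2 = max(sigma2, 1e-10)
            try:
                chol = np.linalg.cholesky(sigma2 * DtD_inv)
            except np.linalg.LinAlgError as exc:
                raise ImputationError(
                    "non-positive-definite coefficient covariance in latent fit"
                ) from exc
            beta = beta_hat + chol @ rng.standard_normal(q)
            b0[j] = beta[0]
            B[j, :j] = beta[1:]
            sds[j] = np.sqrt(sigma2)
        return b0, B, sds

    def refresh_latent(b0: np.ndarray, B: np.ndarray, sds: np.ndarray) -> None:
        """Column-wise Gibbs update of missing cells and observed categorical
        cells from the implied joint normal."""
        A = np.eye(p) - B
        mu = np.linalg.solve(A, b0)
        D_inv = 1.0 / sds**2
        Omega = A.T @ (D_inv[:, None] * A)      # joint precision
        for j in range(p):
            upd_mis = miss[:, j]
            has_cat_obs = bool(cat[j]) and bool((~upd_mis).any())
            if not upd_mis.any() and not has_cat_obs:
                continue
            c = (Z - mu) @ Omega[:, j]
            cond_sd = 1.0 / np.sqrt(Omega[j, j])
            cond_mean = mu[j] - (c - Omega[j, j] * (Z[:, j] - mu[j])) / Omega[j, j]
            if upd_mis.any():
                Z[upd_mis, j] = cond_mean[upd_mis] + cond_sd * rng.standard_normal(
                    int(upd_mis.sum()))
            if cat[j]:
                rows = ~miss[:, j]
                lo, hi = links[j].category_interval(cat_codes[rows, j])
                Z[rows, j] = _truncated_normal_draw(
                    cond_mean[rows], cond_sd, lo, hi, rng)

    for _ in range(params.iterations):
        b0, B, sds = draw_parameters()
        refresh_latent(b0, B, sds)
        trace.append([float(Z[miss[:, j], j].mean()) if miss[:, j].any() else np.nan
                      for j in range(p)])

    completed = []
    for _ in range(params.m):
        b0, B, sds = draw_parameters()
        refresh_latent(b0, B, sds)
        df = data.data.copy()
        for j, (v, link) in enumerate(zip(data.schema, links)):
            mj = miss[:, j]
            if mj.any():
                vals = link.from_latent(Z[mj, j])
                df.loc[mj, v.name] = vals
        completed.append(MixedDataset(df, data.schema))
    return ImputationResult(
        kind="multiple", method="latent", completed=completed,
        diagnostics={"iterations": params.iterations, "trace": trace},
    )


def latent_two_step(
    data: MixedDataset, seed: int, params: LatentParams | None = None
) -> ImputationResult:
    """Latent joint imputation with the two-part semicontinuous procedure."""
    return two_step_wrap(latent_run)(data, seed=seed, params=params)
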