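"""Logistic-selection amputation: MAR and self-masking MNAR missingness.

Missingness for each outcome is imposed by a logistic selection model

    P_i = expit(phi0 + sum_j phi_j x_ij),

where the x_ij are dummy-coded categorical and standardized continuous
covariates with slopes phi_j in {-1, +1}, and — under MNAR — the standardized
outcome itself enters with a self-mask coefficient phi_self (0.1 for small
MNAR, 3 for large MNAR; 0 is MAR). The intercept phi0 is calibrated so the
mean of P equals the target missing rate (default 40%), and the mask is drawn
cell-wise as Bernoulli(P). Covariates are never amputed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .design import DesignError, design_vector
from .schema import MixedDataset

MECHANISMS = ("MAR", "MNAR_small", "MNAR_large")

#: self-mask coefficient of each packaged mechanism
PHI_SELF = {"MAR": 0.0, "MNAR_small": 0.1, "MNAR_large": 3.0}


class AmputationError(ValueError):
    pass


@dataclass(frozen=True)
class AmputationConfig:
    """Selection model for one outcome.

    ``slopes`` maps design-column names (``var`` / ``var=level``) to +-1.
    ``phi_self`` is the coefficient of the standardized outcome itself
    (0 = MAR). ``target_rate`` is the calibrated mean missingness.
    """

    target: str
    predictors: tuple[str, ...]
    slopes: Mapping[str, float]
    phi_self: float = 0.0
    target_rate: float = 0.4

    def __post_init__(self) -> None:
        if not (0.0 <= self.target_rate < 1.0):
            raise AmputationError("target_rate must lie in [0, 1)")
        bad = {k: v for k, v in self.slopes.items() if v not in (-1.0, 1.0, -1, 1)}
        if bad:
            raise AmputationError(f"slopes must be exactly -1 or +1, got {bad}")

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "predictors": list(self.predictors),
            "slopes": {k: float(v) for k, v in self.slopes.items()},
            "phi_self": float(self.phi_self),
            "target_rate": float(self.target_rate),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AmputationConfig":
        return cls(
            target=d["target"],
            predictors=tuple(d["predictors"]),
            slopes=dict(d["slopes"]),
            phi_self=float(d.get("phi_self", 0.0)),
            target_rate=float(d.get("target_rate", 0.4)),
        )


@dataclass
class MissingnessRealization:
    """One amputation draw: probabilities, mask and realized rates per outcome."""

    mask: pd.DataFrame                      # True = missing; columns = amputed outcomes
    probabilities: pd.DataFrame             # P per (row, outcome)
    realized_rate: dict[str, float]
    phi0: dict[str, float]


def save_amputation_configs(configs: Sequence[AmputationConfig], path) -> None:
    """Write configs to a YAML file."""
    import yaml
    from pathlib import Path
    Path(path).write_text(
        yaml.safe_dump({"configs": [c.to_dict() for c in configs]}, sort_keys=False))


def load_amputation_configs(path) -> list[AmputationConfig]:
    import yaml
    from pathlib import Path
    payload = yaml.safe_load(Path(path).read_text())
    return [AmputationConfig.from_dict(d) for d in payload["configs"]]


def missingness_probability(
    X: np.ndarray, phi0: float, slopes: np.ndarray
) -> np.ndarray:
    """Selection probabilities P_i = expit(phi0 + X_i . slopes).

    Overflow-safe through the logistic sigmoid; non-finite inputs are rejected.
    """
    X = np.asarray(X, dtype=float)
    slopes = np.asarray(slopes, dtype=float)
    if X.ndim != 2 or X.shape[1] != slopes.shape[0]:
        raise AmputationError(
            f"design has {X.shape[1] if X.ndim == 2 else '?'} columns "
            f"but {slopes.shape[0]} slopes were given"
        )
    if not np.isfinite(X).all():
        raise AmputationError("design matrix contains non-finite entries")
    return expit(phi0 + X @ slopes)


def calibrate_intercept(
    X: np.ndarray, slopes: np.ndarray, target_rate: float, tol: float = 1e-10
) -> float:
    """Find phi0 with mean_i P_i(phi0) = target_rate.

    Mean selection probability is strictly increasing in phi0 and spans (0, 1),
    so a unique root always exists; it is found by bracketed root finding.
    Deterministic, |mean P - target| <= 1e-8 at the returned value.
    """
    if not (0.0 < target_rate < 1.0):
        raise AmputationError("calibration target must lie in (0, 1)")
    s = np.asarray(X, dtype=float) @ np.asarray(slopes, dtype=float)

    def gap(phi0: float) -> float:
        return float(np.mean(expit(phi0 + s))) - target_rate

    lo, hi = -40.0 - float(np.max(np.abs(s)) if s.size else 0.0), 0.0
    hi = -lo
    return float(brentq(gap, lo, hi, xtol=tol))


def derive_slopes(data: MixedDataset, target: str, predictors: Sequence[str]) -> dict[str, float]:
    """Sign-of-association slope assignment.

    Each design column gets slope +1 if its sample correlation with the
    numeric coding of the target is nonnegative, else -1 — so that
    missingness is informatively driven by covariates associated with the
    outcome.
    """
    X, names = design_vector(data, predictors)
    y = data.numeric(target)
    y = y - y.mean()
    slopes = {}
    for j, name in enumerate(names):
        x = X[:, j] - X[:, j].mean()
        cov = float(x @ y)
        slopes[name] = 1.0 if cov >= 0 else -1.0
    return slopes


def build_amputation_configs(
    data: MixedDataset,
    mechanism: str,
    outcomes: Sequence[str] | None = None,
    predictors: Sequence[str] | None = None,
    target_rate: float = 0.4,
) -> list[AmputationConfig]:
    """Packaged per-outcome configs: all covariates as predictors, slopes from
    marginal associations, self-mask coefficient set by the mechanism."""
    if mechanism not in MECHANISMS:
        raise AmputationError(f"unknown mechanism {mechanism!r}")
    outcomes = list(outcomes) if outcomes is not None else data.outcome_names
    predictors = tuple(predictors) if predictors is not None else tuple(data.covariate_names)
    phi_self = PHI_SELF[mechanism]
    return [
        AmputationConfig(
            target=name,
            predictors=predictors,
            slopes=derive_slopes(data, name, predictors),
            phi_self=phi_self,
            target_rate=target_rate,
        )
        for name in outcomes
    ]


def ampute(
    data: MixedDataset,
    configs: Sequence[AmputationConfig],
    mechanism: str,
    seed: int,
) -> tuple[MixedDataset, MissingnessRealization]:
    """Apply the selection model of each config to a complete dataset.

    Each outcome's mask is drawn from an independent random stream derived
    from ``seed``. The intercept is calibrated on the realized sample. Under
    MNAR the standardized outcome itself is appended to the design with its
    phi_self coefficient. Covariates are never amputed.
    """
    if mechanism not in MECHANISMS:
        raise AmputationError(f"unknown mechanism {mechanism!r}")
    if not data.is_complete:
        raise AmputationError("ampute requires a fully observed dataset")
    targets = [c.target for c in configs]
    if len(set(targets)) != len(targets):
        raise AmputationError("each outcome may appear in at most one config")
    expected_phi = PHI_SELF[mechanism]
    for c in configs:
        if c.phi_self != expected_phi:
            raise AmputationError(
                f"{c.target}: phi_self={c.phi_self} inconsistent with mechanism "
                f"{mechanism} (expected {expected_phi})"
            )
        if data.var(c.target).role != "outcome":
            raise AmputationError(f"{c.target}: only outcome variables may be amputed")

    streams = np.random.SeedSequence(seed).spawn(len(configs))
    out = data.copy()
    n = len(data)
    mask = pd.DataFrame(False, index=range(n), columns=targets)
    probs = pd.DataFrame(0.0, index=range(n), columns=targets)
    realized, phi0s = {}, {}

    for c, ss in zip(configs, streams):
        rng = np.random.default_rng(ss)
        if c.target_rate == 0.0:
            realized[c.target] = 0.0
            phi0s[c.target] = -np.inf
            continue
        include_self = c.target if c.phi_self != 0.0 else None
        X, names = design_vector(data, c.predictors, include_self=include_self)
        pred_names = names[:-1] if include_self is not None else names
        missing_slopes = [nm for nm in pred_names if nm not in c.slopes]
        if missing_slopes:
            raise AmputationError(f"{c.target}: no slope given for {missing_slopes}")
        slope_vec = np.array([c.slopes[nm] for nm in pred_names], dtype=float)
        if include_self is not None:
            slope_vec = np.append(slope_vec, c.phi_self)
        phi0 = calibrate_intercept(X, slope_vec, c.target_rate)
        P = missingness_probability(X, phi0, slope_vec)
        miss = rng.random(n) < P
        mask[c.target] = miss
        probs[c.target] = P
        realized[c.target] = float(miss.mean())
        phi0s[c.target] = phi0
        col = out.data[c.target]
        out.data[c.target] = col.where(~miss, other=np.nan)

    return out, MissingnessRealization(mask=mask, probabilities=probs,
                                       realized_rate=realized, phi0=phi0s)
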