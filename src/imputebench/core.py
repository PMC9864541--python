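"""Shared imputer infrastructure.

Defines the common fit-impute contract and its result container, the
two-part (indicator + positive part) handling of semicontinuous variables,
and design-matrix preparation on partially observed data.

Every imputer in this package maps ``(MixedDataset, params, seed)`` to an
:class:`ImputationResult` that either holds ``m`` completed datasets
(multiple imputation) or one dataset plus a :class:`FractionalAssignment`
(fractional hot-deck). Observed cells are preserved bit-identically; imputed
values respect the schema's type and level sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .design import DesignError, encode_columns
from .schema import MixedDataset, SchemaError, VariableSchema


class ImputationError(ValueError):
    pass


@dataclass
class FractionalAssignment:
    """Per-recipient donor lists with fractional weights.

    ``donors[i]`` are the donor row indices of recipient row ``i`` and
    ``weights[i]`` their fractional weights, stored as exact rationals summing
    to 1 per recipient.
    """

    donors: dict[int, list[int]]
    weights: dict[int, list[Fraction]]

    def __post_init__(self) -> None:
        for r, w in self.weights.items():
            if sum(w) != 1:
                raise ImputationError(f"recipient {r}: fractional weights sum to {sum(w)}")
            if len(w) != len(self.donors[r]):
                raise ImputationError(f"recipient {r}: donors/weights length mismatch")


@dataclass
class ImputationResult:
    """Outcome of one imputation run.

    ``kind`` is ``"multiple"`` (``completed`` holds m complete datasets) or
    ``"fractional"`` (``completed`` holds the single input dataset —
    still containing its missing cells — and ``fractional`` the donor
    assignment that completes it). ``diagnostics`` carries method-specific
    run information (iterations, collapsed cells, warnings).
    """

    kind: str
    method: str
    completed: list[MixedDataset]
    fractional: FractionalAssignment | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("multiple", "fractional"):
            raise ImputationError(f"unknown result kind {self.kind!r}")
        if self.kind == "fractional" and self.fractional is None:
            raise ImputationError("fractional result requires an assignment")

    @property
    def m(self) -> int:
        return len(self.completed)


#: the imputer contract: fit_impute(data, seed, **params) -> ImputationResult
Imputer = Callable[..., ImputationResult]


# ---------------------------------------------------------------------------
# Semicontinuous two-part handling
# ---------------------------------------------------------------------------

IND_SUFFIX = "__ind"
POS_SUFFIX = "__pos"


def split_semicontinuous(column: pd.Series) -> tuple[pd.Series, pd.Series]:
    """Split a nonnegative column into (indicator, positive part).

    The indicator is "0"/"1" (zero vs. positive); the positive part equals the
    value where positive and is NaN elsewhere. Missing cells propagate to both
    parts. Exact round-trip through :func:`merge_semicontinuous` on observed
    cells.
    """
    x = column.astype(float)
    obs = x.notna()
    if (x[obs] < 0).any():
        raise ImputationError(f"{column.name}: semicontinuous values must be >= 0")
    indicator = pd.Series(np.nan, index=column.index, dtype=object)
    indicator[obs] = np.where(x[obs] > 0, "1", "0")
    positive = x.where(obs & (x > 0), other=np.nan)
    return indicator, positive


def merge_semicontinuous(indicator: pd.Series, positive: pd.Series) -> pd.Series:
    """Recombine a (indicator, positive part) pair: 0 where indicator is "0",
    the positive part where "1", NaN where the indicator is missing."""
    out = pd.Series(np.nan, index=indicator.index, dtype=float)
    obs = indicator.notna()
    zero = obs & (indicator == "0")
    one = obs & (indicator == "1")
    out[zero] = 0.0
    out[one] = positive[one].astype(float)
    return out


def split_dataset(data: MixedDataset) -> MixedDataset:
    """Expand every semicontinuous variable into an indicator/positive pair.

    The positive part is flagged as an ``exp``-linked (log-scale) continuous
    variable, so downstream models treat it on the log scale; the indicator is
    a binary outcome. Rows with an observed zero leave the positive part
    missing — the positive-part model is fit on observed-positive rows only.
    """
    new_schema: list[VariableSchema] = []
    cols: dict[str, pd.Series] = {}
    for v in data.schema:
        if v.vtype == "semicontinuous":
            ind, pos = split_semicontinuous(data.data[v.name])
            ind_name, pos_name = v.name + IND_SUFFIX, v.name + POS_SUFFIX
            new_schema.append(VariableSchema(ind_name, v.role, "binary", levels=("0", "1")))
            new_schema.append(VariableSchema(pos_name, v.role, "continuous", transform="exp"))
            cols[ind_name] = ind
            cols[pos_name] = pos
        else:
            new_schema.append(v)
            cols[v.name] = data.data[v.name]
    return MixedDataset(pd.DataFrame(cols), new_schema)


def merge_dataset(completed: MixedDataset, original: MixedDataset) -> MixedDataset:
    """Collapse indicator/positive pairs back to the original schema.

    Observed cells are restored verbatim from the original dataset; imputed
    semicontinuous cells become 0 where the imputed indicator is "0" and the
    imputed positive draw where it is "1".
    """
    cols: dict[str, pd.Series] = {}
    for v in original.schema:
        if v.vtype == "semicontinuous":
            ind = completed.data[v.name + IND_SUFFIX]
            pos = completed.data[v.name + POS_SUFFIX]
            merged = merge_semicontinuous(ind, pos)
            orig = original.data[v.name]
            cols[v.name] = orig.where(orig.notna(), other=merged)
        else:
            cols[v.name] = completed.data[v.name]
    return MixedDataset(pd.DataFrame(cols), original.schema)


def two_step_wrap(imputer: Imputer) -> Imputer:
    """Wrap an imputer with the two-part semicontinuous procedure.

    The wrapped imputer splits each semicontinuous variable into a binary
    indicator (imputed with the binary method) and a log-scale positive part
    (imputed with the continuous method, modeled on observed-positive rows),
    then merges. With no semicontinuous variables the wrapper is the identity.
    """

    def run(data: MixedDataset, seed: int, **params) -> ImputationResult:
        if not any(v.vtype == "semicontinuous" for v in data.schema):
            return imputer(data, seed=seed, **params)
        wide = split_dataset(data)
        res = imputer(wide, seed=seed, **params)
        if res.kind != "multiple":
            raise ImputationError("two_step_wrap supports multiple-imputation methods")
        merged = [merge_dataset(c, data) for c in res.completed]
        return ImputationResult(
            kind="multiple",
            method=res.method + "+2step",
            completed=merged,
            diagnostics=dict(res.diagnostics, two_step=True),
        )

    return run


# ---------------------------------------------------------------------------
# Design preparation on partially observed data
# ---------------------------------------------------------------------------

def design_for_imputation(
    data: MixedDataset,
    target: str,
    predictors: Sequence[str],
    working: pd.DataFrame,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Response and predictor matrix split by the target's original mask.

    ``working`` is the current completed copy of the data (all predictors
    filled in). Returns ``(y_obs, X_obs, X_mis, mis_index)`` where the
    partition follows the target's ORIGINAL missingness and the design is
    reference-coded and standardized.
    """
    variables = [data.var(p) for p in predictors]
    X, _ = encode_columns(working, variables, standardize=True)
    obs = data.data[target].notna().to_numpy()
    if not obs.any():
        raise ImputationError(f"{target}: no observed cases to fit on")
    y_obs = data.numeric(target)[obs]
    return y_obs, X[obs], X[~obs], np.flatnonzero(~obs)
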