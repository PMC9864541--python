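"""Design-matrix construction for mixed-type tables.

Categorical variables are reference-coded (indicator per non-reference level,
reference = first schema level); continuous and semicontinuous variables enter
as-is or standardized to sample mean 0, sd 1. Column order is deterministic:
variables in the requested order, levels in schema order.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .schema import MixedDataset, VariableSchema


class DesignError(ValueError):
    """Raised when a design matrix cannot be built (e.g. zero variance)."""


def encode_columns(
    data: pd.DataFrame,
    variables: Sequence[VariableSchema],
    standardize: bool = True,
    intercept: bool = False,
) -> tuple[np.ndarray, list[str]]:
    """Build a numeric design matrix from fully observed columns.

    Returns the matrix and its column names (``var`` for numeric columns,
    ``var=level`` for indicators).
    """
    cols: list[np.ndarray] = []
    names: list[str] = []
    n = len(data)
    if intercept:
        cols.append(np.ones(n))
        names.append("(intercept)")
    for v in variables:
        raw = data[v.name]
        if raw.isna().any():
            raise DesignError(f"{v.name}: design columns must be fully observed")
        if v.is_categorical:
            for level in v.levels[1:]:
                cols.append((raw.to_numpy() == level).astype(float))
                names.append(f"{v.name}={level}")
        else:
            x = raw.to_numpy(dtype=float)
            if standardize:
                x = standardize_column(x, v.name)
            cols.append(x)
            names.append(v.name)
    if not cols:
        return np.empty((n, 0)), names
    return np.column_stack(cols), names


def standardize_column(x: np.ndarray, name: str = "") -> np.ndarray:
    """Center/scale to sample mean 0, sd 1 (ddof=0). Zero variance is rejected."""
    x = np.asarray(x, dtype=float)
    sd = float(np.std(x))
    if sd == 0.0 or not np.isfinite(sd):
        raise DesignError(f"{name or 'column'}: zero-variance column cannot be standardized")
    return (x - float(np.mean(x))) / sd


def design_vector(
    data: MixedDataset,
    predictors: Sequence[str],
    include_self: str | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Dummy-coded/standardized predictor matrix for the missingness model.

    ``include_self`` appends the (standardized numeric coding of the) named
    outcome as the last column — the self-mask term of the MNAR selection
    model. All named columns must be fully observed.
    """
    variables = [data.var(name) for name in predictors]
    X, names = encode_columns(data.data, variables, standardize=True)
    if include_self is not None:
        self_num = data.numeric(include_self)
        if np.isnan(self_num).any():
            raise DesignError(f"{include_self}: self column must be fully observed")
        X = np.column_stack([X, standardize_column(self_num, include_self)])
        names.append(f"{include_self}(self)")
    return X, names
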