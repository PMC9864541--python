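"""Typed mixed-variable tables.

The universal data currency of the package is a :class:`MixedDataset`: a
rectangular table of named, typed columns (continuous, binary, nominal,
ordinal, semicontinuous) together with a per-cell observed/missing mask.
Missing cells are represented as NaN in the underlying :class:`pandas.DataFrame`;
categorical values are stored as their string level labels.

A :class:`VariableSchema` describes one column — its analysis role
(fully observed covariate vs. potentially incomplete outcome), its type, its
categorical levels and their population prevalences, and the latent-to-observed
link used by the synthetic generator. A :class:`PopulationSpec` bundles a full
schema with a latent correlation matrix and a sample size.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

ROLES = ("covariate", "outcome")
VTYPES = ("continuous", "binary", "nominal", "ordinal", "semicontinuous")
CATEGORICAL_VTYPES = ("binary", "nominal", "ordinal")

#: minimum population prevalence required for every level of a categorical
#: variable that is eligible for amputation (the screening rule applied when
#: selecting incomplete variables).
MIN_OUTCOME_PREVALENCE = 0.20


class SchemaError(ValueError):
    """Raised when a variable or population specification is inconsistent."""


@dataclass(frozen=True)
class VariableSchema:
    """Description of a single column of a mixed-type table.

    Parameters
    ----------
    name:
        Column identifier.
    role:
        ``"covariate"`` (always fully observed) or ``"outcome"`` (eligible for
        amputation and imputation).
    vtype:
        One of ``continuous``, ``binary``, ``nominal``, ``ordinal``,
        ``semicontinuous``.
    levels:
        Ordered level labels; required for categorical types. Binary variables
        have exactly two levels, other categoricals at least two.
    level_probs:
        Population prevalence of each level (sums to 1); used by the synthetic
        generator to place latent thresholds. For a categorical *outcome* every
        level must have prevalence >= 0.20.
    zero_mass:
        For semicontinuous variables, the population probability of an exact
        zero; must lie strictly inside (0, 1).
    loc, scale:
        Affine location/scale applied after the latent link (continuous and
        semicontinuous types).
    transform:
        Monotone latent-to-observed link tag: ``"identity"`` or ``"exp"``
        (lognormal margin, for right-skewed variables). Imputers treat
        ``"exp"``-linked continuous columns as log-scale.
    """

    name: str
    role: str
    vtype: str
    levels: tuple[str, ...] | None = None
    level_probs: tuple[float, ...] | None = None
    zero_mass: float | None = None
    loc: float = 0.0
    scale: float = 1.0
    transform: str = "identity"

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise SchemaError(f"{self.name}: unknown role {self.role!r}")
        if self.vtype not in VTYPES:
            raise SchemaError(f"{self.name}: unknown vtype {self.vtype!r}")
        if self.transform not in ("identity", "exp"):
            raise SchemaError(f"{self.name}: unknown transform {self.transform!r}")
        if self.is_categorical:
            if not self.levels or len(self.levels) < 2:
                raise SchemaError(f"{self.name}: categorical variable needs >=2 levels")
            if self.vtype == "binary" and len(self.levels) != 2:
                raise SchemaError(f"{self.name}: binary variable needs exactly 2 levels")
            if self.level_probs is not None:
                if len(self.level_probs) != len(self.levels):
                    raise SchemaError(f"{self.name}: level_probs/levels length mismatch")
                if abs(sum(self.level_probs) - 1.0) > 1e-8:
                    raise SchemaError(f"{self.name}: level_probs must sum to 1")
                if min(self.level_probs) <= 0:
                    raise SchemaError(f"{self.name}: level_probs must be positive")
                if self.role == "outcome" and min(self.level_probs) < MIN_OUTCOME_PREVALENCE:
                    raise SchemaError(
                        f"{self.name}: level prevalence "
                        f"{min(self.level_probs):.3f} < {MIN_OUTCOME_PREVALENCE} — "
                        "categorical outcomes must satisfy the >=20% occurrence "
                        "screening rule"
                    )
        else:
            if self.levels is not None:
                raise SchemaError(f"{self.name}: levels given for non-categorical variable")
        if self.vtype == "semicontinuous":
            if self.zero_mass is None or not (0.0 < self.zero_mass < 1.0):
                raise SchemaError(
                    f"{self.name}: semicontinuous variable needs zero_mass in (0, 1)"
                )
            if self.scale <= 0:
                raise SchemaError(f"{self.name}: semicontinuous scale must be > 0")
        elif self.zero_mass is not None:
            raise SchemaError(f"{self.name}: zero_mass only valid for semicontinuous")

    @property
    def is_categorical(self) -> bool:
        return self.vtype in CATEGORICAL_VTYPES

    @property
    def is_numeric(self) -> bool:
        return self.vtype in ("continuous", "semicontinuous")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items() if v is not None}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "VariableSchema":
        d = dict(d)
        for key in ("levels", "level_probs"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class PopulationSpec:
    """A complete population description for the synthetic generator.

    ``latent_correlation`` is the correlation matrix of the underlying
    multivariate-normal vector, one coordinate per schema entry, in schema
    order. It must be symmetric with unit diagonal and strictly positive
    eigenvalues.
    """

    schema: tuple[VariableSchema, ...]
    latent_correlation: np.ndarray
    n: int
    seed: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "schema", tuple(self.schema))
        R = np.asarray(self.latent_correlation, dtype=float)
        object.__setattr__(self, "latent_correlation", R)
        p = len(self.schema)
        if R.shape != (p, p):
            raise SchemaError(
                f"latent_correlation shape {R.shape} does not match {p} schema entries"
            )
        if not np.allclose(R, R.T, atol=1e-10):
            raise SchemaError("latent_correlation must be symmetric")
        if not np.allclose(np.diag(R), 1.0, atol=1e-10):
            raise SchemaError("latent_correlation must have unit diagonal")
        eigvals = np.linalg.eigvalsh(R)
        if eigvals[0] <= 0:
            raise SchemaError(
                f"latent_correlation is not positive definite: smallest "
                f"eigenvalue {eigvals[0]:.6g} <= 0"
            )
        if self.n < 1:
            raise SchemaError("n must be >= 1")

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.schema]


class MixedDataset:
    """A rectangular mixed-type table plus a missingness mask.

    ``data`` holds one column per schema entry, in schema order. Missing cells
    are NaN; categorical cells hold level labels (strings). The observed mask
    is derived from the data (``mask`` is True where observed).
    """

    def __init__(self, data: pd.DataFrame, schema: Sequence[VariableSchema]):
        schema = tuple(schema)
        names = [v.name for v in schema]
        if list(data.columns) != names:
            data = data.loc[:, names]
        self.data = data.reset_index(drop=True)
        self.schema = schema
        self._by_name = {v.name: v for v in schema}

    # -- basic accessors ---------------------------------------------------
    def __len__(self) -> int:
        return len(self.data)

    def var(self, name: str) -> VariableSchema:
        return self._by_name[name]

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.schema]

    @property
    def outcome_names(self) -> list[str]:
        return [v.name for v in self.schema if v.role == "outcome"]

    @property
    def covariate_names(self) -> list[str]:
        return [v.name for v in self.schema if v.role == "covariate"]

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean frame, True where the cell is observed."""
        return self.data.notna()

    @property
    def is_complete(self) -> bool:
        return bool(self.data.notna().all().all())

    def copy(self) -> "MixedDataset":
        return MixedDataset(self.data.copy(), self.schema)

    def validate(self) -> None:
        """Full type-conformance check (categorical levels, nonnegativity)."""
        for v in self.schema:
            col = self.data[v.name]
            obs = col.dropna()
            if v.is_categorical:
                bad = set(obs.unique()) - set(v.levels)
                if bad:
                    raise SchemaError(f"{v.name}: values {sorted(bad)} not in levels")
            elif v.vtype == "semicontinuous":
                if (obs.astype(float) < 0).any():
                    raise SchemaError(f"{v.name}: semicontinuous values must be >= 0")

    def numeric(self, name: str) -> np.ndarray:
        """Numeric coding of a column: binary -> 0/1 by level order, ordinal/
        nominal -> level index, numeric types -> float values. NaN preserved."""
        v = self._by_name[name]
        col = self.data[name]
        if v.is_categorical:
            codes = pd.Categorical(col, categories=list(v.levels)).codes.astype(float)
            codes[codes < 0] = np.nan
            return codes
        return col.to_numpy(dtype=float)

    # -- serialization -----------------------------------------------------
    def to_csv(self, csv_path: str | Path, schema_path: str | Path | None = None) -> None:
        """Write the table as CSV (missing cells empty) plus a YAML schema sidecar."""
        csv_path = Path(csv_path)
        self.data.to_csv(csv_path, index=False, na_rep="")
        if schema_path is None:
            schema_path = csv_path.with_suffix(".schema.yaml")
        save_schema(self.schema, schema_path)

    @classmethod
    def from_csv(
        cls, csv_path: str | Path, schema_path: str | Path | None = None
    ) -> "MixedDataset":
        csv_path = Path(csv_path)
        if schema_path is None:
            schema_path = csv_path.with_suffix(".schema.yaml")
        schema = load_schema(schema_path)
        dtypes = {v.name: (str if v.is_categorical else float) for v in schema}
        df = pd.read_csv(csv_path, dtype=dtypes, keep_default_na=True)
        return cls(df, schema)


def save_schema(schema: Iterable[VariableSchema], path: str | Path) -> None:
    payload = {"variables": [v.to_dict() for v in schema]}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_schema(path: str | Path) -> tuple[VariableSchema, ...]:
    payload = yaml.safe_load(Path(path).read_text())
    return tuple(VariableSchema.from_dict(d) for d in payload["variables"])


def save_population_spec(spec: PopulationSpec, path: str | Path) -> None:
    payload = {
        "n": spec.n,
        "seed": spec.seed,
        "latent_correlation": [[float(x) for x in row] for row in spec.latent_correlation],
        "variables": [v.to_dict() for v in spec.schema],
    }
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def load_population_spec(path: str | Path) -> PopulationSpec:
    payload = yaml.safe_load(Path(path).read_text())
    return PopulationSpec(
        schema=tuple(VariableSchema.from_dict(d) for d in payload["variables"]),
        latent_correlation=np.asarray(payload["latent_correlation"], dtype=float),
        n=int(payload["n"]),
        seed=int(payload["seed"]),
    )
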