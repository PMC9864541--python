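"""Gaussian-copula generator for survey-like mixed-type populations.

The study design needs a complete "full sample" with known structure: a block
of fully observed demographic covariates and a handful of mixed-type outcome
variables (binary, continuous, right-skewed semicontinuous) that are
correlated with the covariates strongly enough for covariate-driven (MAR)
missingness to be recoverable by imputation.

The generator draws a latent multivariate-normal vector with a specified
correlation matrix and pushes each coordinate through a monotone link:

* continuous: ``loc + scale * z`` (identity) or ``loc + scale * exp(z)``
  (lognormal margin, for right-skewed variables);
* binary/nominal/ordinal: thresholds at standard-normal quantiles of the
  cumulative level prevalences;
* semicontinuous: exact zero where ``Phi(z) < zero_mass``, otherwise
  ``scale * exp(z)`` — a point mass at zero with a skewed positive part,
  monotone in the latent coordinate.

Nominal variables are generated through the same ordered-threshold machinery;
their nominal-ness matters only to downstream encoders.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .schema import MixedDataset, PopulationSpec, SchemaError, VariableSchema

import pandas as pd


def generate_population(spec: PopulationSpec) -> MixedDataset:
    """Draw a complete n-row population from a :class:`PopulationSpec`.

    Deterministic given ``spec.seed``; the output has an all-observed mask.
    """
    rng = np.random.default_rng(spec.seed)
    p = len(spec.schema)
    L = np.linalg.cholesky(spec.latent_correlation)
    Z = rng.standard_normal((spec.n, p)) @ L.T

    columns = {}
    for j, v in enumerate(spec.schema):
        z = Z[:, j]
        if v.is_categorical:
            probs = v.level_probs
            if probs is None:
                probs = tuple(1.0 / len(v.levels) for _ in v.levels)
            thresholds = stats.norm.ppf(np.cumsum(probs)[:-1])
            idx = np.searchsorted(thresholds, z, side="right")
            columns[v.name] = np.asarray(v.levels, dtype=object)[idx]
        elif v.vtype == "semicontinuous":
            cut = stats.norm.ppf(v.zero_mass)
            x = np.where(z < cut, 0.0, v.scale * np.exp(z))
            columns[v.name] = x
        else:  # continuous
            f = np.exp(z) if v.transform == "exp" else z
            columns[v.name] = v.loc + v.scale * f
    df = pd.DataFrame(columns, columns=[v.name for v in spec.schema])
    return MixedDataset(df, spec.schema)


def true_estimands(pop: MixedDataset, plan) -> dict[str, float]:
    """Full-sample values Q of every estimand in an analysis plan.

    The population must be fully observed; estimates are computed by the same
    estimation routines used on imputed data, so truth and estimate share
    conventions exactly.
    """
    from .estimation import estimate_all

    if not pop.is_complete:
        raise SchemaError("true_estimands requires a fully observed population")
    return estimate_all(pop.data, pop.schema, plan)


# ---------------------------------------------------------------------------
# Packaged fixtures emulating the study's two prepared survey extracts.
# ---------------------------------------------------------------------------

def _factor_correlation(loadings: np.ndarray) -> np.ndarray:
    """Correlation matrix from a factor model: R = L L' + diag(1 - rowsums)."""
    R = loadings @ loadings.T
    np.fill_diagonal(R, 1.0)
    return R


def fixture_brfss_like(seed: int, n: int = 5000) -> PopulationSpec:
    """Population spec shaped like the diabetes-module survey extract.

    Six outcome variables — one age-like continuous, two right-skewed
    semicontinuous counts (point mass at zero), three binary — plus ten mixed
    demographic covariates. Every outcome loads on a shared latent "health
    burden" factor and a socio-economic factor, so each is correlated with at
    least three covariates and MAR missingness driven by the covariates is
    informative.
    """
    schema = (
        # covariates
        VariableSchema("age_group", "covariate", "ordinal",
                       levels=("18-39", "40-54", "55-69", "70+"),
                       level_probs=(0.25, 0.30, 0.25, 0.20)),
        VariableSchema("sex", "covariate", "binary",
                       levels=("male", "female"), level_probs=(0.5, 0.5)),
        VariableSchema("race", "covariate", "nominal",
                       levels=("white", "black", "other"),
                       level_probs=(0.55, 0.25, 0.20)),
        VariableSchema("education", "covariate", "ordinal",
                       levels=("lt_hs", "hs", "some_college", "college"),
                       level_probs=(0.15, 0.30, 0.30, 0.25)),
        VariableSchema("income", "covariate", "ordinal",
                       levels=("low", "mid", "high"),
                       level_probs=(0.35, 0.40, 0.25)),
        VariableSchema("insurance", "covariate", "binary",
                       levels=("no", "yes"), level_probs=(0.15, 0.85)),
        VariableSchema("bmi", "covariate", "continuous", loc=29.0, scale=6.0),
        VariableSchema("exercise", "covariate", "binary",
                       levels=("no", "yes"), level_probs=(0.4, 0.6)),
        VariableSchema("smoker", "covariate", "binary",
                       levels=("no", "yes"), level_probs=(0.6, 0.4)),
        VariableSchema("general_health", "covariate", "ordinal",
                       levels=("poor", "fair", "good"),
                       level_probs=(0.25, 0.40, 0.35)),
        # outcomes
        VariableSchema("age_diagnosed", "outcome", "continuous", loc=50.0, scale=12.0),
        VariableSchema("feet_checks", "outcome", "semicontinuous",
                       zero_mass=0.30, scale=1.5),
        VariableSchema("a1c_checks", "outcome", "semicontinuous",
                       zero_mass=0.35, scale=1.2),
        VariableSchema("insulin_use", "outcome", "binary",
                       levels=("no", "yes"), level_probs=(0.60, 0.40)),
        VariableSchema("eye_affected", "outcome", "binary",
                       levels=("no", "yes"), level_probs=(0.65, 0.35)),
        VariableSchema("diabetes_class", "outcome", "binary",
                       levels=("no", "yes"), level_probs=(0.50, 0.50)),
    )
    # loadings on (health burden, socio-economic) factors
    loadings = np.array([
        [0.45, -0.10],   # age_group
        [0.10,  0.00],   # sex
        [0.10, -0.25],   # race
        [-0.10, 0.60],   # education
        [-0.15, 0.65],   # income
        [0.00,  0.45],   # insurance
        [0.50, -0.10],   # bmi
        [-0.40, 0.20],   # exercise
        [0.30, -0.30],   # smoker
        [-0.55, 0.25],   # general_health (higher = better)
        [0.55, -0.15],   # age_diagnosed
        [0.60, -0.20],   # feet_checks
        [0.60, -0.15],   # a1c_checks
        [0.60, -0.20],   # insulin_use
        [0.60, -0.15],   # eye_affected
        [0.55, -0.20],   # diabetes_class
    ])
    return PopulationSpec(schema, _factor_correlation(loadings), n=n, seed=seed)


def fixture_nhanes_like(seed: int, n: int = 5000) -> PopulationSpec:
    """Population spec shaped like the cardiovascular-module survey extract.

    Five outcome variables — four binary and one right-skewed continuous
    inflammation marker (HsCRP-like, lognormal margin) — plus ten mixed
    covariates, wired to the same two-factor latent structure.
    """
    schema = (
        VariableSchema("sex", "covariate", "binary",
                       levels=("male", "female"), level_probs=(0.5, 0.5)),
        VariableSchema("age", "covariate", "continuous", loc=48.0, scale=17.0),
        VariableSchema("race", "covariate", "nominal",
                       levels=("white", "black", "other"),
                       level_probs=(0.50, 0.25, 0.25)),
        VariableSchema("education", "covariate", "ordinal",
                       levels=("lt_hs", "hs", "college"),
                       level_probs=(0.20, 0.45, 0.35)),
        VariableSchema("income", "covariate", "ordinal",
                       levels=("low", "mid", "high"),
                       level_probs=(0.35, 0.40, 0.25)),
        VariableSchema("insurance", "covariate", "binary",
                       levels=("no", "yes"), level_probs=(0.18, 0.82)),
        VariableSchema("healthcare_access", "covariate", "binary",
                       levels=("no", "yes"), level_probs=(0.25, 0.75)),
        VariableSchema("general_health", "covariate", "ordinal",
                       levels=("poor", "fair", "good"),
                       level_probs=(0.25, 0.40, 0.35)),
        VariableSchema("bmi", "covariate", "continuous", loc=29.5, scale=7.0),
        VariableSchema("smoker", "covariate", "binary",
                       levels=("no", "yes"), level_probs=(0.62, 0.38)),
        # outcomes
        VariableSchema("high_bp", "outcome", "binary",
                       levels=("no", "yes"), level_probs=(0.55, 0.45)),
        VariableSchema("high_chol", "outcome", "binary",
                       levels=("no", "yes"), level_probs=(0.60, 0.40)),
        VariableSchema("overweight", "outcome", "binary",
                       levels=("no", "yes"), level_probs=(0.45, 0.55)),
        VariableSchema("hscrp", "outcome", "continuous",
                       loc=0.0, scale=1.8, transform="exp"),
        VariableSchema("salt_reduction", "outcome", "binary",
                       levels=("no", "yes"), level_probs=(0.70, 0.30)),
    )
    loadings = np.array([
        [0.10,  0.00],   # sex
        [0.50, -0.10],   # age
        [0.10, -0.25],   # race
        [-0.10, 0.60],   # education
        [-0.15, 0.65],   # income
        [0.00,  0.45],   # insurance
        [0.00,  0.50],   # healthcare_access
        [-0.55, 0.25],   # general_health
        [0.50, -0.10],   # bmi
        [0.30, -0.30],   # smoker
        [0.60, -0.15],   # high_bp
        [0.55, -0.15],   # high_chol
        [0.55, -0.10],   # overweight
        [0.60, -0.20],   # hscrp
        [0.45,  0.20],   # salt_reduction
    ])
    return PopulationSpec(schema, _factor_correlation(loadings), n=n, seed=seed)
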