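# Methods

`imputebench` is a simulation framework for comparing multivariate
missing-data imputation methods on survey-like mixed-type data. This note
documents the statistical models it implements, the defaults and their
rationale, the numerical choices, and what the synthetic study conditions do
and do not show about real data.

## Study design

The framework reproduces a standard amputation-based Monte-Carlo design. A
complete "full sample" with a block of fully observed demographic covariates
and several mixed-type outcome variables is treated as the population of
interest; its estimates are the truth Q. Each replicate (1) imposes
missingness on the outcome variables through a known selection model,
(2) imputes with each method under comparison, (3) recomputes the estimands,
and after R replicates summarizes each method × estimand by

- bias `B = E(Q̄) − Q`, where `Q̄` is a replicate estimate and the expectation
  is the mean over replicates;
- `SE` = the standard deviation of the replicate estimates (ddof = 1);
- `RMSE = √(B² + SE²)`;
- relative forms `RB = 100·|B|/|Q|`, `RSE = 100·SE/|Q|`,
  `RRMSE = 100·RMSE/|Q|`, in percent. The absolute value in the numerator and
  denominator makes relative measures nonnegative regardless of the signs of
  B and Q. When Q = 0 the relative measures are undefined and reported blank.

Replicates whose estimate is undefined (for example a logistic fit on a
single-class complete-case subset) are excluded from the moments, with the
effective replicate count reported. Reports round to 4 decimals; unrounded
values are retained internally. Both the amputation draw and the imputation
randomness are refreshed every replicate, so the SE reflects both sources of
variability.

## Synthetic populations (Gaussian copula)

Real survey extracts are replaced by a Gaussian-copula generator: a latent
multivariate-normal vector with a specified correlation matrix is pushed
coordinate-wise through monotone links —

- continuous: `loc + scale·z`, or `loc + scale·exp(z)` for right-skewed
  (lognormal-margin) variables;
- binary/nominal/ordinal: thresholds at standard-normal quantiles of the
  cumulative level prevalences (nominal variables are generated through the
  same ordered machinery; their unordered nature matters only to encoders);
- semicontinuous: exact zero where `Φ(z) < zero_mass`, else `scale·exp(z)` —
  a point mass at zero with a skewed positive part, monotone in z.

Two packaged fixtures mirror the shape of the study's prepared survey
extracts: a diabetes-module-like population (10 covariates; 6 outcomes — one
age-like continuous, two skewed semicontinuous counts with zero masses 0.30
and 0.35, three binary with prevalences 0.40/0.35/0.50) and a
cardiovascular-module-like population (10 covariates; 4 binary outcomes plus
one lognormal inflammation marker). Latent correlations come from a
two-factor loading model ("health burden" and socio-economic factors), which
guarantees positive definiteness and gives every outcome absolute latent
correlation above 0.1 with at least three covariates, so covariate-driven
missingness is informative and recoverable. Every categorical outcome level
has population prevalence at least 0.20, the screening rule used when
selecting variables eligible for amputation; the schema validator enforces
it.

The default per-replicate sample size is n = 5000. The source surveys are
far larger, but the prepared analytic samples are not documented, and
n = 5000 gives per-cell donor pools and regression stability comparable to a
prepared survey module at desk scale. Tests and examples state the n they
use explicitly.

What the generator does *not* emulate: survey design weights and clustering,
skip patterns and structural missingness, measurement error, nominal
variables with outcome roles, and real nonlinear/interaction structure.
Passing tests therefore show that each method is implemented correctly and
behaves as theory predicts under a Gaussian dependence structure — not that
the same rankings would hold on an arbitrary real dataset.

## Amputation (logistic selection)

Missingness for each outcome is drawn cell-wise as Bernoulli(P) with

    P_i = expit(φ0 + φ1 x_i1 + … + φn x_in),

where the x_j are dummy-coded categorical and standardized continuous
covariates. Slopes are ±1 exactly; the packaged configs set each slope to
the sign of the design column's marginal association with the outcome, which
makes the missingness informative (the direction the slopes take is otherwise
arbitrary). Under MNAR the standardized outcome itself enters as the last
term with coefficient φ_self = 0.1 (small) or 3 (large); φ_self = 0 is MAR.
Binary outcomes enter their own selection model through their standardized
0/1 coding, the same treatment given to every other design column.

φ0 is calibrated per realized sample by bracketed root finding so that
mean(P) equals the target rate (default 0.40) to within 1e−8; mean(P) is
strictly increasing in φ0 and spans (0, 1), so the root is unique. The
calibration is exact-mean rather than a fixed population constant, which
stabilizes realized rates across replicates. Covariates are never amputed.
A target rate of 0 is allowed and leaves the data untouched.

## Chained-equations imputation (FCS)

Each incomplete variable gets a conditional model given all other variables,
including the current working values of the other incomplete variables.
Missing cells are initialized by draws from the observed marginal (avoiding
degenerate first-sweep donor pools), then the sampler sweeps the variables in
schema order. Defaults: m = 10 independent chains (one completed dataset
each), 20 sweeps per chain, and:

- continuous/semicontinuous targets: type-1 predictive mean matching with a
  donor pool of k = 5. The Bayesian linear step draws σ² from its scaled
  inverse-χ² posterior and β from N(β̂, σ²(XᵀX)⁻¹); donor distances compare
  observed-row predictions under β̂ with missing-row predictions under the
  draw. Imputed values are always observed donor values, so the support of
  the data is preserved.
- binary targets: logistic regression fit by IRLS, coefficients drawn from
  the asymptotic normal N(β̂, I(β̂)⁻¹), imputation as Bernoulli(expit(xβ*)).
  Single-class observed data imputes the constant class; separation triggers
  a ridge-stabilized refit.

Chains are initialized independently; k is reduced when fewer donors exist.

## Fractional hot-deck imputation

Rows are cross-classified into imputation cells by discretizing every
variable: observed-quantile bins (default 3) for continuous variables, a
dedicated code for semicontinuous zeros with the positive part binned above
it, and native levels for categoricals. Values at a bin edge fall in the
lower bin. Fully observed rows are donors; rows missing anything are
recipients; a recipient's cell is defined by its observed coordinates only.

When any recipient has fewer than M (default 5) eligible donors, cells are
coarsened automatically: among all single merges of two codes of one
variable — adjacent codes for ordered variables, the two smallest-frequency
codes for nominal ones — apply the merge that maximizes the minimum
eligible-donor count, breaking ties by the fraction of recipients already
satisfied and then by candidate order. Full collapse ends in one universal
cell, so termination is guaranteed; every merge is recorded in diagnostics.
This greedy max-min rule is this package's own concretization of automatic
cell collapsing; published implementations do not document their exact
order. Donor counting uses a two-stage match (radix-sorted always-observed
block, then pairwise wildcard comparison on the partially observed columns)
with a pattern-grouped fallback when cells are coarse.

Each recipient receives M distinct donors (uniform without replacement when
the cell is larger) with equal fractional weights 1/M, stored as exact
rationals so the per-recipient weights sum to 1 identically. All of a
recipient's missing variables are imputed jointly from the same donor within
each fractional record. Estimation expands recipients into their weighted
fractional records; donors and other complete rows carry weight 1; weighted
means/proportions and weighted least-squares/IRLS fits follow. Uniform
selection with equal weights is the equal-probability-sampling
specialization of weight-proportional donor assignment — no survey weights
are in play. Variance estimation within a single imputation is out of scope;
uncertainty is measured across Monte-Carlo replicates.

## Latent-Gaussian joint imputation

All variables are linked to one coordinate of a latent normal vector:
continuous by standardization (after log for `exp`-linked skewed columns),
categorical by probit thresholds fixed at standard-normal quantiles of the
observed cumulative frequencies (fixed rather than sampled: it keeps the
sampler identified and simple, and the thresholds are well determined by the
margins at these sample sizes). The joint distribution is parameterized by
sequential (triangular) regressions in schema order, which guarantees a
positive-definite implied covariance.

The sampler alternates conjugate normal-inverse-gamma draws of the
triangular coefficients with latent refreshes computed from the implied
joint precision matrix: missing cells are redrawn from their full
conditional normal, observed categorical cells from the conditional normal
truncated to their category's threshold interval (inverse-CDF draws).
Defaults: 10 burn-in iterations, m = 10 draws taken from consecutive
refreshes after burn-in. Back-transformation inverts the links; raw
semicontinuous columns imputed in one step are clamped at zero (the two-step
wrapper is the preferred treatment). Incomplete unordered categoricals are
not supported; ordinal covariates are handled through their ordered
thresholds.

## Two-part (semicontinuous) procedure

The two-step wrapper splits each semicontinuous variable into a binary
zero/positive indicator and a log-scale positive part, hands the pair to any
multiple imputer (indicator via the binary method, positive part via the
continuous method fit on observed-positive rows), and merges: an imputed
zero indicator yields an exact zero, a positive indicator attaches the
positive draw. Observed cells are restored verbatim at the merge. The
positive-part model is deliberately fit on observed-nonzero rows only —
standard two-part-model semantics, keeping zeros out of the skewed
continuous model.

## Iteration counts and m

Chain length and the number of imputed datasets are genuinely free knobs:
practitioners run chained equations anywhere from 5 to 25 sweeps and the
latent sampler from 10 to 25 rounds depending on convergence diagnostics.
Both are exposed as parameters; the defaults are 20 sweeps (chained
equations), 10 rounds (latent joint), and m = 10 completed datasets for all
multiple imputers — conservative values for data of this dimensionality,
with per-sweep traces of imputed-cell means available in the diagnostics for
convergence inspection.

## Numerical choices

- Standardization uses population (ddof = 0) moments; zero-variance design
  columns are rejected with a diagnostic.
- OLS uses a least-squares solve (`lstsq`); rank deficiency falls back to the
  minimum-norm solution with a warning. IRLS runs to gradient max-norm
  < 1e−8 with step safeguards; separation/ill-conditioning triggers a
  ridge-stabilized refit.
- Intercept calibration uses Brent root finding on an overflow-safe logistic
  sigmoid.
- All randomness flows from integer seeds through `numpy` `SeedSequence`
  spawning: one stream per outcome in amputation, per chain in FCS, per
  replicate and per method in the Monte-Carlo harness. Same seed, same data,
  same result, byte for byte.
- Truncated-normal draws use inverse-CDF sampling with the uniform clipped
  to [1e−12, 1−1e−12] to avoid infinite quantiles in extreme tails.

## Desk-scale settings

Monte-Carlo tests run at reduced scale chosen once for desk-size runs:
R = 200 replicates; n = 4000 for the MCAR-recovery and headline MAR
comparisons, n = 2000 with a compact 4-covariate/2-outcome population for
the MNAR dose-response check; chains shortened to m = 3–5 and 2–5 sweeps.
These settings leave the Monte-Carlo standard error of a bias estimate an
order of magnitude below the effects being tested. The full R = 1000 design
is the package default for real use.

## Known limitations

- The FCS conditional set supports binary, continuous and semicontinuous
  targets only (no polytomous/ordinal/count conditionals, no predictor-matrix
  customization beyond inclusion).
- The fractional hot-deck collapse order is a declared heuristic, not a
  reproduction of any particular package's internals; with many fine cells
  the greedy search is the slowest step of a replicate.
- MNAR driven by fully unobserved external variables is not modeled — the
  self-masking form covers missingness driven by the incomplete value
  itself.
- Estimation supports means, proportions, and linear/logistic coefficients;
  no confidence intervals or within-replicate pooled variances (a
  per-replicate diagnostic only), since the evaluation metrics use
  across-replicate spread.
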