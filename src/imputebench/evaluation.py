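"""Monte-Carlo harness and bias/RMSE metric calculator.

Repeats the ampute -> impute -> estimate pipeline R times with independent
amputation and imputation randomness, then summarizes every method x estimand
pair by the sextuple

    B      = E(Qbar) - Q        (bias, estimand units)
    SE     = sd of the replicate estimates
    RMSE   = sqrt(B^2 + SE^2)
    RB     = 100 |B| / |Q|      (percent)
    RSE    = 100 SE / |Q|
    RRMSE  = 100 RMSE / |Q|

where Q is the full-sample value and Qbar a single replicate's estimate.
Replicates with undefined estimates (e.g. separation in a logistic fit) are
excluded from the moments with the effective replicate count reported.
Reports round to 4 decimals; unrounded values are retained.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .amputation import AmputationConfig, ampute
from .estimation import (AnalysisPlan, complete_case, estimate_multiple,
                         fractional_estimate)
from .fcs import FcsParams, fcs_run, fcs_two_step
from .fhd import fhd_run
from .latent import LatentParams, latent_run, latent_two_step
from .schema import MixedDataset
from .synthetic import true_estimands

METHODS = ("complete_case", "fcs", "fcs_two_step", "fhd", "latent", "latent_two_step")

METRIC_COLUMNS = ["B", "RB", "SE", "RSE", "RMSE", "RRMSE"]


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class EstimateSummary:
    mechanism: str
    estimand: str
    method: str
    Q: float
    B: float
    RB: float
    SE: float
    RSE: float
    RMSE: float
    RRMSE: float
    R_effective: int


def rmse_from_bias_se(B: float, SE: float) -> float:
    """RMSE = sqrt(B^2 + SE^2) — the accuracy/precision compromise."""
    return float(np.sqrt(B * B + SE * SE))


def _apply_method(
    method: str,
    amputed: MixedDataset,
    plan: AnalysisPlan,
    seed: int,
    params: Mapping | None,
) -> dict[str, float]:
    params = dict(params or {})
    if method == "complete_case":
        return {eid: pe.value for eid, pe in complete_case(amputed, plan).items()}
    if method in ("fcs", "fcs_two_step"):
        runner = fcs_run if method == "fcs" else fcs_two_step
        res = runner(amputed, seed=seed, params=FcsParams(**params))
        return estimate_multiple(res, plan)
    if method in ("latent", "latent_two_step"):
        runner = latent_run if method == "latent" else latent_two_step
        res = runner(amputed, seed=seed, params=LatentParams(**params))
        return estimate_multiple(res, plan)
    if method == "fhd":
        res = fhd_run(amputed, seed=seed, **params)
        return fractional_estimate(res, plan)
    raise EvaluationError(f"unknown method {method!r}; choose from {METHODS}")


def run_replicate(
    full_data: MixedDataset,
    configs: Sequence[AmputationConfig],
    mechanism: str,
    methods: Sequence[str],
    plan: AnalysisPlan,
    seed: int,
    method_params: Mapping[str, Mapping] | None = None,
) -> dict[str, dict[str, float]]:
    """One amputation draw, every method applied to the same amputed data.

    A method failure yields NaN estimates for that method; the replicate is
    retained. Per-method seeds are derived from ``seed`` for replay.
    """
    for m in methods:
        if m not in METHODS:
            raise EvaluationError(f"unknown method {m!r}; choose from {METHODS}")
    method_params = method_params or {}
    children = np.random.SeedSequence(seed).spawn(1 + len(methods))
    amp_seed = int(children[0].generate_state(1)[0] % 2**31)
    amputed, _ = ampute(full_data, configs, mechanism, seed=amp_seed)
    out: dict[str, dict[str, float]] = {}
    for method, child in zip(methods, children[1:]):
        m_seed = int(child.generate_state(1)[0] % 2**31)
        try:
            out[method] = _apply_method(
                method, amputed, plan, m_seed, method_params.get(method)
            )
        except EvaluationError:
            raise
        except Exception:
            out[method] = {eid: np.nan for eid in plan.ids}
    return out


def summarize(
    truth: Mapping[str, float],
    estimates: pd.DataFrame,
    mechanism: str,
) -> list[EstimateSummary]:
    """Metric sextuple per method x estimand from a tidy estimates frame
    (columns: estimand, method, replicate, value)."""
    summaries = []
    for (method, eid), grp in estimates.groupby(["method", "estimand"], sort=True):
        Q = float(truth[eid])
        vals = grp["value"].to_numpy(dtype=float)
        defined = vals[~np.isnan(vals)]
        if len(defined) == 0:
            raise EvaluationError(f"{method}/{eid}: no defined replicate estimates")
        B = float(defined.mean() - Q)
        SE = float(defined.std(ddof=1)) if len(defined) > 1 else 0.0
        RMSE = rmse_from_bias_se(B, SE)
        if Q == 0.0:
            RB = RSE = RRMSE = np.nan
        else:
            RB = 100.0 * abs(B) / abs(Q)
            RSE = 100.0 * SE / abs(Q)
            RRMSE = 100.0 * RMSE / abs(Q)
        summaries.append(EstimateSummary(
            mechanism=mechanism, estimand=eid, method=method, Q=Q,
            B=B, RB=RB, SE=SE, RSE=RSE, RMSE=RMSE, RRMSE=RRMSE,
            R_effective=len(defined),
        ))
    return summaries


def monte_carlo(
    full_data: MixedDataset,
    configs: Sequence[AmputationConfig],
    mechanism: str,
    methods: Sequence[str],
    plan: AnalysisPlan,
    R: int,
    seed: int,
    method_params: Mapping[str, Mapping] | None = None,
) -> tuple[list[EstimateSummary], pd.DataFrame]:
    """R independent replicates of ampute -> impute -> estimate.

    Returns the metric summaries and the tidy per-replicate estimates
    (columns: estimand, method, replicate, value).
    """
    if R < 2:
        raise EvaluationError("R must be >= 2 to estimate a standard error")
    truth = true_estimands(full_data, plan)
    rep_seeds = [int(c.generate_state(1)[0] % 2**31)
                 for c in np.random.SeedSequence(seed).spawn(R)]
    records = []
    for r, rep_seed in enumerate(rep_seeds):
        per_method = run_replicate(full_data, configs, mechanism, methods, plan,
                                   rep_seed, method_params)
        for method, ests in per_method.items():
            for eid, value in ests.items():
                records.append((eid, method, r, value))
    estimates = pd.DataFrame(records,
                             columns=["estimand", "method", "replicate", "value"])
    return summarize(truth, estimates, mechanism), estimates


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def report_frame(summaries: Sequence[EstimateSummary]) -> pd.DataFrame:
    """Tidy report table, metrics rounded to 4 decimals."""
    rows = []
    for s in summaries:
        rows.append({
            "mechanism": s.mechanism, "estimand": s.estimand, "method": s.method,
            **{c: round(getattr(s, c), 4) for c in METRIC_COLUMNS},
            "R_effective": s.R_effective,
        })
    return pd.DataFrame(rows, columns=["mechanism", "estimand", "method",
                                       *METRIC_COLUMNS, "R_effective"])


def report_text(summaries: Sequence[EstimateSummary]) -> str:
    """Aligned-text rendering: one block per (estimand, mechanism), one row
    per method, columns B, RB (%), SE, RSE (%), RMSE, RRMSE (%)."""
    df = report_frame(summaries)
    buf = io.StringIO()
    header = (f"{'Imputation Method':<18}" +
              "".join(f"{c:>10}" for c in
                      ["B", "RB (%)", "SE", "RSE (%)", "RMSE", "RRMSE (%)"]))
    if df.empty:
        buf.write(header + "\n")
        return buf.getvalue()
    for (estimand, mechanism), grp in df.groupby(["estimand", "mechanism"], sort=True):
        buf.write(f"Estimand: {estimand}   Missing Mechanism: {mechanism}\n")
        buf.write(header + "\n")
        for _, row in grp.iterrows():
            cells = "".join(
                f"{row[c]:>10.4f}" if np.isfinite(row[c]) else f"{'':>10}"
                for c in METRIC_COLUMNS
            )
            buf.write(f"{row['method']:<18}" + cells + "\n")
        buf.write("\n")
    return buf.getvalue()


def write_report(
    summaries: Sequence[EstimateSummary], csv_path, text_path=None
) -> None:
    report_frame(summaries).to_csv(csv_path, index=False)
    if text_path is not None:
        from pathlib import Path
        Path(text_path).write_text(report_text(summaries))
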