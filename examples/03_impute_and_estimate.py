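"""Impute one amputed dataset with every method and compare estimates.

Applies complete-case analysis, chained-equations multiple imputation (with
and without the two-part semicontinuous procedure), fractional hot-deck, and
the latent-Gaussian joint model to the same MAR-amputed dataset, then prints
each method's estimate of two descriptive estimands next to the full-sample
truth Q.
"""

from imputebench import (AnalysisPlan, DescriptiveEstimand, FcsParams,
                         LatentParams, ampute, build_amputation_configs,
                         complete_case, estimate_multiple, fcs_run,
                         fcs_two_step, fixture_brfss_like, fractional_estimate,
                         generate_population, latent_run, true_estimands)
from imputebench.fhd import fhd_run

pop = generate_population(fixture_brfss_like(seed=1, n=4000))
plan = AnalysisPlan((
    DescriptiveEstimand("age_diagnosed"),
    DescriptiveEstimand("feet_checks"),
))
truth = true_estimands(pop, plan)

configs = build_amputation_configs(pop, "MAR")
amputed, _ = ampute(pop, configs, "MAR", seed=7)

fcs_params = FcsParams(m=5, iterations=5)
lat_params = LatentParams(iterations=10, m=5)
estimates = {
    "complete_case": {k: pe.value for k, pe in complete_case(amputed, plan).items()},
    "fcs (pmm)": estimate_multiple(fcs_run(amputed, seed=21, params=fcs_params), plan),
    "fcs 2-step": estimate_multiple(fcs_two_step(amputed, seed=21, params=fcs_params), plan),
    "fhd (M=5)": fractional_estimate(fhd_run(amputed, seed=22), plan),
    "latent joint": estimate_multiple(latent_run(amputed, seed=23, params=lat_params), plan),
}

for eid in plan.ids:
    print(f"estimand {eid}:  full-sample Q = {truth[eid]:.4f}")
    for method, est in estimates.items():
        err = est[eid] - truth[eid]
        print(f"  {method:<14} estimate = {est[eid]:8.4f}   error = {err:+.4f}")
    print()
print("Under MAR the model-based imputers should sit closer to Q than "
      "listwise deletion; one draw is noisy — the Monte-Carlo example "
      "averages this over replicates.")
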