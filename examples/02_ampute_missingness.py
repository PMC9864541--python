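"""Impose calibrated MAR and self-masking MNAR missingness.

For each mechanism, the logistic selection model is built from dummy-coded /
standardized covariates with +-1 slopes (plus the standardized outcome itself
under MNAR), and the intercept is calibrated so the mean selection
probability equals the 40% target. Prints the calibrated intercepts and
realized per-outcome missing rates.
"""

from imputebench import ampute, build_amputation_configs, fixture_brfss_like, generate_population

pop = generate_population(fixture_brfss_like(seed=1, n=10_000))

for mechanism in ("MAR", "MNAR_small", "MNAR_large"):
    configs = build_amputation_configs(pop, mechanism, target_rate=0.4)
    amputed, realization = ampute(pop, configs, mechanism, seed=7)
    print(f"mechanism: {mechanism}")
    for name in pop.outcome_names:
        print(f"  {name:<15} phi0 = {realization.phi0[name]:+.3f}   "
              f"realized missing rate = {realization.realized_rate[name]:.3f}")
    print()
print("Realized rates should all be within binomial sampling error "
      "(~0.005 at n=10000) of the 0.40 target; covariates stay complete.")
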