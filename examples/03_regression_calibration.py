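"""Regression calibration: model-based stage-1 summaries fix attenuation.

Fits the Bayesian location-scale mixed model, shows the shrinkage of the
subject-level variability estimates, and compares the resulting Cox
coefficient with the naive one. Short chains are used so the example runs
in seconds; production fits use the full protocol.
"""
from varisurv import (MCMCConfig, PopulationParams, VisitSchedule,
                      calibrate_baseline_rate, fit_naive, fit_rc,
                      panel_summaries, simulate_dataset)

params = PopulationParams(gamma3=0.5)
params = params.with_(baseline_hazard=calibrate_baseline_rate(params, rng=1))
ds = simulate_dataset(params, VisitSchedule(1.0, 0.5), 400, rng=13)

cfg = MCMCConfig(n_chains=2, n_burn=600, n_keep=600, seed=0)
rc = fit_rc(ds, mcmc_config=cfg, return_posterior=True)
naive = fit_naive(ds)
post = rc.flags["_posterior"]

print(f"true gamma3 = 0.5")
print(f"naive: gamma3 = {naive.gamma3:+.3f} (se {naive.se['gamma3']:.3f})")
print(f"   rc: gamma3 = {rc.gamma3:+.3f} (se {rc.se['gamma3']:.3f}), "
      f"max R-hat {rc.flags['max_rhat']:.2f}")

ols = panel_summaries(ds.panel).merge(post.subject_effects, on="subject_id")
print(f"\nSD of subject-level log-variance estimates: "
      f"OLS {ols['log_var'].std():.3f} vs posterior mean "
      f"{ols['log_var_mean'].std():.3f}")
print("The posterior means are shrunken toward the population (smaller "
      "SD): borrowing strength across subjects is what removes the "
      "attenuation that the naive plug-in suffers.")
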