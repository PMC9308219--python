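"""A miniature bias study: how series length drives two-stage bias.

Runs the sample-based estimators over two scenarios that differ only in
lead-in time (3 vs 7 measurements before baseline), 30 replicates each,
and prints the mean fitted gamma3 against the truth.
"""
from varisurv import experiment_1_grid, run_scenario, summarize_experiment

grid = experiment_1_grid()
# scenario 2: semi-annual, 1-yr lead-in, gamma3 = 0.5
# scenario 6: semi-annual, 3-yr lead-in, gamma3 = 0.5
results = [run_scenario(grid[i], ["naive", "lma", "tdcox"],
                        n_replicates=30, n_subjects=500, base_seed=0)
           for i in (1, 5)]
summary = summarize_experiment(results)
cols = ["scenario_id", "label", "method", "mean_gamma3", "sd_gamma3", "bias"]
print(summary[cols].round(3).to_string(index=False))
print("\nTruth is gamma3 = 0.5 in both scenarios. With only 3 pre-baseline "
      "measurements every sample-based method is strongly attenuated (the "
      "naive one even changes sign); with 7 the bias shrinks but does not "
      "vanish. Regression calibration or the joint model (examples 03/04) "
      "close the remaining gap.")
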