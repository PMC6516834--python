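"""Run the complete simulated experiment end to end.

Simulates calibration molecules, negative controls, free and
microtubule-bound switching populations, and residence times; then
calibrates, corrects, thresholds, and reports every headline quantity.
Outputs (results.json, CSV curves, a log) are written to ./pipeline_out.
"""

from ndcfret import RunConfig, run_pipeline

config = RunConfig(seed=1)
results = run_pipeline(config, out_dir="pipeline_out")

print(f"config hash {results['config_hash']} (seed {results['seed']})\n")
print(f"S = {results['S']:.3f} +- {results['S_sd']:.3f} (N = {results['n_S']})")
print(f"X = {results['X']:.3f} +- {results['X_sd']:.3f} (N = {results['n_X']})")
print(f"threshold = {results['threshold']:.3f}")
print(f"high-FRET fraction: free = {results['high_fret_fraction_free']:.3f}, "
      f"bound = {results['high_fret_fraction_bound']:.3f}")
print(f"k_closing = {results['k_closing']:.3f} 1/s, "
      f"k_opening = {results['k_opening']:.3f} 1/s")
print(f"Keq_free = {results['keq_free']:.1f}, Keq_bound = {results['keq_bound']:.1f}")
print(f"Kd_closed/Kd_open = {results['kd_ratio']:.1f} "
      f"(~{results['kd_fold_change']}-fold)")
print(f"mean residence = {results['mean_residence_s']:.2f} "
      f"+- {results['mean_residence_se_s']:.2f} s (n = {results['n_dwells']})")
print("\nEvery number is recomputed from the seeded simulation; rerunning with")
print("the same seed reproduces the results byte for byte.")
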