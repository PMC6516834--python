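"""Threshold definition and two-state switching rates from noisy traces.

A Gaussian fit to the no-FRET peak of negative-control molecules sets
the working threshold at mu + 2 sigma (~0.30).  Pooled threshold
crossings over 200 short (2.5 s) molecule records then estimate the
closing (low->high) and opening (high->low) rates; the expected number
of noise-induced crossings, measured on the same negative controls, is
subtracted.
"""

from ndcfret import RunConfig, run_pipeline

config = RunConfig(seed=1, n_molecules=200, fret_frames=25)
res = run_pipeline(config)

print(f"no-FRET peak: mu = {res['no_fret_mu']:.3f}, sigma = {res['no_fret_sigma']:.3f}")
print(f"threshold (mu + 2 sigma) = {res['threshold']:.3f}")
print(f"\nraw rates:       k_closing = {res['k_closing_raw']:.3f} 1/s, "
      f"k_opening = {res['k_opening_raw']:.3f} 1/s")
print(f"noise-corrected: k_closing = {res['k_closing']:.3f} +- {res['k_closing_se']:.3f} 1/s, "
      f"k_opening = {res['k_opening']:.3f} +- {res['k_opening_se']:.3f} 1/s")
print(f"({res['n_up']} upward, {res['n_down']} downward crossings)")
print(f"\nhigh-FRET fraction = {res['high_fret_fraction_free']:.3f} "
      f"+- {res['high_fret_fraction_free_sem']:.3f} (SEM over days)")
print("\nThe traces were generated at k_closing = 0.23 and k_opening = 0.96 1/s;")
print("opening is about fourfold faster than closing, so the tightly bent")
print("state is occupied only ~20% of the time.")
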