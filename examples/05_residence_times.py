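"""Residence-time survival analysis with bootstrap errors.

Two populations of exponential microtubule residence times are compared:
a full-length complex (mean 2.9 s) and a truncated construct lacking
the auto-inhibitory end (mean 5.6 s).  The survival curve, mean, and a
Welch t test quantify the difference.
"""

import numpy as np

from ndcfret import simulate_dwell_times
from ndcfret.residence import (
    bootstrap_se,
    compare_residence,
    mean_residence,
    survival_curve,
)

full_length = simulate_dwell_times(2.9, 537, movie_length=100.0, seed=0)
truncated = simulate_dwell_times(5.6, 315, movie_length=100.0, seed=1)

for name, dwells in (("full-length", full_length), ("truncated", truncated)):
    mean = mean_residence(dwells)
    se = bootstrap_se(dwells, B=1000, seed=2)
    curve = survival_curve(dwells)
    print(f"{name:12s}: mean residence = {mean:.2f} +- {se:.2f} s "
          f"(bootstrap SE, n = {len(dwells)}), S(2 s) = {curve(2.0):.2f}")

p = compare_residence(full_length, truncated)
print(f"\nWelch two-tailed t test: p = {p:.2e}")
print("The truncated construct resides about twice as long, and the tiny")
print("p-value shows the difference far exceeds sampling noise.")
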