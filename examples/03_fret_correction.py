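"""Correct one molecule's acceptor record and compute FRET efficiency.

The raw 700 nm record during donor excitation mixes sensitized (FRET)
emission with donor spillover and direct acceptor cross-excitation.
The correction I_A(t) = I_A*(t) - S*I561_600 - X*I641_700 removes the
two contaminations using scalar reference levels measured in the
donor-alone and direct-excitation intervals of the same molecule.
"""

import numpy as np

from ndcfret import (
    CalibrationConstants,
    KineticsConfig,
    PhotophysicsConfig,
    default_schedule,
    simulate_state_path,
    simulate_trace,
)
from ndcfret.fret import build_fret_series

photo = PhotophysicsConfig()
schedule = default_schedule()
kin = KineticsConfig(0.23, 0.96)
constants = CalibrationConstants(S=0.13, S_sd=0.01, n_S=63, X=0.37, X_sd=0.07, n_X=46)

path = simulate_state_path(kin, schedule.duration, schedule.frame_rate, seed=3)
trace = simulate_trace(path, photo, schedule, seed=4, molecule_id="demo")

series = build_fret_series(
    trace, constants, background=photo.background_per_channel
)
print(f"donor-alone level  I561_600 = {series.donor_alone_level:6.1f} counts/frame")
print(f"direct-excitation  I641_700 = {series.direct_acceptor_level:6.1f} counts/frame")
print(f"acceptor verified by single-step bleach: {series.acceptor_ok} "
      f"({series.n_bleach_steps} step)")

state = trace.ground_truth["state_path"][: len(series.E)]
open_e = series.E[series.valid & ~state]
closed_e = series.E[series.valid & state]
print(f"\nmean E while open   = {open_e.mean():.2f}  (n = {len(open_e)} frames)")
if len(closed_e):
    print(f"mean E while closed = {closed_e.mean():.2f}  (n = {len(closed_e)} frames)")
print("\nOpen frames sit near E = 0 and tightly bent frames near the")
print("generative E_closed = 0.8, so threshold crossings at E = 0.30 track")
print("the conformational switching of this molecule.")
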