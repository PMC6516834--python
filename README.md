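# ndcfret

Simulation and analysis of three-camera single-molecule FRET (smFRET)
experiments on conformationally switching protein complexes — modeled on
TIRF measurements of the budding-yeast Ndc80 kinetochore complex, which
fluctuates between an open conformation and a tightly bent,
auto-inhibited one.

The package is aimed at single-molecule biophysicists who want a fully
seeded, ground-truth-known testbed for the standard smFRET analysis
chain: spot detection and 7×7 ROI trace extraction, crosstalk
calibration, FRET correction, threshold-crossing kinetics,
residence-time survival statistics, and the thermodynamic cycle that
links conformation to binding affinity.

## The model

A molecule switches between open and closed (tightly bent) states as a
two-state Markov process with rates k_closing (open→closed) and
k_opening (closed→open); the stationary closed occupancy is
k_closing/(k_closing + k_opening).  Under 561 nm excitation a donor
photon budget *B*_D is partitioned by the state's FRET efficiency *E*:

- donor channel (600 nm): I_D = (1 − E)·B_D
- acceptor channel (700 nm): I*_A = γ·E·B_D + S·(1 − E)·B_D + X·A

where S is donor **spillover** into the red camera, X is direct
**cross-excitation** of the acceptor (with direct-excitation brightness
A), and γ = 1 by default.  The analysis inverts this with the scalar
correction

    I_A(t) = I*_A(t) − S·I561_600 − X·I641_700,
    E(t)   = I_A(t) / (I_A(t) + I_D(t)),

using per-molecule reference levels from a four-interval laser schedule
(FRET → direct 641 nm → high-power 641 nm acceptor bleach → donor
alone).  Per-frame efficiencies above a threshold set 2σ above the
no-FRET peak of negative controls (≈ 0.30) count as tightly bent;
pooled threshold crossings give the switching rates; and the four-state
cycle open/closed × bound/free obeys microscopic reversibility,

    Kd_closed = Kd_open · Keq_bound / Keq_free,  Keq = (1 − f)/f,

so the measured high-FRET fractions of free and microtubule-bound
complexes yield the affinity penalty of the bent conformation.

## Worked example

```bash
python examples/08_full_pipeline.py
```

prints (seed 1):

```
S = 0.132 +- 0.025 (N = 63)
X = 0.371 +- 0.034 (N = 46)
threshold = 0.300
high-FRET fraction: free = 0.215, bound = 0.036
k_closing = 0.187 1/s, k_opening = 1.006 1/s
Keq_free = 3.7, Keq_bound = 27.1
Kd_closed/Kd_open = 7.4 (~7-fold)
mean residence = 2.93 +- 0.12 s (n = 537)
```

Reading the numbers: the crosstalk calibration recovers the generative
S = 0.13 and X = 0.37 from 63 donor-only and 46 acceptor-only
molecules; the no-FRET Gaussian fit puts the 2σ threshold at 0.30; the
free population (generated at k_closing = 0.23, k_opening = 0.96 s⁻¹,
85 molecules) spends ~21% of frames above threshold while the bound
population sits near 4%; feeding those fractions through the
equilibrium model gives a roughly five-to-seven-fold weaker microtubule
affinity for the tightly bent state (the small bound-population sample
makes this ratio the noisiest output); and 537 exponential residence
events recover their generative 2.9 s mean.  Each
`examples/0*.py` script demonstrates one capability in isolation.

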