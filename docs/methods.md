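# Methods

## Generative model

**Conformational dynamics.** Each molecule is a continuous-time
two-state Markov process (open ↔ tightly bent/"closed") sampled exactly
with exponential holding times.  Defaults: k_closing = 0.23 s⁻¹,
k_opening = 0.96 s⁻¹, initial state drawn from the stationary
distribution.  The continuous path is discretized onto camera frames by
majority occupancy within each frame; exact jump times are kept in the
ground-truth record.  Majority-occupancy discretization erases
sub-half-frame visits, which biases recovered rates downward by a few
percent at 10 frames/s for these rates — an accepted property of the
frame-based protocol rather than a defect.

**Illumination schedule.** Four contiguous laser intervals at
10 frames/s: (i) 150 frames of 561 nm (FRET measurement), (ii) 50
frames of 641 nm at matched power (direct acceptor excitation),
(iii) 100 frames of 641 nm at 4× power (acceptor photobleach),
(iv) 100 frames of 561 nm (donor alone) — a 40 s movie.  All interval
lengths and powers are configurable; short-record experiments shorten
interval (i) (the analysis-scale runs use 25 frames = 2.5 s).

**Emission.** During 561 nm illumination with per-frame efficiency E:
ch600 = (1 − E)·B_D, ch700 = γ·E·B_D + S·(1 − E)·B_D + X·p·A, with
donor budget B_D = 100 counts/frame, direct acceptor brightness A = 80
counts/frame, spillover S = 0.13, cross-excitation X = 0.37, γ = 1
(no detection-efficiency correction is applied anywhere, matching the
analysis it emulates).  During 641 nm intervals ch700 = p·A.  Each
channel adds a constant background (20 counts/frame) before noise.

**Noise.** Poisson shot noise on expected counts plus Gaussian read
noise (SD 13 counts).  These defaults were calibrated so that the
per-frame efficiency distribution of a no-FRET molecule has a fitted
Gaussian SD of ≈ 0.15, placing the μ + 2σ threshold at 0.30 — the
working point of the thresholding analysis.  Because E is a ratio whose
numerator and denominator co-fluctuate, the count-space distance from
the open state to the 0.30 threshold is ≈ 2.6σ (not 2σ), so noise
excursions above threshold occur at ≈ 0.05 s⁻¹ per below-threshold
second.

**Bleaching.** Exponential first-passage hazards, linear in laser
power: the donor hazard (0.005 s⁻¹ per unit power) accrues only during
561 nm intervals and the acceptor hazard (0.05 s⁻¹ per unit power) only
during 641 nm intervals.  After acceptor bleach the transfer efficiency
is zero; after donor bleach all donor-derived emission stops.  Acceptor
bleaching through FRET or cross-excitation during 561 nm illumination
is neglected, which keeps interval (i) pre-bleach by construction.

**States not modeled.** Camera registration error, drift, EMCCD gain,
triplet blinking, intermediate FRET states, and non-exponential dwells
are all outside the generator.  Passing tests therefore demonstrate
correctness of the analysis chain under idealized two-state photophysics,
not robustness to every artifact of real recordings.

## Analysis chain

**Background** is subtracted per channel as a slide-level constant;
negative results are retained as noise.

**Calibration.** S is the per-molecule ratio of interval means
(700 nm)/(600 nm) on donor-only molecules under 561 nm; X the ratio of
700 nm interval means under 561 vs low-power 641 nm on acceptor-only
molecules; both use only pre-bleach frames and are reported as
mean ± SD across molecules.  The ratio-of-means form (rather than the
mean of per-frame ratios) is used because it is stable at low counts.
Molecules with a non-positive denominator are excluded and logged.

**Correction and efficiency.** The default correction subtracts scalar
terms — S times the donor-alone level from interval (iv) and X times
the direct-excitation level from interval (ii) — exactly as the method
it implements prescribes.  Because the donor-alone level reflects the
unquenched donor, the scalar spillover term over-subtracts while FRET
is occurring; an opt-in *instantaneous* mode subtracts S·I_D(t)
framewise instead and inverts the generative model to machine
precision (the package's exactness oracle).  Frames with
I_A + I_D ≤ 0 are flagged invalid, excluded from histograms, and break
crossing analysis into segments; E is never clipped.

**Dye verification.** A molecule enters analysis only if its reference
levels are measurable: the donor must survive into the donor-alone
interval and the acceptor into the direct-excitation interval
(simulation uses ground-truth bleach times; a changepoint fallback
handles real traces).  Dropping unverifiable molecules matters: a
molecule whose donor died early would otherwise get a near-zero
spillover reference and a spurious +S offset on every FRET frame.
Single-acceptor verification counts downward steps in the high-power
641 nm segment by binary changepoint recursion (a step is accepted when
the level drop exceeds 3× the local noise SD, estimated from the median
absolute first difference); exactly one step ending at background
passes.

**Threshold.** The no-FRET peak of pooled negative-control efficiencies
is fit with a least-squares Gaussian on a 0.05-wide histogram
restricted to ±0.3 around the tallest bin (so a high-FRET shoulder
cannot drag the fit); threshold = μ + 2σ.  Sample mean/SD of the peak
region is the fallback if the fit fails.

**Switching rates.** The core estimator is exactly the protocol's:
pooled upward crossings divided by total time below threshold
(k_closing), and downward crossings over time above (k_opening), a
crossing being a sign change of E − threshold between consecutive valid
frames.  SEs use the Poisson counting approximation rate/√n.  An
optional 3-frame median prefilter exists but is off by default and not
used in the pipeline: measured against ground truth it erases ~7% of
genuine crossings and biases k_opening low by ~25%.

On top of the raw estimator the pipeline applies a measured false-event
correction: negative controls (static molecules recorded as full-length
movies, 154 by default) are analyzed identically, their spurious
up-crossings per below-threshold frame *pair* and spurious
above-threshold occupancy are measured, and the expected spurious
counts/time are subtracted from the molecule data.  The corrected rates
are computed as −ln(1 − p̂)/Δt with p̂ = transitions per frame *pair* —
the discrete Markov-chain rate estimator with the first-order
correction for jumps missed within a frame.  The pair basis matters for
short records because a record's last frame contributes occupancy time
but can never contribute a crossing.  Both raw (protocol-literal) and
corrected rates are reported; at the default conditions the corrected
rates recover the generative 0.23/0.96 s⁻¹ to within a few percent on
average, with ~±10% sampling scatter.

**High-FRET fraction** pools every valid 0.1 s measurement across
molecules; its error is the SEM of per-batch ("day") fractions.  When a
test compares a measured fraction of a Markov chain against its
stationary value, the tolerance uses the binomial SE of the *effective*
sample size n/κ, where κ = 1 + 2Σ(1 − k/F)·exp(−(k_c+k_o)·kΔt) is the
chain's integrated autocorrelation over an F-frame record — consecutive
frames are strongly correlated at these rates, and the naive binomial
SE would understate the sampling SD about fourfold.

**Residence times.** Dwells are i.i.d. exponential; events outlasting
the movie are truncated and flagged censored.  Censored events are
excluded from means and survival curves by default (the Kaplan–Meier
product-limit variant is available and is cross-checked against
lifelines in the tests).  Survival curves use the S(t) = P(dwell ≥ t)
convention.  Errors on means come from a seeded nonparametric bootstrap
(B = 1000, SD of resampled means, computed on the sorted sample so the
result is order-invariant); two-sample comparisons use Welch's
two-tailed t test, chosen over the pooled-variance test because dwell
variances differ across conditions.

**Equilibrium model.** Keq = (1 − f)/f maps a closed-state fraction to
an opening equilibrium constant; Kd_closed/Kd_open = Keq_bound/Keq_free
is an exact identity (microscopic reversibility), and both the raw
ratio and its nearest-integer fold change are reported, since published
fold changes are typically computed from rounded Keq values.  Note that
a 6% bound fraction gives Keq_bound = 15.7, not 19 — the package
computes from its inputs and leaves such discrepancies visible.  Errors
propagate by the delta method (SE(Keq) = SE(f)/f²).

## Pipeline, determinism, and problem sizes

`RunConfig` fixes every sample size and toggle; all randomness flows
from one seed through `numpy.random.SeedSequence` spawning, so results
are byte-identical across runs.  Outputs embed the seed and a SHA-256
config hash.  Default scale mirrors the emulated experiment: 85
free-population molecules (200 for rate-recovery runs), 91 bound, 63
donor-only, 46 acceptor-only, 154 negative controls, 537 residence
events, 2.5 s FRET records at 10 fps.  At these sizes the full pipeline
runs in a few seconds and the complete test suite in well under a
minute.

## Known limitations

- Switching-rate recovery inherits ~±10% sampling scatter at the
  default 200×2.5 s scale (≈100 crossings pooled); the bound-population
  equilibrium constant is the noisiest output because only ~6% of its
  frames are above threshold.
- The scalar correction's over-subtraction during FRET deflates
  closed-state E from 0.80 to ≈ 0.78 (harmless for thresholding at
  0.30, visible in histograms).
- The exponential dwell generator reproduces published mean residence
  times but not bootstrap SEs larger than the i.i.d. expectation; real
  dwell samples appear to carry day-to-day clustering or
  non-exponential structure the generator does not model.
- Real multi-camera registration is out of scope; synthetic movies are
  generated registered, and colocalization assumes an identity mapping
  between channels.
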