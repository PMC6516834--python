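"""Threshold definition, high-FRET fraction, and switching-rate estimation.

The no-FRET peak of the negative-control efficiency histogram is fit
with a Gaussian; the working threshold is mu + 2 sigma (0.30 under the
default noise model).  Conformational switching rates come from a
two-state threshold-crossing analysis pooled over molecules:
k_closing = upward crossings / total time below threshold and
k_opening = downward crossings / total time above.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage, optimize

__all__ = [
    "ThresholdModel",
    "SwitchingEstimate",
    "SpuriousCrossingModel",
    "fit_no_fret_gaussian",
    "compute_threshold",
    "high_fret_fraction",
    "estimate_switching_rates",
    "measure_spurious_crossings",
    "correct_switching_estimate",
]


@dataclass(frozen=True)
class ThresholdModel:
    mu: float
    sigma: float

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    @property
    def threshold(self) -> float:
        return self.mu + 2.0 * self.sigma


@dataclass
class SwitchingEstimate:
    k_closing: float  # up-crossings per second of time below threshold
    k_opening: float  # down-crossings per second of time above threshold
    n_up: int
    n_down: int
    t_below: float
    t_above: float
    k_closing_se: float
    k_opening_se: float
    n_below_pairs: int = 0  # consecutive valid pairs starting below threshold
    n_above_pairs: int = 0
    frame_interval: float = 0.1

    @property
    def k_closing_defined(self) -> bool:
        return math.isfinite(self.k_closing)

    @property
    def k_opening_defined(self) -> bool:
        return math.isfinite(self.k_opening)


@dataclass(frozen=True)
class SpuriousCrossingModel:
    """False-event rates measured on negative controls (no dynamics).

    ``up_rate`` is the spurious up-crossing rate per second of
    below-threshold time; ``above_occupancy`` the spurious above-threshold
    time per second of below-threshold time.  Each noise excursion above
    the threshold contributes one spurious up- and one spurious
    down-crossing, so the same rate corrects both counts.
    """

    up_rate: float
    above_occupancy: float
    n_up: int
    q_up: float = 0.0  # spurious up-crossings per below-threshold frame pair
    pair_above_occupancy: float = 0.0  # spurious above-pairs per below-pair


def measure_spurious_crossings(
    negative_e_traces: Sequence[np.ndarray],
    threshold: float,
    frame_interval: float,
) -> SpuriousCrossingModel:
    """Spurious crossing statistics from static (no-FRET) control traces
    analyzed identically to the molecules of interest."""
    est = estimate_switching_rates(negative_e_traces, threshold, frame_interval)
    if est.t_below <= 0:
        raise ValueError("negative controls spend no time below threshold")
    return SpuriousCrossingModel(
        up_rate=est.n_up / est.t_below,
        above_occupancy=est.t_above / est.t_below,
        n_up=est.n_up,
        q_up=est.n_up / est.n_below_pairs if est.n_below_pairs else 0.0,
        pair_above_occupancy=(
            est.n_above_pairs / est.n_below_pairs if est.n_below_pairs else 0.0
        ),
    )


def correct_switching_estimate(
    est: SwitchingEstimate, spurious: SpuriousCrossingModel
) -> SwitchingEstimate:
    """Subtract the expected false-event background from a switching
    estimate: noise excursions from the below-threshold state add equal
    numbers of up- and down-crossings (and a little above-threshold time)
    at the rates measured on negative controls.  The expected spurious
    count is the controls' per-below-pair crossing probability times the
    number of below-threshold frame pairs in the data (a noise excursion
    can only start from a below-threshold frame that has a successor).

    The corrected rates use transition counts over frame-*pair* counts
    (the discrete-Markov-chain transition-rate estimator) rather than
    over frame counts, which removes the window-edge bias of short
    records: the final frame of a record contributes occupancy time but
    can never contribute a crossing."""
    if not (est.n_below_pairs and est.t_below > 0):
        return est
    exp_spurious = spurious.q_up * est.n_below_pairs
    n_up = max(est.n_up - exp_spurious, 0.0)
    n_down = max(est.n_down - exp_spurious, 0.0)
    above_pairs = max(
        est.n_above_pairs - spurious.pair_above_occupancy * est.n_below_pairs,
        est.n_above_pairs * 0.1,
    )
    frame_interval = est.frame_interval
    t_below_pairs = est.n_below_pairs * frame_interval
    t_above_pairs = above_pairs * frame_interval

    def _rate(n_events: float, n_pairs: float) -> float:
        # discrete-chain rate with the first-order correction for jumps
        # missed within a frame: k = -ln(1 - p)/dt, p = events/pairs
        if n_pairs <= 0:
            return math.nan
        p = min(n_events / n_pairs, 0.999)
        return -math.log1p(-p) / frame_interval

    k_closing = _rate(n_up, est.n_below_pairs)
    k_opening = _rate(n_down, above_pairs)
    return SwitchingEstimate(
        k_closing=k_closing,
        k_opening=k_opening,
        n_up=int(round(n_up)),
        n_down=int(round(n_down)),
        t_below=t_below_pairs,
        t_above=t_above_pairs,
        k_closing_se=k_closing / math.sqrt(n_up) if n_up > 0 else math.nan,
        k_opening_se=k_opening / math.sqrt(n_down) if n_down > 0 else math.nan,
        n_below_pairs=est.n_below_pairs,
        n_above_pairs=int(round(above_pairs)),
        frame_interval=frame_interval,
    )


def _gauss(x, amp, mu, sigma):
    return amp * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def fit_no_fret_gaussian(
    e_values: np.ndarray,
    bin_width: float = 0.05,
    hist_range: tuple[float, float] = (-0.5, 1.5),
    peak_region_half_width: float = 0.3,
) -> tuple[float, float]:
    """Least-squares Gaussian fit to the dominant (no-FRET) histogram peak.

    The fit is restricted to bins within ``peak_region_half_width`` of the
    tallest bin so a high-FRET shoulder cannot drag the fit.  On fit
    failure the sample mean/SD of the values in the peak region is
    reported instead.  All-identical input (zero width) is an error.
    """
    e_values = np.asarray(e_values, dtype=float)
    e_values = e_values[np.isfinite(e_values)]
    if len(e_values) < 100:
        raise ValueError("need at least 100 efficiency values for a stable fit")
    if np.ptp(e_values) == 0:
        raise ValueError("degenerate input: all efficiency values identical")
    edges = np.arange(hist_range[0], hist_range[1] + bin_width, bin_width)
    counts, edges = np.histogram(e_values, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    peak_center = centers[np.argmax(counts)]
    in_peak = np.abs(centers - peak_center) <= peak_region_half_width
    region_mask = np.abs(e_values - peak_center) <= peak_region_half_width
    fallback = (float(e_values[region_mask].mean()),
                float(e_values[region_mask].std()))
    try:
        popt, _ = optimize.curve_fit(
            _gauss,
            centers[in_peak],
            counts[in_peak],
            p0=(counts.max(), peak_center, max(bin_width, fallback[1])),
            maxfev=10000,
        )
        mu, sigma = float(popt[1]), abs(float(popt[2]))
        if not (np.isfinite(mu) and np.isfinite(sigma)) or sigma == 0:
            raise RuntimeError("non-finite fit")
    except (RuntimeError, ValueError):
        mu, sigma = fallback
    if sigma == 0:
        raise ValueError("fitted sigma is zero")
    return mu, sigma


def compute_threshold(mu: float, sigma: float) -> float:
    """Threshold two standard deviations above the no-FRET peak center."""
    return ThresholdModel(mu=mu, sigma=sigma).threshold


def high_fret_fraction(
    e_values: np.ndarray,
    threshold: float,
    batch_labels: np.ndarray | None = None,
) -> tuple[float, float | None]:
    """Fraction of valid per-frame efficiency values above the threshold,
    pooling every measurement across molecules.  When batch (day/slide)
    labels are given, the quoted error is the SEM across per-batch
    fractions (day-to-day variability)."""
    e_values = np.asarray(e_values, dtype=float)
    finite = np.isfinite(e_values)
    if not finite.any():
        raise ValueError("no valid efficiency values")
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    fraction = float((e_values[finite] > threshold).mean())
    sem = None
    if batch_labels is not None:
        batch_labels = np.asarray(batch_labels)[finite]
        vals = e_values[finite]
        per_batch = np.array(
            [(vals[batch_labels == b] > threshold).mean() for b in np.unique(batch_labels)]
        )
        if len(per_batch) > 1:
            sem = float(per_batch.std(ddof=1) / np.sqrt(len(per_batch)))
        else:
            sem = 0.0
    return fraction, sem


def _valid_segments(e: np.ndarray) -> list[np.ndarray]:
    """Split a trace at invalid (NaN) frames; crossings are never counted
    across a gap."""
    isvalid = np.isfinite(e)
    segments = []
    idx = np.flatnonzero(np.diff(isvalid.astype(int)) != 0) + 1
    for chunk in np.split(e, idx):
        if len(chunk) and np.isfinite(chunk[0]):
            segments.append(chunk)
    return segments


def estimate_switching_rates(
    e_traces: Sequence[np.ndarray],
    threshold: float,
    frame_interval: float,
    median_filter: bool = False,
) -> SwitchingEstimate:
    """Pooled two-state threshold-crossing rates.

    A crossing is a sign change of (E - threshold) between consecutive
    valid frames; each frame contributes ``frame_interval`` seconds to the
    state it sits in.  ``median_filter`` applies a 3-frame running median
    per contiguous valid segment before thresholding (off by default; for
    noisy traces it suppresses single-frame noise excursions across the
    threshold).  SEs use the Poisson counting approximation rate/sqrt(n).
    A state never visited leaves the corresponding rate undefined (NaN).
    """
    if frame_interval <= 0:
        raise ValueError("frame_interval must be positive")
    if not e_traces:
        raise ValueError("need at least one trace")
    n_up = n_down = 0
    f_below = f_above = 0  # frame counts
    p_below = p_above = 0  # consecutive-pair counts by first-frame state
    for e in e_traces:
        for seg in _valid_segments(np.asarray(e, dtype=float)):
            if median_filter and len(seg) >= 3:
                seg = ndimage.median_filter(seg, size=3, mode="nearest")
            above = seg > threshold
            n_up += int(np.sum(~above[:-1] & above[1:]))
            n_down += int(np.sum(above[:-1] & ~above[1:]))
            f_above += int(above.sum())
            f_below += int((~above).sum())
            p_below += int((~above[:-1]).sum())
            p_above += int(above[:-1].sum())
    t_below = f_below * frame_interval
    t_above = f_above * frame_interval
    k_closing = n_up / t_below if t_below > 0 else math.nan
    k_opening = n_down / t_above if t_above > 0 else math.nan
    k_closing_se = k_closing / math.sqrt(n_up) if n_up > 0 else math.nan
    k_opening_se = k_opening / math.sqrt(n_down) if n_down > 0 else math.nan
    return SwitchingEstimate(
        k_closing=k_closing,
        k_opening=k_opening,
        n_up=n_up,
        n_down=n_down,
        t_below=t_below,
        t_above=t_above,
        k_closing_se=k_closing_se,
        k_opening_se=k_opening_se,
        n_below_pairs=p_below,
        n_above_pairs=p_above,
        frame_interval=frame_interval,
    )
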