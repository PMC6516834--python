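"""Synthetic three-camera smFRET data with known ground truth.

This module is the generative counterpart of the analysis pipeline: it
produces per-molecule intensity traces in the 525/600/700 nm emission
channels under a multi-interval laser schedule, calibration molecules
carrying a single dye, dually-labeled control molecules, exponential
microtubule residence-time samples, and (optionally) rendered image
stacks with a ground-truth sidecar.

The conformational dynamics are a continuous-time two-state Markov
process (open <-> tightly bent/"closed"), sampled exactly with
exponential holding times and discretized onto camera frames by
majority occupancy.  The emission model partitions a fixed donor
photon budget between the donor and acceptor channels according to the
state's FRET efficiency, then adds donor spillover into the red
channel, direct acceptor cross-excitation, background, Poisson shot
noise, and Gaussian read noise.  Every stochastic entry point takes an
explicit seed (or an already-constructed ``numpy.random.Generator``).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import special

__all__ = [
    "KineticsConfig",
    "PhotophysicsConfig",
    "LaserInterval",
    "IlluminationSchedule",
    "ThreeChannelTrace",
    "DwellSample",
    "simulate_state_path",
    "simulate_trace",
    "simulate_control_trace",
    "simulate_dwell_times",
    "render_movie",
    "default_schedule",
]

CHANNELS = ("ch525", "ch600", "ch700")


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class KineticsConfig:
    """Two-state switching rates for the open <-> closed conformational change.

    ``k_closing`` is the low-to-high FRET rate (open -> tightly bent),
    ``k_opening`` the reverse, both in 1/s.  ``initial_state_prob_closed``
    is the probability that a molecule starts in the closed state; ``None``
    means draw from the stationary distribution k_closing/(k_closing+k_opening).
    """

    k_closing: float = 0.23
    k_opening: float = 0.96
    initial_state_prob_closed: float | None = None

    def __post_init__(self):
        if self.k_closing < 0 or self.k_opening < 0:
            raise ValueError("switching rates must be nonnegative")
        p = self.initial_state_prob_closed
        if p is not None and not (0.0 <= p <= 1.0):
            raise ValueError("initial_state_prob_closed must be in [0, 1]")
        if self.k_closing == 0 and self.k_opening == 0 and p is None:
            raise ValueError(
                "both rates are zero and no initial state probability given"
            )

    @property
    def stationary_prob_closed(self) -> float:
        total = self.k_closing + self.k_opening
        if total == 0:
            raise ValueError("stationary distribution undefined when both rates are 0")
        return self.k_closing / total


@dataclass(frozen=True)
class PhotophysicsConfig:
    """Emission-model parameters for one molecule class.

    ``donor_total_emission`` is the unquenched donor photon budget B_D in
    counts/frame at reference 561 nm power; ``acceptor_direct_emission``
    the acceptor counts/frame under direct 641 nm excitation at reference
    power.  ``spillover_true`` (S) and ``crossex_true`` (X) are the
    generative crosstalk ratios that the calibration module estimates.
    Bleach rates are exponential hazards in 1/s per unit ``power_scale``.
    Defaults are calibrated so that the no-FRET efficiency distribution
    has a standard deviation of about 0.15, putting the mu + 2 sigma
    threshold near 0.30.
    """

    donor_total_emission: float = 100.0
    acceptor_direct_emission: float = 80.0
    E_open: float = 0.0
    E_closed: float = 0.8
    spillover_true: float = 0.13
    crossex_true: float = 0.37
    background_per_channel: tuple[float, float, float] = (20.0, 20.0, 20.0)
    read_noise_sd: float = 13.0
    shot_noise: bool = True
    donor_bleach_rate: float = 0.005
    acceptor_bleach_rate: float = 0.05
    gamma: float = 1.0
    gfp_emission: float = 0.0

    def __post_init__(self):
        for name in (
            "donor_total_emission",
            "acceptor_direct_emission",
            "spillover_true",
            "crossex_true",
            "read_noise_sd",
            "donor_bleach_rate",
            "acceptor_bleach_rate",
            "gfp_emission",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if any(b < 0 for b in self.background_per_channel):
            raise ValueError("backgrounds must be nonnegative")
        if not (0.0 <= self.E_open < self.E_closed <= 1.0):
            raise ValueError("require 0 <= E_open < E_closed <= 1")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")


@dataclass(frozen=True)
class LaserInterval:
    laser_nm: int
    power_scale: float
    n_frames: int

    def __post_init__(self):
        if self.laser_nm not in (488, 561, 641):
            raise ValueError(f"unsupported laser wavelength {self.laser_nm}")
        if self.n_frames < 1:
            raise ValueError("each interval needs at least one frame")
        if self.power_scale <= 0:
            raise ValueError("power_scale must be positive")


@dataclass(frozen=True)
class IlluminationSchedule:
    """Ordered laser intervals; frame times are contiguous at 1/frame_rate."""

    intervals: tuple[LaserInterval, ...]
    frame_rate: float = 10.0

    def __post_init__(self):
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if not self.intervals:
            raise ValueError("schedule needs at least one interval")

    @property
    def n_frames(self) -> int:
        return sum(iv.n_frames for iv in self.intervals)

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate

    @property
    def frame_interval(self) -> float:
        return 1.0 / self.frame_rate

    def frame_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-frame (interval_id, laser_nm, power_scale)."""
        ids = np.concatenate(
            [np.full(iv.n_frames, i, dtype=int) for i, iv in enumerate(self.intervals)]
        )
        lasers = np.array([iv.laser_nm for iv in self.intervals])[ids]
        powers = np.array([iv.power_scale for iv in self.intervals])[ids]
        return ids, lasers, powers

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate


def default_schedule(
    n_fret_frames: int = 150,
    n_direct_frames: int = 50,
    n_bleach_frames: int = 100,
    n_donor_alone_frames: int = 100,
    frame_rate: float = 10.0,
    bleach_power: float = 4.0,
) -> IlluminationSchedule:
    """The four-interval sequence: (i) 561 nm FRET, (ii) 641 nm direct
    acceptor excitation, (iii) high-power 641 nm acceptor photobleach,
    (iv) 561 nm donor alone.  Defaults give a 40 s movie at 10 fps."""
    return IlluminationSchedule(
        intervals=(
            LaserInterval(561, 1.0, n_fret_frames),
            LaserInterval(641, 1.0, n_direct_frames),
            LaserInterval(641, bleach_power, n_bleach_frames),
            LaserInterval(561, 1.0, n_donor_alone_frames),
        ),
        frame_rate=frame_rate,
    )


@dataclass
class ThreeChannelTrace:
    """Per-frame intensities of one particle in the three emission channels."""

    molecule_id: str
    batch_label: str
    schedule: IlluminationSchedule
    time_s: np.ndarray
    interval_id: np.ndarray
    laser_nm: np.ndarray
    power_scale: np.ndarray
    ch525: np.ndarray
    ch600: np.ndarray
    ch700: np.ndarray
    ground_truth: dict | None = None

    def __post_init__(self):
        n = len(self.time_s)
        for name in ("interval_id", "laser_nm", "power_scale", *CHANNELS):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length does not match time axis")
        dt = np.diff(self.time_s)
        if n > 1 and not np.all(dt > 0):
            raise ValueError("frame times must be strictly increasing")
        for name in CHANNELS:
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"{name} contains non-finite counts")

    @property
    def n_frames(self) -> int:
        return len(self.time_s)

    def channel(self, name: str) -> np.ndarray:
        return getattr(self, name)

    def replace_channels(self, **channels: np.ndarray) -> "ThreeChannelTrace":
        return dataclasses.replace(self, **channels)


@dataclass
class DwellSample:
    """Microtubule residence (dwell) times with censoring flags."""

    dwell_s: np.ndarray
    censored: np.ndarray
    batch_label: np.ndarray
    movie_length: float

    def __post_init__(self):
        self.dwell_s = np.asarray(self.dwell_s, dtype=float)
        self.censored = np.asarray(self.censored, dtype=bool)
        self.batch_label = np.asarray(self.batch_label)
        if len(self.dwell_s) != len(self.censored) or len(self.dwell_s) != len(
            self.batch_label
        ):
            raise ValueError("dwell arrays must have equal length")
        if np.any(self.dwell_s <= 0):
            raise ValueError("dwell times must be positive")
        if np.any(self.dwell_s[self.censored] > self.movie_length):
            raise ValueError("censored dwells cannot exceed the movie length")

    def __len__(self) -> int:
        return len(self.dwell_s)

    @property
    def uncensored(self) -> np.ndarray:
        return self.dwell_s[~self.censored]


# ---------------------------------------------------------------------------
# state-path simulation


def sample_jump_process(
    kinetics: KineticsConfig, duration: float, seed
) -> tuple[np.ndarray, np.ndarray]:
    """Exact two-state Markov jump process on [0, duration].

    Returns (jump_times, states) where states[i] (True = closed) holds on
    [jump_times[i], jump_times[i+1]); jump_times[0] == 0.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = _rng(seed)
    p0 = kinetics.initial_state_prob_closed
    if p0 is None:
        p0 = kinetics.stationary_prob_closed
    state = bool(rng.random() < p0)
    times = [0.0]
    states = [state]
    t = 0.0
    while True:
        rate = kinetics.k_opening if state else kinetics.k_closing
        if rate == 0:
            break
        t += rng.exponential(1.0 / rate)
        if t >= duration:
            break
        state = not state
        times.append(t)
        states.append(state)
    return np.asarray(times), np.asarray(states, dtype=bool)


def _discretize_majority(
    jump_times: np.ndarray, states: np.ndarray, n_frames: int, frame_rate: float
) -> np.ndarray:
    """Frame is closed iff closed-state occupancy covers >= half the frame."""
    dt = 1.0 / frame_rate
    edges = np.arange(n_frames + 1) * dt
    # occupancy of closed state accumulated over segments
    seg_starts = jump_times
    seg_ends = np.append(jump_times[1:], n_frames * dt)
    closed_occ = np.zeros(n_frames)
    for start, end, st in zip(seg_starts, seg_ends, states):
        if not st or end <= start:
            continue
        lo = np.clip(edges[:-1], start, end)
        hi = np.clip(edges[1:], start, end)
        closed_occ += np.maximum(hi - lo, 0.0)
    return closed_occ >= dt / 2


def simulate_state_path(
    kinetics: KineticsConfig, duration: float, frame_rate: float, seed
) -> np.ndarray:
    """Per-frame boolean state sequence (True = closed/high FRET).

    The continuous-time chain is sampled exactly (exponential holding
    times) and then discretized by majority occupancy within each frame.
    """
    if frame_rate <= 0:
        raise ValueError("frame_rate must be positive")
    n_frames = int(round(duration * frame_rate))
    if n_frames < 1:
        raise ValueError("duration shorter than one frame")
    jump_times, states = sample_jump_process(kinetics, duration, seed)
    return _discretize_majority(jump_times, states, n_frames, frame_rate)


# ---------------------------------------------------------------------------
# trace simulation


def _sample_bleach_time(
    schedule: IlluminationSchedule,
    hazard_per_power: float,
    active_laser: int,
    rng: np.random.Generator,
) -> float:
    """Exponential first-passage bleach time under a piecewise-constant
    hazard = rate * power_scale, active only while ``active_laser`` is on."""
    if hazard_per_power == 0:
        return math.inf
    target = rng.exponential(1.0)
    t = 0.0
    acc = 0.0
    for iv in schedule.intervals:
        span = iv.n_frames / schedule.frame_rate
        rate = hazard_per_power * iv.power_scale if iv.laser_nm == active_laser else 0.0
        if rate > 0 and acc + rate * span >= target:
            return t + (target - acc) / rate
        acc += rate * span
        t += span
    return math.inf


def _render_channels(
    efficiency: np.ndarray,
    donor_present: bool,
    acceptor_present: bool,
    photo: PhotophysicsConfig,
    schedule: IlluminationSchedule,
    seed,
    molecule_id: str = "mol",
    batch_label: str = "batch0",
) -> ThreeChannelTrace:
    """Forward emission model shared by FRET and control molecules.

    ``efficiency`` is the per-frame transfer efficiency the molecule would
    exhibit while both dyes are alive; bleaching overrides it to 0.
    """
    n = schedule.n_frames
    if len(efficiency) != n:
        raise ValueError("state/efficiency path length must match the schedule")
    rng = _rng(seed)
    ids, lasers, powers = schedule.frame_arrays()
    times = schedule.times()

    donor_bleach = (
        _sample_bleach_time(schedule, photo.donor_bleach_rate, 561, rng)
        if donor_present
        else 0.0
    )
    acceptor_bleach = (
        _sample_bleach_time(schedule, photo.acceptor_bleach_rate, 641, rng)
        if acceptor_present
        else 0.0
    )
    donor_alive = donor_present & (times < donor_bleach)
    acceptor_alive = acceptor_present & (times < acceptor_bleach)

    eff = np.where(donor_alive & acceptor_alive, efficiency, 0.0)
    bg525, bg600, bg700 = photo.background_per_channel
    B = photo.donor_total_emission
    A = photo.acceptor_direct_emission
    S, X, g = photo.spillover_true, photo.crossex_true, photo.gamma

    exp525 = np.full(n, bg525, dtype=float)
    exp600 = np.full(n, bg600, dtype=float)
    exp700 = np.full(n, bg700, dtype=float)

    is561 = lasers == 561
    is641 = lasers == 641
    is488 = lasers == 488
    p = powers

    exp600[is561] += (p * donor_alive * (1 - eff) * B)[is561]
    exp700[is561] += (
        p * donor_alive * (g * eff + S * (1 - eff)) * B + X * p * acceptor_alive * A
    )[is561]
    exp700[is641] += (p * acceptor_alive * A)[is641]
    exp525[is488] += (p * photo.gfp_emission)[is488]

    def noisy(expected: np.ndarray) -> np.ndarray:
        out = rng.poisson(expected).astype(float) if photo.shot_noise else expected.copy()
        if photo.read_noise_sd > 0:
            out = out + rng.normal(0.0, photo.read_noise_sd, size=n)
        return out

    return ThreeChannelTrace(
        molecule_id=molecule_id,
        batch_label=batch_label,
        schedule=schedule,
        time_s=times,
        interval_id=ids,
        laser_nm=lasers,
        power_scale=p.astype(float),
        ch525=noisy(exp525),
        ch600=noisy(exp600),
        ch700=noisy(exp700),
        ground_truth={
            "efficiency": eff,
            "state_efficiency": efficiency.copy(),
            "donor_present": donor_present,
            "acceptor_present": acceptor_present,
            "donor_bleach_time": donor_bleach,
            "acceptor_bleach_time": acceptor_bleach,
            "photophysics": photo,
        },
    )


def simulate_trace(
    state_path: np.ndarray,
    photo: PhotophysicsConfig,
    schedule: IlluminationSchedule,
    seed,
    molecule_id: str = "mol",
    batch_label: str = "batch0",
) -> ThreeChannelTrace:
    """Render a dually-labeled molecule's three-channel trace.

    ``state_path`` (True = closed) must span the whole schedule; the
    conformational efficiency only matters during 561 nm illumination.
    """
    state_path = np.asarray(state_path, dtype=bool)
    if len(state_path) != schedule.n_frames:
        raise ValueError("state path length must equal the schedule's frame count")
    eff = np.where(state_path, photo.E_closed, photo.E_open)
    trace = _render_channels(
        eff, True, True, photo, schedule, seed, molecule_id, batch_label
    )
    trace.ground_truth["state_path"] = state_path
    return trace


CONTROL_KINDS = ("donor_only", "acceptor_only", "positive", "negative")


def simulate_control_trace(
    kind: str,
    photo: PhotophysicsConfig,
    schedule: IlluminationSchedule,
    seed,
    positive_e: float = 0.9,
    molecule_id: str = "ctrl",
    batch_label: str = "batch0",
) -> ThreeChannelTrace:
    """Calibration/control molecules: single-dye, or dual-dye at fixed E."""
    if kind not in CONTROL_KINDS:
        raise ValueError(f"unknown control kind {kind!r}; expected one of {CONTROL_KINDS}")
    n = schedule.n_frames
    if kind == "donor_only":
        eff, donor, acceptor = np.zeros(n), True, False
    elif kind == "acceptor_only":
        eff, donor, acceptor = np.zeros(n), False, True
    elif kind == "negative":
        eff, donor, acceptor = np.zeros(n), True, True
    else:  # positive
        eff, donor, acceptor = np.full(n, positive_e), True, True
    trace = _render_channels(
        eff, donor, acceptor, photo, schedule, seed, molecule_id, batch_label
    )
    trace.ground_truth["control_kind"] = kind
    return trace


# ---------------------------------------------------------------------------
# dwell times


def simulate_dwell_times(
    mean_tau: float,
    n: int,
    movie_length: float = math.inf,
    seed=None,
    batch_labels: Sequence[str] | None = None,
    n_batches: int = 1,
) -> DwellSample:
    """I.i.d. exponential residence times; events outlasting the movie are
    truncated at ``movie_length`` and flagged censored."""
    if mean_tau <= 0:
        raise ValueError("mean_tau must be positive")
    if n < 1:
        raise ValueError("need at least one dwell")
    rng = _rng(seed)
    dwells = rng.exponential(mean_tau, size=n)
    censored = dwells > movie_length
    dwells = np.minimum(dwells, movie_length)
    if batch_labels is None:
        batch_labels = np.array([f"day{i % n_batches}" for i in range(n)])
    return DwellSample(
        dwell_s=dwells,
        censored=censored,
        batch_label=np.asarray(batch_labels),
        movie_length=movie_length,
    )


# ---------------------------------------------------------------------------
# movie rendering


def _gaussian_spot(
    shape: tuple[int, int], x: float, y: float, mass: float, sigma: float
) -> np.ndarray:
    """Pixel-integrated symmetric 2-D Gaussian of total integral ``mass``."""
    h, w = shape
    xs = np.arange(w)
    ys = np.arange(h)
    sq = sigma * math.sqrt(2.0)
    fx = 0.5 * (special.erf((xs + 0.5 - x) / sq) - special.erf((xs - 0.5 - x) / sq))
    fy = 0.5 * (special.erf((ys + 0.5 - y) / sq) - special.erf((ys - 0.5 - y) / sq))
    return mass * np.outer(fy, fx)


def render_movie(
    traces: Sequence[ThreeChannelTrace],
    positions: Sequence[tuple[float, float]],
    fov: tuple[int, int] = (64, 64),
    psf_sigma: float = 1.0,
    seed=None,
    background: float = 0.0,
    noise: bool = False,
    margin: float = 3.0,
    n_frames: int | None = None,
) -> tuple[dict[str, np.ndarray], dict]:
    """Render traces as Gaussian spots into one stack per emission channel.

    Each particle contributes, per frame and channel, a pixel-integrated
    2-D Gaussian whose total mass equals the trace value for that frame.
    Returns ``(stacks, sidecar)`` where ``stacks`` maps channel name to a
    (T, H, W) float array and the sidecar records true positions/identities.
    """
    if len(traces) != len(positions):
        raise ValueError("one position per trace required")
    h, w = fov
    for x, y in positions:
        if not (margin <= x <= w - 1 - margin and margin <= y <= h - 1 - margin):
            raise ValueError(f"position ({x}, {y}) outside field with margin {margin}")
    if n_frames is None:
        n_frames = traces[0].n_frames if traces else 0
    for tr in traces:
        if tr.n_frames != n_frames:
            raise ValueError("all traces must share a frame count")
    rng = _rng(seed)
    stacks = {
        ch: np.full((n_frames, h, w), float(background)) for ch in CHANNELS
    }
    for tr, (x, y) in zip(traces, positions):
        for ch in CHANNELS:
            vals = tr.channel(ch)
            # render each frame's mass; spots are static in position
            spot_unit = _gaussian_spot((h, w), x, y, 1.0, psf_sigma)
            stacks[ch] += vals[:, None, None] * spot_unit[None, :, :]
    if noise:
        for ch in CHANNELS:
            stacks[ch] = rng.poisson(np.clip(stacks[ch], 0, None)).astype(float)
    sidecar = {
        "positions": [list(map(float, p)) for p in positions],
        "molecule_ids": [tr.molecule_id for tr in traces],
        "fov": list(fov),
        "psf_sigma": psf_sigma,
        "background": background,
        "n_frames": n_frames,
    }
    return stacks, sidecar
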