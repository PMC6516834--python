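"""Background subtraction, crosstalk correction, and FRET efficiency.

The acceptor record measured during donor excitation, I_A*(t), contains
three contributions: sensitized (FRET) emission, donor spillover, and
direct cross-excitation of the acceptor.  The correction

    I_A(t) = I_A*(t) - S * I561_600 - X * I641_700

removes the latter two using scalar terms: the donor-alone level
I561_600 (mean 600 nm emission after acceptor photobleaching) and the
direct-acceptor level I641_700 (mean 700 nm emission under low-power
641 nm excitation).  Efficiency is then E(t) = I_A(t) / (I_A(t) + I_D(t)).

The scalar form is the default.  Because the donor-alone level reflects
the unquenched donor, the scalar spillover term over-subtracts while
FRET is occurring; the opt-in ``instantaneous`` mode instead subtracts
S * I_D(t) framewise, which inverts the emission model exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .calibration import CalibrationConstants
from .simulate import ThreeChannelTrace, IlluminationSchedule

__all__ = [
    "FretSeries",
    "ScheduleSegments",
    "subtract_background",
    "segment_schedule",
    "correct_acceptor",
    "compute_fret",
    "bulk_fret_from_spectrum",
    "verify_single_acceptor",
    "build_fret_series",
]


@dataclass
class FretSeries:
    """Corrected donor/acceptor signals and per-frame efficiency for one
    molecule, restricted to the FRET interval before acceptor bleach."""

    molecule_id: str
    batch_label: str
    time_s: np.ndarray
    I_D: np.ndarray
    I_A: np.ndarray
    E: np.ndarray
    valid: np.ndarray
    donor_alone_level: float
    direct_acceptor_level: float
    acceptor_ok: bool | None = None
    n_bleach_steps: int | None = None

    @property
    def valid_E(self) -> np.ndarray:
        return self.E[self.valid]


@dataclass(frozen=True)
class ScheduleSegments:
    """Frame slices of the four illumination intervals."""

    fret: slice
    direct: slice
    bleach: slice
    donor_alone: slice
    fret_end_frame: int  # exclusive end of the pre-bleach FRET portion


def subtract_background(
    trace: ThreeChannelTrace, background: tuple[float, float, float]
) -> ThreeChannelTrace:
    """Constant per-channel subtraction (slide/batch-level background).
    Negative results are permitted; they are noise around zero."""
    b525, b600, b700 = background
    return trace.replace_channels(
        ch525=trace.ch525 - b525,
        ch600=trace.ch600 - b600,
        ch700=trace.ch700 - b700,
    )


def _interval_slices(schedule: IlluminationSchedule) -> list[slice]:
    out = []
    start = 0
    for iv in schedule.intervals:
        out.append(slice(start, start + iv.n_frames))
        start += iv.n_frames
    return out


def segment_schedule(
    trace: ThreeChannelTrace, schedule: IlluminationSchedule | None = None
) -> ScheduleSegments:
    """Identify the FRET, direct-excitation, bleach, and donor-alone
    intervals.  The FRET interval is the first 561 nm interval; among the
    641 nm intervals the lowest power is the direct-excitation segment and
    the highest the bleach segment; the last 561 nm interval (distinct
    from the first) measures the donor alone.  The FRET segment is cut at
    the acceptor bleach frame when the trace carries ground truth."""
    schedule = schedule or trace.schedule
    if trace.n_frames != schedule.n_frames:
        raise ValueError(
            f"trace has {trace.n_frames} frames but schedule expects "
            f"{schedule.n_frames}"
        )
    slices = _interval_slices(schedule)
    i561 = [i for i, iv in enumerate(schedule.intervals) if iv.laser_nm == 561]
    i641 = [i for i, iv in enumerate(schedule.intervals) if iv.laser_nm == 641]
    if len(i561) < 2 or not i641:
        raise ValueError("schedule must contain two 561 nm and a 641 nm interval")
    fret_i = i561[0]
    donor_alone_i = i561[-1]
    direct_i = min(i641, key=lambda i: schedule.intervals[i].power_scale)
    bleach_i = max(i641, key=lambda i: schedule.intervals[i].power_scale)

    fret_slice = slices[fret_i]
    end = fret_slice.stop
    gt = trace.ground_truth or {}
    for key in ("acceptor_bleach_time", "donor_bleach_time"):
        bleach_t = gt.get(key)
        if bleach_t is not None and np.isfinite(bleach_t):
            bleach_frame = int(np.ceil(bleach_t * schedule.frame_rate))
            end = min(end, max(fret_slice.start, bleach_frame))
    return ScheduleSegments(
        fret=fret_slice,
        direct=slices[direct_i],
        bleach=slices[bleach_i],
        donor_alone=slices[donor_alone_i],
        fret_end_frame=end,
    )


def correct_acceptor(
    i_a_star: np.ndarray,
    donor_alone_level: float | np.ndarray,
    direct_acceptor_level: float,
    constants: CalibrationConstants,
) -> np.ndarray:
    """I_A(t) = I_A*(t) - S * donor_alone - X * direct_acceptor.

    ``donor_alone_level`` may be a scalar (the default, paper-style
    correction) or a per-frame array (instantaneous donor signal)."""
    S = constants.S if constants.S is not None else 0.0
    X = constants.X if constants.X is not None else 0.0
    if not (np.all(np.isfinite(np.atleast_1d(donor_alone_level)))
            and np.isfinite(direct_acceptor_level)):
        raise ValueError("correction levels must be finite")
    return np.asarray(i_a_star, dtype=float) - S * donor_alone_level - X * direct_acceptor_level


def compute_fret(i_a: np.ndarray, i_d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame E = I_A / (I_A + I_D) and a validity mask.

    Frames with total intensity I_A + I_D <= 0 are flagged invalid (E set
    to NaN) and should be excluded from histograms and kinetics."""
    i_a = np.asarray(i_a, dtype=float)
    i_d = np.asarray(i_d, dtype=float)
    if i_a.shape != i_d.shape:
        raise ValueError("donor and acceptor series must have equal length")
    total = i_a + i_d
    valid = total > 0
    E = np.full_like(total, np.nan)
    np.divide(i_a, total, out=E, where=valid)
    return E, valid


def bulk_fret_from_spectrum(
    wavelength_nm: np.ndarray,
    intensity: np.ndarray,
    donor_peak: float = 565.0,
    acceptor_peak: float = 670.0,
    background: np.ndarray | None = None,
) -> float:
    """Ensemble FRET proxy E = I_A / (I_A + I_D) from an emission spectrum,
    evaluated at the donor and acceptor peak emission wavelengths."""
    wavelength_nm = np.asarray(wavelength_nm, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if background is not None:
        intensity = intensity - np.asarray(background, dtype=float)
    lo, hi = wavelength_nm.min(), wavelength_nm.max()
    if not (lo <= donor_peak <= hi and lo <= acceptor_peak <= hi):
        raise ValueError("peak wavelengths fall outside the measured spectrum")
    i_d = float(np.interp(donor_peak, wavelength_nm, intensity))
    i_a = float(np.interp(acceptor_peak, wavelength_nm, intensity))
    total = i_a + i_d
    if total <= 0:
        return 0.0
    return max(i_a, 0.0) / total


def _alive_mask(trace: ThreeChannelTrace, dye: str) -> np.ndarray:
    """Frames before the dye's bleach time (all True without ground truth)."""
    gt = trace.ground_truth or {}
    t = gt.get(f"{dye}_bleach_time")
    if t is None or not np.isfinite(t):
        return np.ones(trace.n_frames, dtype=bool)
    return trace.time_s < t


# ---------------------------------------------------------------------------
# photobleach step counting


def _best_split(y: np.ndarray) -> tuple[int | None, float]:
    """Best single mean-shift changepoint by least squares.

    Returns (index, |mean drop|); the split is y[:k] vs y[k:].  None when
    the series is too short to split with >= 3 frames on each side."""
    n = len(y)
    if n < 6:
        return None, 0.0
    csum = np.cumsum(y)
    total = csum[-1]
    ks = np.arange(3, n - 2)
    left_mean = csum[ks - 1] / ks
    right_mean = (total - csum[ks - 1]) / (n - ks)
    # maximizing between-segment SS is equivalent to minimizing residual SS
    score = ks * (n - ks) * (left_mean - right_mean) ** 2
    best = int(np.argmax(score))
    k = int(ks[best])
    return k, float(abs(left_mean[best] - right_mean[best]))


def _count_steps(y: np.ndarray, noise_sd: float, levels: list[float]) -> None:
    k, drop = _best_split(y)
    if k is None or drop <= 3 * noise_sd:
        levels.append(float(np.mean(y)))
        return
    _count_steps(y[:k], noise_sd, levels)
    _count_steps(y[k:], noise_sd, levels)


def verify_single_acceptor(
    direct_excitation_segment: np.ndarray, min_frames: int = 10
) -> tuple[bool, int]:
    """Count downward bleaching steps in the high-power 641 nm segment by
    binary changepoint recursion; a step is accepted when the level drop
    exceeds 3x the local noise SD.  The acceptor passes iff exactly one
    downward step lands at background (near zero for background-subtracted
    input)."""
    y = np.asarray(direct_excitation_segment, dtype=float)
    if len(y) < min_frames:
        raise ValueError(f"segment too short ({len(y)} < {min_frames} frames)")
    noise_sd = 1.4826 * float(np.median(np.abs(np.diff(y)))) / np.sqrt(2)
    if noise_sd == 0:
        noise_sd = max(float(y.std()) * 1e-6, 1e-12)
    levels: list[float] = []
    _count_steps(y, noise_sd, levels)
    diffs = np.diff(levels)
    n_down = int(np.sum(diffs < 0))
    n_up = int(np.sum(diffs > 0))
    final_at_background = bool(levels and abs(levels[-1]) < 3 * noise_sd)
    ok = n_down == 1 and n_up == 0 and final_at_background
    return ok, n_down


# ---------------------------------------------------------------------------
# per-molecule assembly


def build_fret_series(
    trace: ThreeChannelTrace,
    constants: CalibrationConstants,
    background: tuple[float, float, float] | None = None,
    instantaneous: bool = False,
    check_acceptor: bool = True,
) -> FretSeries:
    """Full per-molecule path: (optional) background subtraction, schedule
    segmentation, scalar correction levels from the direct-excitation and
    donor-alone intervals, crosstalk correction, and per-frame efficiency
    over the pre-bleach FRET interval."""
    if background is not None:
        trace = subtract_background(trace, background)
    seg = segment_schedule(trace)
    fret = slice(seg.fret.start, seg.fret_end_frame)
    if fret.stop <= fret.start:
        raise ValueError(f"{trace.molecule_id}: no pre-bleach FRET frames")
    # scalar levels come from pre-bleach frames of their intervals: the
    # donor-alone level must exclude frames after the donor itself died,
    # and the direct-acceptor level frames after the acceptor bleached
    donor_mask = _alive_mask(trace, "donor")[seg.donor_alone]
    accept_mask = _alive_mask(trace, "acceptor")[seg.direct]
    if not donor_mask.any():
        # dye verification fails: no donor left to measure the spillover
        # reference, so the molecule cannot be corrected reliably
        raise ValueError(
            f"{trace.molecule_id}: donor bleached before the donor-alone interval"
        )
    if not accept_mask.any():
        raise ValueError(
            f"{trace.molecule_id}: acceptor bleached before the direct-excitation "
            "interval"
        )
    donor_alone_level = float(trace.ch600[seg.donor_alone][donor_mask].mean())
    direct_acceptor_level = float(trace.ch700[seg.direct][accept_mask].mean())
    i_d = trace.ch600[fret]
    spill_ref = i_d if instantaneous else donor_alone_level
    i_a = correct_acceptor(
        trace.ch700[fret], spill_ref, direct_acceptor_level, constants
    )
    E, valid = compute_fret(i_a, i_d)
    acceptor_ok = n_steps = None
    if check_acceptor:
        try:
            acceptor_ok, n_steps = verify_single_acceptor(trace.ch700[seg.bleach])
        except ValueError:
            acceptor_ok, n_steps = None, None
    return FretSeries(
        molecule_id=trace.molecule_id,
        batch_label=trace.batch_label,
        time_s=trace.time_s[fret],
        I_D=np.asarray(i_d, dtype=float),
        I_A=i_a,
        E=E,
        valid=valid,
        donor_alone_level=donor_alone_level,
        direct_acceptor_level=direct_acceptor_level,
        acceptor_ok=acceptor_ok,
        n_bleach_steps=n_steps,
    )
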