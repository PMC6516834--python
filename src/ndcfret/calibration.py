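"""Crosstalk calibration from single-dye molecules.

Spillover S is the fraction of donor emission that lands on the 700 nm
camera (S = I561_700 / I561_600, measured on donor-only molecules under
561 nm excitation).  Cross-excitation X is the direct acceptor emission
produced by the donor laser relative to direct 641 nm excitation at
nominally identical power (X = I561_700 / I641_700, measured on
acceptor-only molecules).  Each molecule contributes one ratio of
interval means over its pre-bleach frames; the constants are reported as
mean +- SD across molecules.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

from .simulate import ThreeChannelTrace

__all__ = [
    "CalibrationConstants",
    "estimate_spillover",
    "estimate_cross_excitation",
    "merge_constants",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CalibrationConstants:
    S: float | None = None
    S_sd: float | None = None
    n_S: int | None = None
    X: float | None = None
    X_sd: float | None = None
    n_X: int | None = None

    def __post_init__(self):
        for name in ("S", "X"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("S_sd", "X_sd"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be nonnegative")
        for name in ("n_S", "n_X"):
            v = getattr(self, name)
            if v is not None and v < 1:
                raise ValueError(f"{name} must be at least 1")

    def to_json(self, path, **provenance) -> None:
        payload = {k: v for k, v in asdict(self).items() if v is not None}
        payload.update(provenance)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def merge_constants(
    spill: CalibrationConstants, crossex: CalibrationConstants
) -> CalibrationConstants:
    return CalibrationConstants(
        S=spill.S, S_sd=spill.S_sd, n_S=spill.n_S,
        X=crossex.X, X_sd=crossex.X_sd, n_X=crossex.n_X,
    )


def _interval_frames(trace: ThreeChannelTrace, laser_nm: int, which: str) -> np.ndarray:
    """Frame mask of the first/lowest-power interval with the given laser."""
    ids, lasers, powers = trace.interval_id, trace.laser_nm, trace.power_scale
    candidates = []
    for iv in np.unique(ids):
        mask = ids == iv
        if lasers[mask][0] == laser_nm:
            candidates.append((iv, powers[mask][0]))
    if not candidates:
        raise ValueError(f"trace has no {laser_nm} nm interval")
    if which == "first":
        iv = candidates[0][0]
    elif which == "lowest_power":
        iv = min(candidates, key=lambda c: c[1])[0]
    else:  # pragma: no cover
        raise ValueError(which)
    return ids == iv


def _prebleach_mask(trace: ThreeChannelTrace, dye: str) -> np.ndarray:
    """Frames before the dye's bleach; from ground truth when available,
    otherwise a changepoint estimate on the relevant channel."""
    gt = trace.ground_truth or {}
    key = f"{dye}_bleach_time"
    if key in gt:
        return trace.time_s < gt[key]
    # fall back: changepoint on the dye's primary channel
    from .fret import _best_split  # local import to avoid a cycle at import time

    y = trace.ch600 if dye == "donor" else trace.ch700
    mask = np.ones(trace.n_frames, dtype=bool)
    k, drop = _best_split(y)
    noise = 1.4826 * np.median(np.abs(np.diff(y))) / np.sqrt(2) if len(y) > 1 else 0.0
    if k is not None and drop > 3 * noise:
        mask[k:] = False
    return mask


def _per_molecule_ratio(
    trace: ThreeChannelTrace,
    num_channel: str,
    num_mask: np.ndarray,
    den_channel: str,
    den_mask: np.ndarray,
) -> float | None:
    num = trace.channel(num_channel)[num_mask]
    den = trace.channel(den_channel)[den_mask]
    if len(num) == 0 or len(den) == 0:
        return None
    den_mean = float(den.mean())
    if den_mean <= 0:
        return None
    return float(num.mean()) / den_mean


def estimate_spillover(
    donor_only_traces: Sequence[ThreeChannelTrace],
) -> CalibrationConstants:
    """S from donor-only molecules: per molecule, mean 700 nm emission
    divided by mean 600 nm emission over the pre-bleach portion of the
    first 561 nm interval.  Traces must be background-subtracted.
    Molecules with a nonpositive donor denominator are excluded and logged.
    """
    ratios = []
    for trace in donor_only_traces:
        mask = _interval_frames(trace, 561, "first") & _prebleach_mask(trace, "donor")
        r = _per_molecule_ratio(trace, "ch700", mask, "ch600", mask)
        if r is None:
            log.warning("excluding %s from spillover: nonpositive donor signal",
                        trace.molecule_id)
            continue
        ratios.append(r)
    if not ratios:
        raise ValueError("no usable donor-only molecules")
    arr = np.asarray(ratios)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return CalibrationConstants(S=max(float(arr.mean()), 0.0), S_sd=sd, n_S=len(arr))


def estimate_cross_excitation(
    acceptor_only_traces: Sequence[ThreeChannelTrace],
) -> CalibrationConstants:
    """X from acceptor-only molecules: per molecule, mean 700 nm emission
    under 561 nm excitation divided by mean 700 nm emission under the
    low-power 641 nm interval (pre-bleach).  Background-subtracted input.
    """
    ratios = []
    for trace in acceptor_only_traces:
        num_mask = _interval_frames(trace, 561, "first") & _prebleach_mask(
            trace, "acceptor"
        )
        den_mask = _interval_frames(trace, 641, "lowest_power") & _prebleach_mask(
            trace, "acceptor"
        )
        r = _per_molecule_ratio(trace, "ch700", num_mask, "ch700", den_mask)
        if r is None:
            log.warning("excluding %s from cross-excitation: no usable frames",
                        trace.molecule_id)
            continue
        ratios.append(r)
    if not ratios:
        raise ValueError("no usable acceptor-only molecules")
    arr = np.asarray(ratios)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return CalibrationConstants(X=max(float(arr.mean()), 0.0), X_sd=sd, n_X=len(arr))
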