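"""Plain-text trace tables and TIFF movie I/O.

Trace tables are TSV with one row per frame and columns
molecule_id, batch, frame, time_s, interval, laser_nm, power_scale,
ch525, ch600, ch700.  Floats are written at full round-trip precision
so a write/read cycle is lossless.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .simulate import (
    CHANNELS,
    IlluminationSchedule,
    LaserInterval,
    ThreeChannelTrace,
)

__all__ = [
    "SchemaError",
    "write_trace_table",
    "read_trace_table",
    "write_movie",
    "read_movie",
]

TRACE_COLUMNS = [
    "molecule_id",
    "batch",
    "frame",
    "time_s",
    "interval",
    "laser_nm",
    "power_scale",
    "ch525",
    "ch600",
    "ch700",
]


class SchemaError(ValueError):
    """A trace table violates the documented schema."""


def write_trace_table(traces: Sequence[ThreeChannelTrace], path) -> None:
    frames = []
    for tr in traces:
        frames.append(
            pd.DataFrame(
                {
                    "molecule_id": tr.molecule_id,
                    "batch": tr.batch_label,
                    "frame": np.arange(tr.n_frames),
                    "time_s": tr.time_s,
                    "interval": tr.interval_id,
                    "laser_nm": tr.laser_nm,
                    "power_scale": tr.power_scale,
                    "ch525": tr.ch525,
                    "ch600": tr.ch600,
                    "ch700": tr.ch700,
                }
            )
        )
    table = pd.concat(frames, ignore_index=True)
    # %.17g preserves float64 exactly across a write/read cycle
    table.to_csv(path, sep="\t", index=False, float_format="%.17g")


def _schedule_from_frames(
    interval: np.ndarray, laser: np.ndarray, power: np.ndarray, time_s: np.ndarray
) -> IlluminationSchedule:
    ids, starts = np.unique(interval, return_index=True)
    order = np.argsort(starts)
    intervals = []
    for iv in ids[order]:
        mask = interval == iv
        intervals.append(
            LaserInterval(
                laser_nm=int(laser[mask][0]),
                power_scale=float(power[mask][0]),
                n_frames=int(mask.sum()),
            )
        )
    if len(time_s) > 1:
        frame_rate = 1.0 / float(np.median(np.diff(time_s)))
    else:
        frame_rate = 10.0
    return IlluminationSchedule(intervals=tuple(intervals), frame_rate=frame_rate)


def read_trace_table(path) -> list[ThreeChannelTrace]:
    """Read and validate a trace table; schema violations name the
    offending column or the first bad row."""
    table = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in TRACE_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"trace table missing column(s): {', '.join(missing)}")
    traces = []
    for (mol, batch), grp in table.groupby(["molecule_id", "batch"], sort=False):
        grp = grp.sort_values("frame")
        time_s = grp["time_s"].to_numpy(dtype=float)
        if len(time_s) > 1 and not np.all(np.diff(time_s) > 0):
            bad = int(grp["frame"].iloc[int(np.argmin(np.diff(time_s)))])
            raise SchemaError(
                f"molecule {mol}: non-monotonic time at frame {bad}"
            )
        interval = grp["interval"].to_numpy(dtype=int)
        laser = grp["laser_nm"].to_numpy(dtype=int)
        power = grp["power_scale"].to_numpy(dtype=float)
        for iv in np.unique(interval):
            sub = laser[interval == iv]
            if len(np.unique(sub)) != 1:
                raise SchemaError(
                    f"molecule {mol}: interval {iv} mixes laser wavelengths"
                )
        try:
            schedule = _schedule_from_frames(interval, laser, power, time_s)
        except ValueError as exc:
            raise SchemaError(f"molecule {mol}: {exc}") from exc
        traces.append(
            ThreeChannelTrace(
                molecule_id=str(mol),
                batch_label=str(batch),
                schedule=schedule,
                time_s=time_s,
                interval_id=interval,
                laser_nm=laser,
                power_scale=power,
                ch525=grp["ch525"].to_numpy(dtype=float),
                ch600=grp["ch600"].to_numpy(dtype=float),
                ch700=grp["ch700"].to_numpy(dtype=float),
            )
        )
    return traces


def write_movie(stacks: dict[str, np.ndarray], sidecar: dict, out_dir) -> dict[str, Path]:
    """One multi-page TIFF per channel plus a ground-truth sidecar JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for ch in CHANNELS:
        if ch not in stacks:
            continue
        p = out_dir / f"movie_{ch}.tif"
        tifffile.imwrite(p, stacks[ch].astype(np.float32))
        paths[ch] = p
    sc = out_dir / "ground_truth.json"
    with open(sc, "w") as fh:
        json.dump(sidecar, fh, indent=2)
    paths["sidecar"] = sc
    return paths


def read_movie(out_dir) -> tuple[dict[str, np.ndarray], dict]:
    out_dir = Path(out_dir)
    stacks = {}
    for ch in CHANNELS:
        p = out_dir / f"movie_{ch}.tif"
        if p.exists():
            stacks[ch] = tifffile.imread(p)
    with open(out_dir / "ground_truth.json") as fh:
        sidecar = json.load(fh)
    return stacks, sidecar
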