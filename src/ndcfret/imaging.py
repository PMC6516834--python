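"""Particle detection, 7x7 ROI trace extraction, and colocalization.

Channels are assumed pre-registered (identity mapping between cameras);
synthetic movies are generated registered, and real multi-camera affine
registration is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.feature import peak_local_max

__all__ = [
    "ParticleDetection",
    "ParticleClass",
    "average_initial_frames",
    "detect_particles",
    "integrate_roi",
    "colocalize",
]


@dataclass(frozen=True)
class ParticleDetection:
    channel: str
    x: float
    y: float
    peak_intensity: float


@dataclass
class ParticleClass:
    """A colocalization class: which channels share a matched detection."""

    label: str  # donor_only | acceptor_only | two_color | three_color | gfp_only
    detections: dict[str, ParticleDetection] = field(default_factory=dict)


def average_initial_frames(stack: np.ndarray, n_frames: int = 10) -> np.ndarray:
    """Pixelwise mean of the first ``n_frames`` frames (static image)."""
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("expected a (T, H, W) stack")
    if stack.shape[0] < n_frames:
        raise ValueError(
            f"stack has {stack.shape[0]} frames, need at least {n_frames}"
        )
    return stack[:n_frames].mean(axis=0)


def detect_particles(
    image: np.ndarray,
    min_snr: float = 5.0,
    min_separation_px: int = 5,
    channel: str = "ch600",
) -> list[ParticleDetection]:
    """Local maxima above background mean + min_snr * background SD.

    Background statistics are estimated robustly (median and MAD) so the
    sparse spots do not inflate them.  Maxima closer than
    ``min_separation_px`` collapse to the brighter one; centroids are
    refined by intensity-weighted averaging in a 7x7 window.
    """
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise ValueError("image must be finite")
    bg_level = float(np.median(image))
    mad = float(np.median(np.abs(image - bg_level)))
    bg_sd = 1.4826 * mad
    if bg_sd == 0:
        bg_sd = float(image.std()) or 1.0
    threshold = bg_level + min_snr * bg_sd
    peaks = peak_local_max(
        image, min_distance=int(min_separation_px), threshold_abs=threshold
    )
    detections = []
    h, w = image.shape
    for py, px in peaks:
        y0, y1 = max(py - 3, 0), min(py + 4, h)
        x0, x1 = max(px - 3, 0), min(px + 4, w)
        window = np.clip(image[y0:y1, x0:x1] - bg_level, 0, None)
        total = window.sum()
        if total > 0:
            ys, xs = np.mgrid[y0:y1, x0:x1]
            cy = float((ys * window).sum() / total)
            cx = float((xs * window).sum() / total)
        else:
            cy, cx = float(py), float(px)
        detections.append(
            ParticleDetection(
                channel=channel, x=cx, y=cy, peak_intensity=float(image[py, px])
            )
        )
    return detections


def integrate_roi(
    stack: np.ndarray, centroid: tuple[float, float], size: int = 7
) -> np.ndarray:
    """Per-frame sum over the size x size window centered on the
    nearest-integer pixel of ``centroid`` (x, y).  Particles whose ROI
    would fall partially outside the image are rejected."""
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("expected a (T, H, W) stack")
    half = size // 2
    x = int(round(centroid[0]))
    y = int(round(centroid[1]))
    _, h, w = stack.shape
    if x - half < 0 or y - half < 0 or x + half >= w or y + half >= h:
        raise ValueError(
            f"ROI of size {size} at ({x}, {y}) extends outside the {h}x{w} image"
        )
    return stack[:, y - half : y + half + 1, x - half : x + half + 1].sum(axis=(1, 2))


def _greedy_pairs(
    a: list[ParticleDetection], b: list[ParticleDetection], max_dist: float
) -> list[tuple[int, int]]:
    """Globally greedy nearest-neighbor matching: closest pair first,
    each detection used at most once.  Symmetric in the argument order."""
    if not a or not b:
        return []
    pa = np.array([[d.x, d.y] for d in a])
    pb = np.array([[d.x, d.y] for d in b])
    dist = np.hypot(pa[:, None, 0] - pb[None, :, 0], pa[:, None, 1] - pb[None, :, 1])
    order = np.argsort(dist, axis=None, kind="stable")
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for flat in order:
        i, j = divmod(int(flat), len(b))
        if dist[i, j] > max_dist:
            break
        if i in used_a or j in used_b:
            continue
        pairs.append((i, j))
        used_a.add(i)
        used_b.add(j)
    return pairs


_CLASS_BY_CHANNELS = {
    frozenset({"ch600"}): "donor_only",
    frozenset({"ch700"}): "acceptor_only",
    frozenset({"ch525"}): "gfp_only",
    frozenset({"ch600", "ch700"}): "two_color",
    frozenset({"ch525", "ch600"}): "donor_only",
    frozenset({"ch525", "ch700"}): "acceptor_only",
    frozenset({"ch525", "ch600", "ch700"}): "three_color",
}


def colocalize(
    detections: dict[str, list[ParticleDetection]],
    max_dist_px: float = 2.0,
) -> list[ParticleClass]:
    """Classify particles by which channels show a matched detection.

    The donor (600 nm) and acceptor (700 nm) channels are paired first by
    globally greedy nearest-neighbor matching; 525 nm (GFP) detections
    are then matched to the pair midpoints (or to remaining singletons).
    ``two_color`` requires matched 600 and 700 nm detections;
    ``three_color`` additionally a 525 nm match.
    """
    if max_dist_px <= 0:
        raise ValueError("max_dist_px must be positive")
    d600 = list(detections.get("ch600", []))
    d700 = list(detections.get("ch700", []))
    d525 = list(detections.get("ch525", []))

    pairs = _greedy_pairs(d600, d700, max_dist_px)
    used600 = {i for i, _ in pairs}
    used700 = {j for _, j in pairs}

    groups: list[dict[str, ParticleDetection]] = []
    for i, j in pairs:
        groups.append({"ch600": d600[i], "ch700": d700[j]})
    groups.extend({"ch600": d} for k, d in enumerate(d600) if k not in used600)
    groups.extend({"ch700": d} for k, d in enumerate(d700) if k not in used700)

    # represent each group by its mean position, then attach GFP detections
    reps = [
        ParticleDetection(
            channel="group",
            x=float(np.mean([d.x for d in g.values()])),
            y=float(np.mean([d.y for d in g.values()])),
            peak_intensity=0.0,
        )
        for g in groups
    ]
    gfp_pairs = _greedy_pairs(reps, d525, max_dist_px)
    used525 = set()
    for gi, k in gfp_pairs:
        groups[gi]["ch525"] = d525[k]
        used525.add(k)
    groups.extend({"ch525": d} for k, d in enumerate(d525) if k not in used525)

    out = []
    for g in groups:
        label = _CLASS_BY_CHANNELS[frozenset(g.keys())]
        out.append(ParticleClass(label=label, detections=g))
    return out
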