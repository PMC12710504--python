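"""Inter-frame picking-point tracking and the pixel-consistency gate.

Depth samples fused across a window are only meaningful if every frame's
pixel coordinates refer to the same physical point. The gate computes the
Euclidean displacement of a tracked keypoint between consecutive frames,

    delta_i = sqrt((u_i - u_{i-1})^2 + (v_i - v_{i-1})^2),

and discards any frame whose displacement exceeds a threshold epsilon
(default 3 px); discarded frames contribute no depth sample downstream.
Displacement is measured against the previous *raw* frame, so one jumpy
frame costs only its own depth sample.

Cross-frame correspondence in the field system comes from a learned dense
matcher; here matching is a pluggable interface with a greedy
mutual-nearest-neighbour fallback adequate for synthetic sequences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DEFAULT_EPSILON_PX",
    "KeypointTrack",
    "GatedFrame",
    "GatedTrack",
    "match_next_frame",
    "gate_track",
    "flag_jitter_frames",
]

DEFAULT_EPSILON_PX = 3.0
DEFAULT_WINDOW = 5
WINDOW_RANGE = (3, 10)  # sensible fusion window at a 90 fps depth stream


@dataclass
class KeypointTrack:
    """Per-frame pixel coordinates of one picking point."""

    frames: list[tuple[int, float, float]]  # (frame_id, u, v)
    window: int = DEFAULT_WINDOW

    def __post_init__(self) -> None:
        ids = [f[0] for f in self.frames]
        if any(b <= a for a, b in zip(ids, ids[1:])):
            raise ValueError("frame ids must be strictly increasing")
        if len(self.frames) > self.window:
            raise ValueError(
                f"track of {len(self.frames)} frames exceeds window N={self.window}"
            )


@dataclass(frozen=True)
class GatedFrame:
    frame_id: int
    u: float
    v: float
    delta: float | None  # none for the first frame
    kept: bool


@dataclass
class GatedTrack:
    frames: list[GatedFrame]
    epsilon: float

    @property
    def kept_frames(self) -> list[GatedFrame]:
        return [f for f in self.frames if f.kept]

    @property
    def dropped_ids(self) -> list[int]:
        return [f.frame_id for f in self.frames if not f.kept]


def match_next_frame(points_t, points_t1, radius: float):
    """Greedy mutual-nearest matching between two frames' point sets.

    Pairs are accepted in order of increasing distance; each point is used
    at most once and pairs farther than ``radius`` are never formed.
    Returns a list of ``(index_t, index_t1)`` pairs.
    """
    if radius <= 0:
        raise ValueError(f"matching radius must be positive, got {radius}")
    a = np.asarray(points_t, dtype=float).reshape(-1, 2)
    b = np.asarray(points_t1, dtype=float).reshape(-1, 2)
    if a.size == 0 or b.size == 0:
        return []
    d = np.hypot(a[:, None, 0] - b[None, :, 0], a[:, None, 1] - b[None, :, 1])
    order = np.argsort(d, axis=None, kind="stable")
    used_a, used_b, pairs = set(), set(), []
    for flat in order:
        i, j = divmod(int(flat), d.shape[1])
        if d[i, j] > radius:
            break
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        pairs.append((i, j))
    return pairs


def gate_track(track: KeypointTrack, epsilon: float = DEFAULT_EPSILON_PX) -> GatedTrack:
    """Apply the consistency gate; a frame is kept iff delta <= epsilon.

    The first frame has no predecessor and is always kept. The boundary
    case delta == epsilon is kept (only exceedance triggers discard).
    """
    if not track.frames:
        raise ValueError("cannot gate an empty track")
    gated = []
    prev = None
    for frame_id, u, v in track.frames:
        if not (math.isfinite(u) and math.isfinite(v)):
            raise ValueError(f"non-finite coordinates in frame {frame_id}")
        if prev is None:
            gated.append(GatedFrame(frame_id, u, v, None, True))
        else:
            delta = math.hypot(u - prev[0], v - prev[1])
            gated.append(GatedFrame(frame_id, u, v, delta, delta <= epsilon))
        prev = (u, v)  # against the previous raw frame, kept or not
    return GatedTrack(frames=gated, epsilon=epsilon)


def flag_jitter_frames(gated: GatedTrack, factor: float = 3.0) -> list[int]:
    """Optional temporal-stability filter (off by default in the pipeline):
    flags frames whose displacement exceeds ``factor`` times the median
    displacement of the window, catching motion-blur style jitter that
    slips under the absolute gate."""
    deltas = [f.delta for f in gated.frames if f.delta is not None]
    if not deltas:
        return []
    med = float(np.median(deltas))
    if med == 0.0:
        return []
    return [f.frame_id for f in gated.frames
            if f.delta is not None and f.delta > factor * med]
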