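"""Adaptive multi-frame depth fusion and pinhole back-projection.

A depth camera's per-frame reading at one pixel fluctuates with sensor
noise, and occasionally fails outright (zero-valued holes) or bleeds
through to the background (large positive outliers). The fusion rule looks
at the valid samples {d_i > 0} of the gated window, computes their
population standard deviation sigma, and

* averages them when sigma <= T (stable sequence, noise suppression),
* takes their median when sigma > T (outliers present, robustness),

with T = 0.01 m by default. The fused depth d_hat and pixel (u, v) are then
back-projected through the pinhole model

    X = (u - cx) * d_hat / fx,   Y = (v - cy) * d_hat / fy,   Z = d_hat.

Units are meters internally; reports at the interface are in millimeters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .tracking import GatedTrack, KeypointTrack, gate_track

__all__ = [
    "DEFAULT_SIGMA_THRESHOLD_M",
    "CameraIntrinsics",
    "DepthSampleSequence",
    "FusedDepth",
    "Point3D",
    "AllInvalidDepthError",
    "collect_depth_samples",
    "fuse_depth",
    "deproject_pixel",
    "project_point",
    "localize_track",
    "LocalizationResult",
]

DEFAULT_SIGMA_THRESHOLD_M = 0.01


class AllInvalidDepthError(ValueError):
    """Every depth sample in the window is a hole; the point is unlocatable."""


@dataclass(frozen=True)
class CameraIntrinsics:
    """Pinhole parameters; distortion defaults to none (the depth stream of
    the target sensor is emitted undistorted)."""

    fx: float
    fy: float
    cx: float
    cy: float
    width: int
    height: int
    distortion: tuple = ()

    def __post_init__(self) -> None:
        if self.fx <= 0 or self.fy <= 0:
            raise ValueError("focal lengths must be positive")
        if not (0 <= self.cx < self.width and 0 <= self.cy < self.height):
            raise ValueError("principal point must lie inside the sensor")


@dataclass
class DepthSampleSequence:
    """Raw depth samples (meters; 0 marks a hole) with matching frame ids."""

    samples: list[float]
    frame_ids: list[int]

    def __post_init__(self) -> None:
        if len(self.samples) != len(self.frame_ids):
            raise ValueError("samples and frame_ids must have equal length")
        if any(d < 0 for d in self.samples):
            raise ValueError("depth samples must be >= 0")

    @property
    def valid(self) -> np.ndarray:
        return np.asarray([d for d in self.samples if d > 0], dtype=float)

    @property
    def M(self) -> int:
        return int(sum(1 for d in self.samples if d > 0))


@dataclass(frozen=True)
class FusedDepth:
    d_hat: float
    sigma: float
    M: int
    strategy: str  # single | mean | median | adaptive->mean | adaptive->median


@dataclass(frozen=True)
class Point3D:
    X: float
    Y: float
    Z: float

    def to_mm(self) -> tuple[float, float, float]:
        return (self.X * 1000.0, self.Y * 1000.0, self.Z * 1000.0)


def collect_depth_samples(depth_frames, gated: GatedTrack) -> DepthSampleSequence:
    """Read one depth sample per kept frame at the nearest integer pixel.

    ``depth_frames`` maps frame id -> depth map (meters) or is a sequence
    indexed by position within the gated track. Dropped frames contribute
    nothing; holes are recorded as 0 (and excluded from M downstream); a
    pixel outside the map raises a warning and the sample is skipped.
    """
    samples: list[float] = []
    ids: list[int] = []
    for pos, frame in enumerate(gated.frames):
        if not frame.kept:
            continue
        if isinstance(depth_frames, dict):
            depth = depth_frames[frame.frame_id]
        else:
            depth = depth_frames[pos]
        depth = np.asarray(depth)
        r, c = int(round(frame.v)), int(round(frame.u))
        if not (0 <= r < depth.shape[0] and 0 <= c < depth.shape[1]):
            warnings.warn(
                f"frame {frame.frame_id}: pixel ({frame.u:.1f}, {frame.v:.1f}) "
                f"outside {depth.shape[1]}x{depth.shape[0]} depth map; sample skipped",
                stacklevel=2,
            )
            continue
        samples.append(float(depth[r, c]))
        ids.append(frame.frame_id)
    return DepthSampleSequence(samples=samples, frame_ids=ids)


def fuse_depth(
    seq: DepthSampleSequence,
    strategy: str = "adaptive",
    T: float = DEFAULT_SIGMA_THRESHOLD_M,
) -> FusedDepth:
    """Fuse the valid samples of a window into one depth estimate.

    ``sigma`` is the population standard deviation of the valid set (so a
    single sample gives sigma = 0 deterministically). The adaptive rule
    takes the mean when sigma <= T, otherwise the median; ``mean`` /
    ``median`` apply unconditionally; ``single`` returns the first valid
    sample. An even-sized median averages the two central values.
    """
    valid = seq.valid
    if valid.size == 0:
        raise AllInvalidDepthError("no valid (d > 0) depth sample in the window")
    sigma = float(np.std(valid))  # population form (divide by M)
    if strategy == "single":
        return FusedDepth(float(valid[0]), sigma, valid.size, "single")
    if strategy == "mean":
        return FusedDepth(float(np.mean(valid)), sigma, valid.size, "mean")
    if strategy == "median":
        return FusedDepth(float(np.median(valid)), sigma, valid.size, "median")
    if strategy == "adaptive":
        if sigma <= T:
            return FusedDepth(float(np.mean(valid)), sigma, valid.size, "adaptive->mean")
        return FusedDepth(float(np.median(valid)), sigma, valid.size, "adaptive->median")
    raise ValueError(f"unknown fusion strategy {strategy!r}")


def deproject_pixel(K: CameraIntrinsics, u: float, v: float, d_hat: float) -> Point3D:
    """Back-project pixel (u, v) at fused depth d_hat to camera-frame meters."""
    if d_hat <= 0:
        raise ValueError(f"depth must be positive, got {d_hat}")
    return Point3D(
        X=(u - K.cx) * d_hat / K.fx,
        Y=(v - K.cy) * d_hat / K.fy,
        Z=d_hat,
    )


def project_point(K: CameraIntrinsics, p: Point3D) -> tuple[float, float]:
    """Forward pinhole projection (inverse of :func:`deproject_pixel`)."""
    if p.Z <= 0:
        raise ValueError(f"point behind camera (Z={p.Z})")
    return (K.fx * p.X / p.Z + K.cx, K.fy * p.Y / p.Z + K.cy)


@dataclass
class LocalizationResult:
    """3D picking-point estimate with a structured provenance record."""

    point: Point3D | None
    point_mm: tuple[float, float, float] | None
    fused: FusedDepth | None
    gated: GatedTrack
    localized: bool
    pixel: tuple[float, float] | None = None
    dropped_frames: list[int] = field(default_factory=list)


def localize_track(
    depth_frames,
    track: KeypointTrack,
    K: CameraIntrinsics,
    epsilon: float = 3.0,
    T: float = DEFAULT_SIGMA_THRESHOLD_M,
    strategy: str = "adaptive",
) -> LocalizationResult:
    """Full pipeline for one picking point: gate -> collect -> fuse ->
    deproject. The pixel used for back-projection is the most recent kept
    frame's (u, v) — the actionable current position of the point. Returns
    an unlocalized result when every sample in the window is a hole.
    """
    gated = gate_track(track, epsilon)
    seq = collect_depth_samples(depth_frames, gated)
    try:
        fused = fuse_depth(seq, strategy=strategy, T=T)
    except AllInvalidDepthError:
        return LocalizationResult(
            point=None, point_mm=None, fused=None, gated=gated,
            localized=False, dropped_frames=gated.dropped_ids,
        )
    last = gated.kept_frames[-1]
    point = deproject_pixel(K, last.u, last.v, fused.d_hat)
    return LocalizationResult(
        point=point, point_mm=point.to_mm(), fused=fused, gated=gated,
        localized=True, pixel=(last.u, last.v), dropped_frames=gated.dropped_ids,
    )
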