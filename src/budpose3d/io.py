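"""File-format plumbing: 16-bit depth PNGs, intrinsics JSON, track CSV."""

from __future__ import annotations

import csv
import json

import numpy as np
from PIL import Image

from .localize3d import CameraIntrinsics
from .tracking import KeypointTrack

__all__ = [
    "write_depth_png",
    "read_depth_png",
    "write_intrinsics",
    "read_intrinsics",
    "read_tracks_csv",
    "write_tracks_csv",
]

DEPTH_SCALE_MM = 1000.0  # stored integer unit: millimeters


def write_depth_png(path, depth_m: np.ndarray) -> None:
    """Store a metric depth map as a 16-bit PNG in millimeter units."""
    mm = np.clip(np.rint(np.asarray(depth_m) * DEPTH_SCALE_MM), 0, 65535)
    Image.fromarray(mm.astype(np.uint16)).save(path)


def read_depth_png(path) -> np.ndarray:
    mm = np.asarray(Image.open(path), dtype=np.float64)
    return mm / DEPTH_SCALE_MM


def write_intrinsics(path, K: CameraIntrinsics) -> None:
    with open(path, "w") as fh:
        json.dump({"fx": K.fx, "fy": K.fy, "cx": K.cx, "cy": K.cy,
                   "width": K.width, "height": K.height,
                   "distortion": list(K.distortion)}, fh, indent=2)


def read_intrinsics(path) -> CameraIntrinsics:
    with open(path) as fh:
        d = json.load(fh)
    return CameraIntrinsics(fx=d["fx"], fy=d["fy"], cx=d["cx"], cy=d["cy"],
                            width=d["width"], height=d["height"],
                            distortion=tuple(d.get("distortion", ())))


def write_tracks_csv(path, tracks: dict[str, KeypointTrack]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["track_id", "frame_id", "u", "v"])
        for tid, track in tracks.items():
            for frame_id, u, v in track.frames:
                writer.writerow([tid, frame_id, f"{u:.4f}", f"{v:.4f}"])


def read_tracks_csv(path, window: int = 10) -> dict[str, KeypointTrack]:
    rows: dict[str, list[tuple[int, float, float]]] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        has_id = header and header[0].strip().lower() == "track_id"
        if not has_id:
            fh.seek(0)
            reader = csv.reader(fh)
            first = next(reader)
            if first[0].strip().lower() != "frame_id":
                rows.setdefault("0", []).append(
                    (int(first[0]), float(first[1]), float(first[2])))
        for row in reader:
            if not row:
                continue
            if has_id:
                rows.setdefault(row[0], []).append(
                    (int(row[1]), float(row[2]), float(row[3])))
            else:
                rows.setdefault("0", []).append(
                    (int(row[0]), float(row[1]), float(row[2])))
    return {tid: KeypointTrack(frames=frames, window=max(window, len(frames)))
            for tid, frames in rows.items()}
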