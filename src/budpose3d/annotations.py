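"""Visibility-aware eight-keypoint bud annotations.

A tea bud is annotated as one bounding box plus eight structural keypoints
(bud tip, leaf nodes, picking point, ...), each carrying a visibility flag:

* ``0`` — invisible: heavily occluded, position indeterminable (placeholder
  coordinates allowed),
* ``1`` — occluded: hidden but inferable from structural cues,
* ``2`` — visible: clearly discernible.

The module reads Labelme-style JSON, converts to/from YOLO-pose label lines
(``class xc yc w h  x1 y1 v1 ... x8 y8 v8``, coordinates normalized by the
image size) and performs the deterministic 7:2:1 train/test/val split.
"""

from __future__ import annotations

import json
import math
import tomllib
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "N_KEYPOINTS",
    "Keypoint2D",
    "BudAnnotation",
    "DatasetSplit",
    "KeypointSchema",
    "SchemaViolation",
    "parse_labelme",
    "write_yolo_pose",
    "read_yolo_pose",
    "split_dataset",
]

N_KEYPOINTS = 8

#: default anatomical slot names for the eight keypoints; the last slot is
#: the picking point (the cut location 1-2 cm below the third-leaf node).
DEFAULT_KEYPOINT_NAMES = (
    "bud_tip",
    "bud_base",
    "first_leaf_node",
    "second_leaf_node",
    "third_leaf_node",
    "first_leaf_tip",
    "second_leaf_tip",
    "picking_point",
)


class SchemaViolation(ValueError):
    """An annotation breaks the eight-keypoint schema."""


@dataclass(frozen=True)
class KeypointSchema:
    """Names of the eight keypoint slots and which slot is the picking point.

    The anatomical identity of each slot is configurable (loaded from a TOML
    file); only the count (eight) and the flag semantics are fixed.
    """

    names: tuple[str, ...] = DEFAULT_KEYPOINT_NAMES
    picking_point_index: int = 7

    def __post_init__(self) -> None:
        if len(self.names) != N_KEYPOINTS:
            raise SchemaViolation(
                f"schema must name exactly {N_KEYPOINTS} keypoints, got {len(self.names)}"
            )
        if not 0 <= self.picking_point_index < N_KEYPOINTS:
            raise SchemaViolation("picking_point_index out of range")

    def index_of(self, name: str) -> int:
        return self.names.index(name)

    @classmethod
    def from_toml(cls, text: str) -> "KeypointSchema":
        doc = tomllib.loads(text)
        kp = doc.get("keypoints", doc)
        return cls(
            names=tuple(kp["names"]),
            picking_point_index=int(kp.get("picking_point_index", 7)),
        )


@dataclass
class Keypoint2D:
    """One keypoint in pixel coordinates (origin top-left, ``u`` = column)."""

    u: float
    v: float
    visibility: int = 2
    index: int = 0

    def __post_init__(self) -> None:
        if self.visibility not in (0, 1, 2):
            raise ValueError(f"visibility must be 0, 1 or 2, got {self.visibility}")
        if not 0 <= self.index < N_KEYPOINTS:
            raise ValueError(f"keypoint index must be in [0,{N_KEYPOINTS}), got {self.index}")


@dataclass
class BudAnnotation:
    """One bud: normalized bbox + exactly eight keypoints in schema order."""

    bbox: tuple[float, float, float, float]  # (xc, yc, w, h), normalized
    keypoints: list[Keypoint2D]
    image_size: tuple[int, int]  # (width, height) in pixels
    class_id: int = 0

    def __post_init__(self) -> None:
        if len(self.keypoints) != N_KEYPOINTS:
            raise SchemaViolation(
                f"bud must carry exactly {N_KEYPOINTS} keypoints, got {len(self.keypoints)}"
            )
        if len({kp.index for kp in self.keypoints}) != N_KEYPOINTS:
            raise SchemaViolation("keypoint indices must be unique within one bud")
        for comp in self.bbox:
            if not 0.0 <= comp <= 1.0:
                raise ValueError(f"normalized bbox component {comp} outside [0,1]")

    def validate_bounds(self) -> None:
        """Every visible keypoint must lie inside the image bounds."""
        w, h = self.image_size
        for kp in self.keypoints:
            if kp.visibility == 2 and not (0 <= kp.u < w and 0 <= kp.v < h):
                raise SchemaViolation(
                    f"visible keypoint {kp.index} at ({kp.u}, {kp.v}) outside {w}x{h} image"
                )

    def keypoints_sorted(self) -> list[Keypoint2D]:
        return sorted(self.keypoints, key=lambda kp: kp.index)


@dataclass
class DatasetSplit:
    train: list = field(default_factory=list)
    test: list = field(default_factory=list)
    val: list = field(default_factory=list)
    seed: int = 0


# ---------------------------------------------------------------------------
# Labelme parsing


def _rect_corners(points: list) -> tuple[float, float, float, float]:
    (xa, ya), (xb, yb) = points[0], points[1]
    return min(xa, xb), min(ya, yb), max(xa, xb), max(ya, yb)


def _point_visibility(shape: dict) -> int:
    # Labelme has no native visibility field; annotators store it either in
    # the flags dict or as a shape attribute. Absent -> clearly visible (2).
    flags = shape.get("flags") or {}
    for key in ("visibility", "visible"):
        if key in flags:
            return int(flags[key])
        if key in shape:
            return int(shape[key])
    # flag-style booleans: {"visible": true} handled above; {"v0": true} etc.
    for flag, value in flags.items():
        if value and flag in ("v0", "v1", "v2"):
            return int(flag[1])
    return 2


def parse_labelme(
    json_text: str,
    image_size: tuple[int, int],
    schema: KeypointSchema | None = None,
) -> list[BudAnnotation]:
    """Parse a Labelme-dialect document into :class:`BudAnnotation` objects.

    Rectangle shapes are buds; point shapes are keypoints. A point is
    assigned to the rectangle containing it (ties broken by nearest
    rectangle center; a point inside no rectangle goes to the nearest
    center). Each rectangle must end up with exactly eight points whose
    labels resolve to the eight distinct schema slots.
    """
    schema = schema or KeypointSchema()
    try:
        doc = json.loads(json_text)
    except json.JSONDecodeError as exc:
        raise ValueError(f"malformed Labelme JSON: {exc}") from exc

    shapes = doc.get("shapes", [])
    w, h = image_size
    rects: list[tuple[float, float, float, float]] = []
    points: list[tuple[float, float, int, int]] = []  # u, v, visibility, slot

    for shape in shapes:
        stype = shape.get("shape_type")
        if stype == "rectangle":
            rects.append(_rect_corners(shape["points"]))
        elif stype == "point":
            (u, v) = shape["points"][0]
            label = shape.get("label", "")
            if label in schema.names:
                slot = schema.index_of(label)
            else:
                # accept "kp1".."kp8" style labels as 1-based slots
                digits = "".join(ch for ch in label if ch.isdigit())
                if not digits:
                    raise SchemaViolation(f"point label {label!r} not in schema")
                slot = int(digits) - 1
                if not 0 <= slot < N_KEYPOINTS:
                    raise SchemaViolation(f"point label {label!r} resolves outside slots 1..8")
            points.append((float(u), float(v), _point_visibility(shape), slot))

    if not rects:
        if points:
            raise SchemaViolation("keypoints present but no bud rectangle to assign them to")
        return []

    centers = [((x1 + x2) / 2.0, (y1 + y2) / 2.0) for x1, y1, x2, y2 in rects]
    assigned: list[list[tuple[float, float, int, int]]] = [[] for _ in rects]
    for u, v, vis, slot in points:
        containing = [
            i for i, (x1, y1, x2, y2) in enumerate(rects) if x1 <= u <= x2 and y1 <= v <= y2
        ]
        candidates = containing if containing else range(len(rects))
        best = min(candidates, key=lambda i: math.hypot(u - centers[i][0], v - centers[i][1]))
        assigned[best].append((u, v, vis, slot))

    annotations = []
    for bud_id, ((x1, y1, x2, y2), pts) in enumerate(zip(rects, assigned)):
        if len(pts) != N_KEYPOINTS:
            raise SchemaViolation(
                f"bud {bud_id}: expected {N_KEYPOINTS} keypoints, got {len(pts)}"
            )
        kps = [Keypoint2D(u=u, v=v, visibility=vis, index=slot) for u, v, vis, slot in pts]
        if len({kp.index for kp in kps}) != N_KEYPOINTS:
            raise SchemaViolation(f"bud {bud_id}: duplicate keypoint slots")
        bbox = ((x1 + x2) / 2 / w, (y1 + y2) / 2 / h, (x2 - x1) / w, (y2 - y1) / h)
        ann = BudAnnotation(bbox=bbox, keypoints=sorted(kps, key=lambda kp: kp.index),
                            image_size=(w, h))
        ann.validate_bounds()
        annotations.append(ann)
    return annotations


# ---------------------------------------------------------------------------
# YOLO-pose label lines


def write_yolo_pose(annotations: list[BudAnnotation]) -> list[str]:
    """Format annotations as YOLO-pose label lines (6-decimal fixed)."""
    lines = []
    for ann in annotations:
        w, h = ann.image_size
        fields = [str(ann.class_id)] + [f"{c:.6f}" for c in ann.bbox]
        for kp in ann.keypoints_sorted():
            un, vn = kp.u / w, kp.v / h
            if kp.visibility != 0 and not (0.0 <= un <= 1.0 and 0.0 <= vn <= 1.0):
                raise ValueError(
                    f"keypoint {kp.index} normalizes to ({un:.4f}, {vn:.4f}) outside [0,1]"
                )
            fields += [f"{un:.6f}", f"{vn:.6f}", str(kp.visibility)]
        lines.append(" ".join(fields))
    return lines


def read_yolo_pose(label_lines: list[str], image_size: tuple[int, int]) -> list[BudAnnotation]:
    """Inverse of :func:`write_yolo_pose` (round trip exact to 1e-6)."""
    w, h = image_size
    annotations = []
    for lineno, line in enumerate(label_lines, start=1):
        fields = line.split()
        if not fields:
            continue
        expected = 5 + 3 * N_KEYPOINTS
        if len(fields) != expected:
            raise ValueError(
                f"line {lineno}: expected {expected} fields, got {len(fields)}"
            )
        class_id = int(fields[0])
        bbox = tuple(float(x) for x in fields[1:5])
        kps = []
        for i in range(N_KEYPOINTS):
            un, vn, vis_s = fields[5 + 3 * i : 8 + 3 * i]
            vis = int(float(vis_s))
            if vis not in (0, 1, 2):
                raise ValueError(f"line {lineno}: visibility {vis_s!r} not in {{0,1,2}}")
            kps.append(Keypoint2D(u=float(un) * w, v=float(vn) * h, visibility=vis, index=i))
        annotations.append(
            BudAnnotation(bbox=bbox, keypoints=kps, image_size=(w, h), class_id=class_id)
        )
    return annotations


# ---------------------------------------------------------------------------
# Dataset split


def split_dataset(
    item_ids: list,
    ratios: tuple[float, float, float] = (0.7, 0.2, 0.1),
    seed: int = 0,
) -> DatasetSplit:
    """Randomly partition items into train/test/val at the given ratios.

    Sizes are floor allocations of ``n * ratio`` with the rounding remainder
    assigned to the training set; deterministic for a fixed seed.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {sum(ratios)}")
    if not item_ids:
        raise ValueError("cannot split an empty item list")
    n = len(item_ids)
    n_train = int(n * ratios[0])
    n_test = int(n * ratios[1])
    n_val = int(n * ratios[2])
    n_train += n - (n_train + n_test + n_val)  # remainder -> train
    order = np.random.default_rng(seed).permutation(n)
    shuffled = [item_ids[i] for i in order]
    return DatasetSplit(
        train=shuffled[:n_train],
        test=shuffled[n_train : n_train + n_test],
        val=shuffled[n_train + n_test :],
        seed=seed,
    )
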