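"""Label-synchronized image augmentation.

Every transform returns ``(image, annotations)`` with the labels moved by
exactly the same mapping as the pixels: geometric ops (rotation, flips) map
keypoints through the pixel affine transform and recompute boxes as the
axis-aligned hull of the transformed corners; photometric ops (brightness,
exposure, Gaussian noise/blur, rain streaks, fog) never touch the labels;
synthetic occlusion patches blacken pixels and downgrade covered visible
keypoints to "occluded". A keypoint mapped off the canvas becomes invisible
(flag 0).

Pixel convention: 0-based indices, origin top-left, ``u`` = column; rotation
is about the pixel center ``((W-1)/2, (H-1)/2)`` so that a 90-degree turn of
a square image maps ``(u, v) -> (W-1-v, u)`` exactly.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.draw import line_aa
from skimage.transform import resize

from .annotations import BudAnnotation, Keypoint2D

__all__ = [
    "AugmentSpec",
    "apply_geometric",
    "apply_photometric",
    "apply_occlusion",
    "letterbox",
    "LetterboxMapping",
    "apply",
]

GEOMETRIC_KINDS = {"rotate", "hflip", "vflip"}
PHOTOMETRIC_KINDS = {"brightness", "exposure", "gauss_noise", "gauss_blur", "rain", "fog"}


@dataclass(frozen=True)
class AugmentSpec:
    """One augmentation step: a kind plus its parameters and a seed.

    Defaults follow field-realistic ranges: rotations within +/-30 degrees,
    fog opacity 0.2-0.6, 1-3 occlusion patches of 5-20% image width.
    """

    kind: str
    params: dict = dataclasses.field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        p = self.params
        if self.kind == "gauss_noise" and p.get("sigma", 0.0) < 0:
            raise ValueError("noise sigma must be >= 0")
        if self.kind == "gauss_blur" and p.get("sigma", 1.0) < 0:
            raise ValueError("blur sigma must be >= 0")
        if self.kind == "fog" and not 0.0 <= p.get("opacity", 0.4) <= 1.0:
            raise ValueError("fog opacity must lie in [0,1]")
        if self.kind == "rotate" and not math.isfinite(p.get("angle_deg", 0.0)):
            raise ValueError("rotation angle must be finite")
        if self.kind == "occlusion":
            if p.get("n_patches", 1) < 1:
                raise ValueError("occlusion needs at least one patch")


def _transformed_annotations(
    annotations: list[BudAnnotation],
    point_map,
    out_size: tuple[int, int],
) -> list[BudAnnotation]:
    """Map keypoints and bbox corners of each bud through ``point_map``."""
    w_out, h_out = out_size
    out = []
    for ann in annotations:
        w, h = ann.image_size
        xc, yc, bw, bh = ann.bbox
        x1, y1 = (xc - bw / 2) * w, (yc - bh / 2) * h
        x2, y2 = (xc + bw / 2) * w, (yc + bh / 2) * h
        corners = np.array([point_map(u, v) for (u, v) in
                            [(x1, y1), (x2, y1), (x2, y2), (x1, y2)]])
        cx1, cy1 = corners.min(axis=0)
        cx2, cy2 = corners.max(axis=0)
        cx1, cx2 = np.clip([cx1, cx2], 0, w_out)
        cy1, cy2 = np.clip([cy1, cy2], 0, h_out)
        bbox = (
            (cx1 + cx2) / 2 / w_out,
            (cy1 + cy2) / 2 / h_out,
            (cx2 - cx1) / w_out,
            (cy2 - cy1) / h_out,
        )
        kps = []
        for kp in ann.keypoints:
            u2, v2 = point_map(kp.u, kp.v)
            vis = kp.visibility
            if vis != 0 and not (0 <= u2 < w_out and 0 <= v2 < h_out):
                vis = 0  # left the canvas
            kps.append(Keypoint2D(u=u2, v=v2, visibility=vis, index=kp.index))
        out.append(BudAnnotation(bbox=bbox, keypoints=kps,
                                 image_size=(w_out, h_out), class_id=ann.class_id))
    return out


def apply_geometric(image, annotations, spec: AugmentSpec):
    """Rotate or flip the image with keypoints/boxes mapped identically."""
    if spec.kind not in GEOMETRIC_KINDS:
        raise ValueError(f"{spec.kind!r} is not a geometric augmentation")
    image = np.asarray(image)
    h, w = image.shape[:2]

    if spec.kind == "hflip":
        out = image[:, ::-1].copy()
        point_map = lambda u, v: (w - 1 - u, v)  # noqa: E731
    elif spec.kind == "vflip":
        out = image[::-1].copy()
        point_map = lambda u, v: (u, h - 1 - v)  # noqa: E731
    else:
        angle = math.radians(spec.params.get("angle_deg", 0.0))
        cu, cv = (w - 1) / 2.0, (h - 1) / 2.0
        cos, sin = math.cos(angle), math.sin(angle)

        def point_map(u, v):
            du, dv = u - cu, v - cv
            return (cu + cos * du - sin * dv, cv + sin * du + cos * dv)

        # right-angle turns of a square canvas are exact array ops
        deg = spec.params.get("angle_deg", 0.0) % 360.0
        if h == w and deg in (0.0, 90.0, 180.0, 270.0):
            out = np.ascontiguousarray(np.rot90(image, k=-int(deg // 90), axes=(0, 1)))
        else:
            # pull-back: ndimage applies the matrix to output coords, so use
            # the inverse rotation of the forward point map
            mat = np.array([[cos, sin], [-sin, cos]])
            offset = np.array([cv, cu]) - mat @ np.array([cv, cu])
            chans = image[..., None] if image.ndim == 2 else image
            planes = [
                ndimage.affine_transform(
                    chans[..., c].astype(np.float64), mat, offset=offset,
                    order=1, mode="constant", cval=0.0)
                for c in range(chans.shape[-1])
            ]
            out = np.stack(planes, axis=-1)
            if image.ndim == 2:
                out = out[..., 0]
            if np.issubdtype(image.dtype, np.integer):
                out = np.clip(np.rint(out), 0, 255).astype(image.dtype)
    return out, _transformed_annotations(annotations, point_map, (w, h))


def _clip_like(image, values):
    if np.issubdtype(image.dtype, np.integer):
        return np.clip(np.rint(values), 0, 255).astype(image.dtype)
    return np.clip(values, 0.0, 1.0).astype(image.dtype)


def apply_photometric(image, annotations, spec: AugmentSpec):
    """Pixel-value augmentation; annotations pass through untouched."""
    if spec.kind not in PHOTOMETRIC_KINDS:
        raise ValueError(f"{spec.kind!r} is not a photometric augmentation")
    image = np.asarray(image)
    x = image.astype(np.float64)
    rng = np.random.default_rng(spec.seed)
    p = spec.params

    if spec.kind == "brightness":
        x = x + p.get("delta", 0.0)
    elif spec.kind == "exposure":
        x = x * p.get("gain", 1.0)
    elif spec.kind == "gauss_noise":
        x = x + rng.normal(0.0, p.get("sigma", 10.0), size=x.shape)
    elif spec.kind == "gauss_blur":
        sigma = p.get("sigma", 1.5)
        spatial = (sigma, sigma) + (0,) * (x.ndim - 2)
        x = ndimage.gaussian_filter(x, sigma=spatial)
    elif spec.kind == "fog":
        alpha = p.get("opacity", 0.4)
        fog_val = p.get("color", 200.0 if np.issubdtype(image.dtype, np.integer) else 0.8)
        x = (1.0 - alpha) * x + alpha * fog_val
    elif spec.kind == "rain":
        x = _render_rain(x, rng, p)
    return _clip_like(image, x), annotations


def _render_rain(x, rng, p):
    """Seeded anti-aliased streaks with a common direction plus jitter."""
    h, w = x.shape[:2]
    n = int(p.get("n_streaks", 60))
    length = float(p.get("length", 0.05 * max(h, w) + 8))
    angle = math.radians(p.get("angle_deg", 75.0))
    jitter = math.radians(p.get("direction_jitter_deg", 5.0))
    bright = float(p.get("intensity", 180.0))
    for _ in range(n):
        u0 = rng.uniform(0, w - 1)
        v0 = rng.uniform(0, h - 1)
        a = angle + rng.uniform(-jitter, jitter)
        u1 = np.clip(u0 + length * math.cos(a), 0, w - 1)
        v1 = np.clip(v0 + length * math.sin(a), 0, h - 1)
        rr, cc, val = line_aa(int(round(v0)), int(round(u0)), int(round(v1)), int(round(u1)))
        if x.ndim == 3:
            x[rr, cc] = x[rr, cc] * (1 - val[:, None] * 0.7) + bright * (val[:, None] * 0.7)
        else:
            x[rr, cc] = x[rr, cc] * (1 - val * 0.7) + bright * (val * 0.7)
    return x


def apply_occlusion(image, annotations, spec: AugmentSpec):
    """Black rectangular patches; covered visible keypoints become occluded.

    Visibility transitions are monotone non-increasing: 2 -> 1 inside a
    patch, flags 0 and 1 are never changed.
    """
    if spec.kind != "occlusion":
        raise ValueError(f"{spec.kind!r} is not the occlusion augmentation")
    image = np.asarray(image)
    h, w = image.shape[:2]
    patches = spec.params.get("patches")
    if patches is None:
        rng = np.random.default_rng(spec.seed)
        n = int(spec.params.get("n_patches", rng.integers(1, 4)))
        lo, hi = spec.params.get("size_frac", (0.05, 0.20))
        patches = []
        for _ in range(n):
            pw = max(1, int(rng.uniform(lo, hi) * w))
            ph = max(1, int(rng.uniform(lo, hi) * w))
            u0 = int(rng.uniform(0, max(1, w - pw)))
            v0 = int(rng.uniform(0, max(1, h - ph)))
            patches.append((u0, v0, u0 + pw, v0 + ph))
    out = image.copy()
    clipped = []
    for (x1, y1, x2, y2) in patches:
        x1c, x2c = int(np.clip(x1, 0, w)), int(np.clip(x2, 0, w))
        y1c, y2c = int(np.clip(y1, 0, h)), int(np.clip(y2, 0, h))
        if x2c <= x1c or y2c <= y1c:
            raise ValueError(f"zero-area occlusion patch ({x1},{y1},{x2},{y2})")
        out[y1c:y2c, x1c:x2c] = 0
        clipped.append((x1c, y1c, x2c, y2c))

    new_annotations = []
    for ann in annotations:
        kps = []
        for kp in ann.keypoints:
            vis = kp.visibility
            if vis == 2 and any(x1 <= kp.u < x2 and y1 <= kp.v < y2
                                for (x1, y1, x2, y2) in clipped):
                vis = 1
            kps.append(Keypoint2D(u=kp.u, v=kp.v, visibility=vis, index=kp.index))
        new_annotations.append(BudAnnotation(
            bbox=ann.bbox, keypoints=kps, image_size=ann.image_size, class_id=ann.class_id))
    return out, new_annotations


@dataclass(frozen=True)
class LetterboxMapping:
    """Forward/inverse point mapping of an aspect-preserving letterbox."""

    scale: float
    pad: tuple[float, float]  # (pad_u, pad_v)

    def map(self, u, v):
        return u * self.scale + self.pad[0], v * self.scale + self.pad[1]

    def unmap(self, u, v):
        return (u - self.pad[0]) / self.scale, (v - self.pad[1]) / self.scale


def letterbox(image, annotations, target: tuple[int, int] = (640, 640)):
    """Aspect-preserving resize with symmetric padding to a square canvas.

    Returns ``(image, annotations, mapping)`` where ``mapping`` carries the
    exact forward and inverse point transforms so pixel-space predictions
    can be mapped back to the original frame.
    """
    tw, th = target
    if tw != th:
        raise ValueError("letterbox target must be square")
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    h, w = image.shape[:2]
    s = min(tw / w, th / h)
    new_w, new_h = int(round(w * s)), int(round(h * s))
    pad_u, pad_v = (tw - new_w) / 2.0, (th - new_h) / 2.0
    mapping = LetterboxMapping(scale=s, pad=(pad_u, pad_v))

    if (new_w, new_h) == (w, h):
        resized = image.astype(np.float64)
    else:
        resized = resize(image.astype(np.float64), (new_h, new_w) + image.shape[2:],
                         order=1, anti_aliasing=new_w < w, preserve_range=True)
    shape = (th, tw) + image.shape[2:]
    canvas = np.zeros(shape, dtype=np.float64)
    top, left = int(math.floor(pad_v)), int(math.floor(pad_u))
    canvas[top:top + new_h, left:left + new_w] = resized
    out = _clip_like(image, canvas)
    anns = _transformed_annotations(annotations, mapping.map, (tw, th))
    return out, anns, mapping


def apply(image, annotations, spec: AugmentSpec):
    """Dispatch a spec to the matching transform (letterbox excluded)."""
    if spec.kind in GEOMETRIC_KINDS:
        return apply_geometric(image, annotations, spec)
    if spec.kind in PHOTOMETRIC_KINDS:
        return apply_photometric(image, annotations, spec)
    if spec.kind == "occlusion":
        return apply_occlusion(image, annotations, spec)
    raise ValueError(f"unknown augmentation kind {spec.kind!r}")
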