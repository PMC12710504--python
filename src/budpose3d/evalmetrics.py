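"""Detection and keypoint-localization evaluation.

Implements the standard detection triple — precision ``P = TP/(TP+FP)``,
recall ``R = TP/(TP+FN)``, and average precision ``AP = integral of P(R)``
over the monotone precision envelope — with greedy IoU matching at a 0.5
threshold, plus two 3D localization metrics:

* ``PCK@t``: the fraction of keypoints whose error d_i is strictly below a
  threshold t, sampled on a 0.5 mm grid;
* ``OKS``: a Gaussian similarity ``exp(-d^2 / (2 s^2 k^2))`` in the object
  scale s (mm) with scale-adjusting factor k; 1 means a perfect hit.

For keypoint detection P(K)/R(K)/mAP(K), the mean OKS of a predicted
keypoint set replaces IoU in the greedy matcher (the field has no single
canonical rule; the threshold is configurable).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DetEval",
    "PCKCurve",
    "OKSResult",
    "iou",
    "match_detections",
    "pr_ap",
    "pck_curve",
    "oks_score",
    "oks_set",
    "keypoint_pr",
]

DEFAULT_OKS_K = 0.1


@dataclass(frozen=True)
class DetEval:
    TP: int
    FP: int
    FN: int
    precision: float
    recall: float
    AP: float | None  # None when undefined (no ground truth)


@dataclass
class PCKCurve:
    thresholds: np.ndarray  # mm
    values: np.ndarray  # PCK@t in [0, 1]
    errors: np.ndarray  # per-point errors d_i (mm)

    def at(self, t: float) -> float:
        idx = int(np.argmin(np.abs(self.thresholds - t)))
        return float(self.values[idx])


@dataclass(frozen=True)
class OKSResult:
    d: float  # mm
    s: float  # object scale, mm
    k: float
    oks: float


def iou(box_a, box_b) -> float:
    """Intersection-over-union of two (x1, y1, x2, y2) boxes."""
    for box in (box_a, box_b):
        if box[2] <= box[0] or box[3] <= box[1]:
            raise ValueError(f"degenerate box {box}")
    ix1, iy1 = max(box_a[0], box_b[0]), max(box_a[1], box_b[1])
    ix2, iy2 = min(box_a[2], box_b[2]), min(box_a[3], box_b[3])
    iw, ih = max(0.0, ix2 - ix1), max(0.0, iy2 - iy1)
    inter = iw * ih
    area_a = (box_a[2] - box_a[0]) * (box_a[3] - box_a[1])
    area_b = (box_b[2] - box_b[0]) * (box_b[3] - box_b[1])
    union = area_a + area_b - inter
    return inter / union if union > 0 else 0.0


def match_detections(dets, gts, iou_thr: float = 0.5, similarity=iou):
    """Greedy confidence-ranked matching of detections to ground truths.

    ``dets`` is a list of ``(box, confidence)``. Each detection, in
    descending confidence, claims the highest-similarity unmatched ground
    truth with similarity >= threshold. Returns ``(flags, n_fn)`` where
    ``flags`` is the per-detection True (TP) / False (FP) list in ranked
    order and ``n_fn`` the count of unmatched ground truths.
    """
    order = sorted(range(len(dets)), key=lambda i: -dets[i][1])
    matched_gt: set[int] = set()
    flags = []
    for i in order:
        box = dets[i][0]
        best_j, best_s = -1, iou_thr
        for j, gt in enumerate(gts):
            if j in matched_gt:
                continue
            s = similarity(box, gt)
            if s >= best_s:
                best_s, best_j = s, j
        if best_j >= 0:
            matched_gt.add(best_j)
            flags.append(True)
        else:
            flags.append(False)
    return flags, len(gts) - len(matched_gt)


def pr_ap(flags, n_gt: int) -> DetEval:
    """Precision/recall/AP from a confidence-ranked TP/FP flag list.

    AP is the area under the monotone non-increasing precision envelope
    across recall (all-points interpolation of the P(R) integral). With no
    ground truth, recall and AP are undefined: AP is reported as None.
    """
    if n_gt < 0:
        raise ValueError("n_gt must be >= 0")
    flags = [bool(f) for f in flags]
    tp = sum(flags)
    fp = len(flags) - tp
    fn = n_gt - tp
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    recall = tp / n_gt if n_gt > 0 else 0.0
    if n_gt == 0:
        return DetEval(tp, fp, fn, precision, recall, None)
    cum_tp = np.cumsum(flags)
    ranks = np.arange(1, len(flags) + 1)
    prec = cum_tp / ranks if len(flags) else np.array([])
    rec = cum_tp / n_gt if len(flags) else np.array([])
    # monotone envelope over an appended (recall 0, precision of first rank)
    ap = 0.0
    if len(flags):
        env = np.maximum.accumulate(prec[::-1])[::-1]
        prev_r = 0.0
        for r, p in zip(rec, env):
            ap += (r - prev_r) * p
            prev_r = r
    return DetEval(int(tp), int(fp), int(fn), float(precision), float(recall), float(ap))


def pck_curve(errors_mm, t_max: float, step: float = 0.5) -> PCKCurve:
    """PCK@t over the grid t = 0, step, ..., t_max with strict inequality
    (d_i < t), so PCK@0 is always 0."""
    errors = np.asarray(errors_mm, dtype=float)
    if errors.size == 0:
        raise ValueError("PCK needs at least one error value")
    if np.any(errors < 0):
        raise ValueError("errors must be >= 0")
    if step <= 0:
        raise ValueError("step must be positive")
    n_steps = int(round(t_max / step))
    thresholds = np.arange(n_steps + 1) * step
    values = (errors[None, :] < thresholds[:, None]).mean(axis=1)
    return PCKCurve(thresholds=thresholds, values=values, errors=errors)


def oks_score(d_mm: float, s_mm: float, k: float = DEFAULT_OKS_K) -> float:
    """Object keypoint similarity exp(-d^2 / (2 s^2 k^2))."""
    if s_mm <= 0 or k <= 0:
        raise ValueError("object scale s and factor k must be positive")
    if d_mm < 0:
        raise ValueError("error distance must be >= 0")
    return float(np.exp(-(d_mm**2) / (2.0 * s_mm**2 * k**2)))


def oks_set(pred_points, gt_points, s_mm: float, k: float = DEFAULT_OKS_K) -> float:
    """Mean OKS over corresponding points of one predicted/true keypoint set."""
    pred = np.asarray(pred_points, dtype=float)
    gt = np.asarray(gt_points, dtype=float)
    if pred.shape != gt.shape:
        raise ValueError("prediction and ground truth shapes differ")
    d = np.linalg.norm(pred - gt, axis=-1)
    return float(np.mean([oks_score(di, s_mm, k) for di in np.atleast_1d(d)]))


def keypoint_pr(pred_sets, gt_sets, s_mm: float, k: float = DEFAULT_OKS_K,
                oks_thr: float = 0.5) -> DetEval:
    """Keypoint-set detection metrics with mean OKS replacing IoU.

    ``pred_sets`` is a list of ``(points, confidence)``; a prediction is a
    TP when its mean OKS against an unmatched ground-truth set reaches the
    threshold.
    """
    sim = lambda pred, gt: oks_set(pred, gt, s_mm, k)  # noqa: E731
    flags, _ = match_detections(pred_sets, gt_sets, iou_thr=oks_thr, similarity=sim)
    return pr_ap(flags, len(gt_sets))
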