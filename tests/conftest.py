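import numpy as np
import pytest

from budpose3d.annotations import BudAnnotation, Keypoint2D, N_KEYPOINTS
from budpose3d.localize3d import CameraIntrinsics


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def K():
    return CameraIntrinsics(fx=600.0, fy=600.0, cx=320.0, cy=240.0,
                            width=640, height=480)


def random_annotation(rng, image_size=(640, 640), n_buds=1):
    """Random buds with keypoints inside their own (disjoint-ish) boxes."""
    w, h = image_size
    anns = []
    for b in range(n_buds):
        bw = rng.uniform(0.1, 0.4)
        bh = rng.uniform(0.1, 0.4)
        xc = rng.uniform(bw / 2, 1 - bw / 2)
        yc = rng.uniform(bh / 2, 1 - bh / 2)
        kps = []
        for i in range(N_KEYPOINTS):
            u = rng.uniform((xc - bw / 2) * w + 1, (xc + bw / 2) * w - 1)
            v = rng.uniform((yc - bh / 2) * h + 1, (yc + bh / 2) * h - 1)
            vis = int(rng.integers(0, 3))
            kps.append(Keypoint2D(u=u, v=v, visibility=vis, index=i))
        anns.append(BudAnnotation(bbox=(xc, yc, bw, bh), keypoints=kps,
                                  image_size=image_size))
    return anns


def labelme_json_for(anns):
    """Build a Labelme-dialect document matching the given annotations."""
    import json

    shapes = []
    for ann in anns:
        w, h = ann.image_size
        xc, yc, bw, bh = ann.bbox
        x1, y1 = (xc - bw / 2) * w, (yc - bh / 2) * h
        x2, y2 = (xc + bw / 2) * w, (yc + bh / 2) * h
        shapes.append({"label": "bud", "shape_type": "rectangle",
                       "points": [[x1, y1], [x2, y2]], "flags": {}})
        for kp in ann.keypoints:
            shapes.append({"label": f"kp{kp.index + 1}", "shape_type": "point",
                           "points": [[kp.u, kp.v]],
                           "flags": {"visibility": kp.visibility}})
    return json.dumps({"shapes": shapes,
                       "imageWidth": anns[0].image_size[0],
                       "imageHeight": anns[0].image_size[1]})
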