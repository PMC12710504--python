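"""Label-synchronized augmentation on a synthetic image.

Rotates an image 90 degrees and shows the keypoint moving with the pixels,
then occludes it with a black patch and shows the visibility downgrade
(visible -> occluded) that keeps training labels honest.
"""

import numpy as np

from budpose3d import AugmentSpec, apply_geometric, apply_occlusion
from budpose3d.annotations import BudAnnotation, Keypoint2D

rng = np.random.default_rng(7)
image = rng.integers(0, 256, size=(640, 640, 3), dtype=np.uint8)
kps = [Keypoint2D(u=10.0 + 5 * i, v=20.0 + 5 * i, visibility=2, index=i)
       for i in range(8)]
anns = [BudAnnotation(bbox=(0.1, 0.1, 0.15, 0.15), keypoints=kps,
                      image_size=(640, 640))]

_, rotated = apply_geometric(image, anns, AugmentSpec("rotate", {"angle_deg": 90}))
kp = rotated[0].keypoints[0]
print(f"keypoint (10, 20) after a 90-degree rotation -> ({kp.u:.0f}, {kp.v:.0f})")
print("  (the label moved through exactly the same map as the pixels)")

_, occluded = apply_occlusion(image, anns,
                              AugmentSpec("occlusion", {"patches": [(0, 0, 60, 60)]}))
flags = [k.visibility for k in occluded[0].keypoints]
print(f"visibility flags after a patch over the first keypoints: {flags}")
print("  (2 = visible, 1 = occluded: covered points were downgraded, never upgraded)")
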