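"""Convert a Labelme-style bud annotation to YOLO-pose labels and back.

Builds one annotated bud (a box plus eight keypoints with visibility
flags), writes the YOLO-pose label line, re-reads it and shows the 7:2:1
dataset split on 5,000 synthetic item ids.
"""

import json

from budpose3d import parse_labelme, read_yolo_pose, split_dataset, write_yolo_pose

shapes = [{"label": "bud", "shape_type": "rectangle",
           "points": [[100, 100], [400, 500]], "flags": {}}]
for i in range(8):
    shapes.append({"label": f"kp{i + 1}", "shape_type": "point",
                   "points": [[150 + 30 * i, 200 + 25 * i]],
                   "flags": {"visibility": 2 if i < 7 else 1}})
doc = json.dumps({"shapes": shapes})

[bud] = parse_labelme(doc, image_size=(640, 640))
[line] = write_yolo_pose([bud])
print("YOLO-pose label line (class, bbox, then u v visibility x 8):")
print(" ", line)

[back] = read_yolo_pose([line], (640, 640))
drift = max(abs(a.u - b.u) + abs(a.v - b.v)
            for a, b in zip(bud.keypoints, back.keypoints))
print(f"round-trip pixel drift: {drift:.2e} px (6-decimal label precision)")

split = split_dataset(list(range(5000)), (0.7, 0.2, 0.1), seed=42)
print(f"5000 items split 7:2:1 -> train {len(split.train)}, "
      f"test {len(split.test)}, val {len(split.val)}")
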