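"""Gate a jittery pixel track, fuse its depth samples, deproject to 3D.

One tracked picking point over five frames: frame 3 jumps 13 px (a slipped
match) and is gated out, taking frame 4 with it; among the kept frames'
depth samples one reading bled through to the background, so the adaptive
rule switches from mean to median before back-projection.
"""

from budpose3d import CameraIntrinsics, DepthSampleSequence, deproject_pixel, fuse_depth
from budpose3d.tracking import KeypointTrack, gate_track

track = KeypointTrack([(0, 320.0, 240.0), (1, 321.0, 241.0), (2, 321.5, 240.5),
                       (3, 331.0, 250.0), (4, 321.0, 240.8)], window=5)
gated = gate_track(track, epsilon=3.0)
for f in gated.frames:
    delta = "  --" if f.delta is None else f"{f.delta:4.1f}"
    print(f"frame {f.frame_id}: delta {delta} px  -> {'kept' if f.kept else 'DROPPED'}")
print("  (a displacement above 3 px means the match slipped; its depth is discarded)")

samples = DepthSampleSequence(samples=[0.802, 1.950, 0.801], frame_ids=[0, 1, 2])
fused = fuse_depth(samples, strategy="adaptive", T=0.01)
print(f"\ndepth samples {samples.samples} m -> sigma {fused.sigma:.3f} m > T=0.01 m,"
      f" so {fused.strategy}: d_hat = {fused.d_hat:.3f} m")

K = CameraIntrinsics(fx=600, fy=600, cx=320, cy=240, width=640, height=480)
p = deproject_pixel(K, 321.5, 240.5, fused.d_hat)
x, y, z = p.to_mm()
print(f"picking point in the camera frame: ({x:.1f}, {y:.1f}, {z:.1f}) mm")
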