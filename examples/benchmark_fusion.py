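"""Four-strategy depth-fusion benchmark on a synthetic bud scene.

Simulates 200 picking points over 10-frame windows with 5 mm depth noise,
5% holes and 10% background outliers (+0.5-2 m), then compares
single-frame, mean, median and adaptive fusion on identical inputs.
"""

from budpose3d import NoiseSpec, SceneSpec, benchmark_strategies, default_intrinsics, make_scene, render_sequence

scene = make_scene(SceneSpec(n_buds=200, seed=42))
obs = render_sequence(scene, default_intrinsics(), NoiseSpec(seed=42), 10,
                      points="picking")
report = benchmark_strategies(scene, obs)

print(f"{report.n_points} picking points, {len(obs.frames)}-frame windows\n")
print(f"{'strategy':>10} {'RMSE (mm)':>12} {'PCK@5mm':>9} {'mean OKS':>9}")
for name, res in report.strategies.items():
    print(f"{name:>10} {res.rmse_mm:12.2f} {res.pck.at(5.0):9.2f} "
          f"{res.mean_oks:9.3f}")
print("\nRMSE is the 3D localization error against ground truth; PCK@5mm the")
print("fraction of points within 5 mm; OKS a scale-normalized similarity")
print("(1 = perfect). Outliers wreck the mean; the adaptive rule matches the")
print("mean on quiet windows and falls back to the median on corrupted ones.")
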