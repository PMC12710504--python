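import numpy as np
import pytest

from budpose3d.augment import (
    AugmentSpec,
    apply_geometric,
    apply_occlusion,
    apply_photometric,
    letterbox,
)
from conftest import random_annotation


@pytest.fixture
def image(rng):
    return rng.integers(0, 256, size=(640, 640, 3), dtype=np.uint8)


def annotations_equal(a, b, tol=1e-9):
    for ann_a, ann_b in zip(a, b):
        if not np.allclose(ann_a.bbox, ann_b.bbox, atol=tol):
            return False
        for kp_a, kp_b in zip(ann_a.keypoints, ann_b.keypoints):
            if abs(kp_a.u - kp_b.u) > tol or abs(kp_a.v - kp_b.v) > tol:
                return False
            if kp_a.visibility != kp_b.visibility:
                return False
    return len(a) == len(b)


class TestGeometric:
    def test_hflip_is_an_involution(self, image, rng):
        anns = random_annotation(rng)
        img1, ann1 = apply_geometric(image, anns, AugmentSpec("hflip"))
        img2, ann2 = apply_geometric(img1, ann1, AugmentSpec("hflip"))
        assert np.array_equal(img2, image)
        assert annotations_equal(ann2, anns, tol=1e-9)

    def test_rotate_90_maps_pixel_convention_exactly(self, image, rng):
        anns = random_annotation(rng)
        anns[0].keypoints[0].u = 10.0
        anns[0].keypoints[0].v = 20.0
        anns[0].keypoints[0].visibility = 2
        _, out = apply_geometric(image, anns, AugmentSpec("rotate", {"angle_deg": 90}))
        kp = out[0].keypoints[0]
        assert (kp.u, kp.v) == pytest.approx((619.0, 10.0), abs=1e-9)

    def test_rotation_matches_hand_applied_matrix(self, image, rng):
        import math
        anns = random_annotation(rng)
        angle = 30.0
        _, out = apply_geometric(image, anns, AugmentSpec("rotate", {"angle_deg": angle}))
        th = math.radians(angle)
        c = (640 - 1) / 2.0
        for kp_in, kp_out in zip(anns[0].keypoints, out[0].keypoints):
            du, dv = kp_in.u - c, kp_in.v - c
            exp_u = c + math.cos(th) * du - math.sin(th) * dv
            exp_v = c + math.sin(th) * du + math.cos(th) * dv
            assert (kp_out.u, kp_out.v) == pytest.approx((exp_u, exp_v), abs=1e-9)

    def test_keypoint_leaving_canvas_becomes_invisible(self, image, rng):
        anns = random_annotation(rng)
        anns[0].keypoints[0].u = 635.0
        anns[0].keypoints[0].v = 5.0
        anns[0].keypoints[0].visibility = 2
        _, out = apply_geometric(image, anns, AugmentSpec("rotate", {"angle_deg": 30}))
        assert out[0].keypoints[0].visibility == 0

    def test_photometric_kind_rejected(self, image, rng):
        with pytest.raises(ValueError, match="not a geometric"):
            apply_geometric(image, random_annotation(rng), AugmentSpec("fog"))

    @pytest.mark.parametrize("spec", [
        AugmentSpec("hflip"), AugmentSpec("vflip"),
        AugmentSpec("rotate", {"angle_deg": 90}),
        AugmentSpec("rotate", {"angle_deg": 180}),
    ])
    def test_label_synchronization_with_rasterized_markers(self, rng, spec):
        """Transforming keypoints matches transforming a marker image."""
        anns = random_annotation(rng)
        marker = np.zeros((640, 640), dtype=np.uint8)
        for kp in anns[0].keypoints:
            marker[int(round(kp.v)), int(round(kp.u))] = 255
        marker_t, anns_t = apply_geometric(marker, anns, spec)
        for kp in anns_t[0].keypoints:
            r, c = int(round(kp.v)), int(round(kp.u))
            window = marker_t[max(0, r - 1):r + 2, max(0, c - 1):c + 2]
            assert window.max() == 255  # marker within 1 px of mapped keypoint


class TestPhotometric:
    def test_zero_brightness_delta_is_identity(self, image, rng):
        anns = random_annotation(rng)
        out, anns_out = apply_photometric(image, anns, AugmentSpec("brightness", {"delta": 0}))
        assert np.array_equal(out, image)
        assert anns_out is anns

    def test_gauss_noise_deterministic_for_fixed_seed(self, image, rng):
        spec = AugmentSpec("gauss_noise", {"sigma": 10.0}, seed=99)
        out1, _ = apply_photometric(image, [], spec)
        out2, _ = apply_photometric(image, [], spec)
        assert np.array_equal(out1, out2)

    def test_full_fog_replaces_every_pixel(self, image):
        out, _ = apply_photometric(image, [], AugmentSpec("fog", {"opacity": 1.0, "color": 200}))
        assert np.all(out == 200)

    def test_annotations_pass_through_unchanged(self, image, rng):
        anns = random_annotation(rng)
        for kind in ("brightness", "exposure", "gauss_noise", "gauss_blur", "rain", "fog"):
            _, out = apply_photometric(image, anns, AugmentSpec(kind, seed=1))
            assert out is anns

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError, match="sigma"):
            AugmentSpec("gauss_noise", {"sigma": -1.0})

    def test_fog_opacity_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="opacity"):
            AugmentSpec("fog", {"opacity": 1.5})

    def test_rain_adds_streaks_and_is_seeded(self, image):
        spec = AugmentSpec("rain", {"n_streaks": 40}, seed=5)
        out1, _ = apply_photometric(image, [], spec)
        out2, _ = apply_photometric(image, [], spec)
        assert np.array_equal(out1, out2)
        assert not np.array_equal(out1, image)


class TestOcclusion:
    def test_patch_missing_keypoints_leaves_labels_alone(self, image, rng):
        anns = random_annotation(rng)
        for kp in anns[0].keypoints:  # push everything away from the patch
            kp.u, kp.v = 500.0 + kp.index, 500.0
        out_img, out = apply_occlusion(image, anns,
                                       AugmentSpec("occlusion", {"patches": [(0, 0, 50, 50)]}))
        assert np.all(out_img[:50, :50] == 0)
        assert [kp.visibility for kp in out[0].keypoints] == \
            [kp.visibility for kp in anns[0].keypoints]

    def test_covered_visible_keypoint_downgraded_to_occluded(self, image, rng):
        anns = random_annotation(rng)
        anns[0].keypoints[2].u, anns[0].keypoints[2].v = 25.0, 25.0
        anns[0].keypoints[2].visibility = 2
        _, out = apply_occlusion(image, anns,
                                 AugmentSpec("occlusion", {"patches": [(0, 0, 50, 50)]}))
        assert out[0].keypoints[2].visibility == 1

    def test_invisible_keypoint_stays_invisible(self, image, rng):
        anns = random_annotation(rng)
        anns[0].keypoints[3].u, anns[0].keypoints[3].v = 25.0, 25.0
        anns[0].keypoints[3].visibility = 0
        _, out = apply_occlusion(image, anns,
                                 AugmentSpec("occlusion", {"patches": [(0, 0, 50, 50)]}))
        assert out[0].keypoints[3].visibility == 0

    def test_zero_area_patch_rejected(self, image):
        with pytest.raises(ValueError, match="zero-area"):
            apply_occlusion(image, [], AugmentSpec("occlusion", {"patches": [(10, 10, 10, 30)]}))

    def test_visibility_never_increases(self, image, rng):
        for seed in range(10):
            anns = random_annotation(rng)
            _, out = apply_occlusion(image, anns, AugmentSpec("occlusion", seed=seed))
            for kp_in, kp_out in zip(anns[0].keypoints, out[0].keypoints):
                assert kp_out.visibility <= kp_in.visibility


class TestLetterbox:
    def test_square_input_is_identity(self, image, rng):
        anns = random_annotation(rng)
        out, anns_out, mapping = letterbox(image, anns, (640, 640))
        assert mapping.scale == 1.0 and mapping.pad == (0.0, 0.0)
        assert np.array_equal(out, image)

    def test_wide_image_scale_and_padding(self, rng):
        img = rng.integers(0, 256, size=(720, 1280, 3), dtype=np.uint8)
        _, _, mapping = letterbox(img, [], (640, 640))
        assert mapping.scale == 0.5
        assert mapping.pad == (0.0, 140.0)
        assert mapping.map(640, 360) == (320.0, 320.0)

    def test_map_unmap_roundtrip(self, rng):
        img = rng.integers(0, 256, size=(720, 1280, 3), dtype=np.uint8)
        _, _, mapping = letterbox(img, [], (640, 640))
        pts = rng.uniform(0, 1280, size=(100, 2))
        for u, v in pts:
            u2, v2 = mapping.unmap(*mapping.map(u, v))
            assert abs(u2 - u) < 1e-9 and abs(v2 - v) < 1e-9

    def test_empty_image_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            letterbox(np.zeros((0, 0, 3)), [], (640, 640))
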