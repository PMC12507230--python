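"""Ring-profile arm detection: geometry, profiles, circular peaks."""

import numpy as np
import pytest

from octoplume import arms
from octoplume import synthetic as syn
from octoplume.angles import wrap_deg


class TestBins:
    def test_bin_angle_roundtrip(self):
        b = np.arange(arms.N_BINS)
        assert np.array_equal(arms.angle_to_bin(arms.bin_center_deg(b)), b)

    def test_bin_width(self):
        assert arms.BIN_WIDTH_DEG == pytest.approx(3.6)
        assert arms.bin_center_deg(0) == pytest.approx(1.8)


class TestDynamicBackground:
    def make_blob_video(self, n=30, drift=0.0):
        rng = np.random.default_rng(0)
        H, W = 40, 700
        frames = np.zeros((n, H, W), dtype=float)
        centers = np.zeros((n, 2))
        for i in range(n):
            frames[i] += 10.0 + drift * i
            x = 30 if i % 2 == 0 else 670  # alternate far-apart positions
            frames[i, 15:25, x - 5 : x + 5] += 100.0
            centers[i] = (x, 20)
        return frames, centers

    def test_moving_blob_isolated(self):
        frames, centers = self.make_blob_video()
        bg = arms.dynamic_background(frames, centers, min_dist_px=600, k=5)
        sub = arms.subtract_background(frames, bg)
        # the blob survives; the static background cancels
        assert sub[0].max() == pytest.approx(100.0)
        assert sub[0, :, 100:600].max() == pytest.approx(0.0)

    def test_static_animal_has_no_background_material(self):
        frames = np.zeros((5, 10, 10))
        centers = np.tile([(5.0, 5.0)], (5, 1))
        with pytest.raises(ValueError, match="no frames"):
            arms.dynamic_background(frames, centers, min_dist_px=600)

    def test_tracks_brightness_drift_better_than_global_mean(self):
        frames, centers = self.make_blob_video(drift=1.0)
        bg = arms.dynamic_background(frames, centers, min_dist_px=600, k=4)
        global_mean = frames.mean(axis=0)
        resid_dyn = np.abs(bg[:, :, 200:400] - frames[:, :, 200:400]).mean()
        resid_glob = np.abs(global_mean[None, :, 200:400] - frames[:, :, 200:400]).mean()
        assert resid_dyn < resid_glob

    def test_lazy_stack_matches_eager_path(self):
        frames, centers = self.make_blob_video()
        bg = arms.dynamic_background(frames, centers, min_dist_px=600, k=10)
        eager = arms.subtract_background(frames, bg)
        lazy = arms.BackgroundSubtractedStack(frames, centers, min_dist_px=600, k=10)
        assert len(lazy) == len(frames)
        for i in (0, 7, 29):
            assert np.allclose(lazy[i], eager[i])


class TestCropAndRotate:
    def test_axis_already_down_is_near_identity(self):
        rng = np.random.default_rng(0)
        img = rng.random((200, 200)) * 0.0
        img[60:140, 90:110] = 1.0
        # body axis -90 deg maps to itself
        out = arms.crop_and_rotate(img, (100.0, 100.0), -90.0, size=200)
        inner = (slice(40, 160), slice(40, 160))
        assert np.allclose(out[inner], img[inner], atol=1e-6)

    def test_eye_positions_map_to_horizontal(self, scene, stationary_truth):
        """After standardization the recomputed axis points down the image."""
        truth = stationary_truth
        eyeL, eyeR, _ = truth.eye_mantle_geometry()
        center = truth.true_center_cm[0] * scene.px_per_cm
        axis_deg = truth.true_body_axis_deg[0]
        half = 150.0
        delta = np.deg2rad(axis_deg + 90.0)
        rot = np.array(
            [[np.cos(-delta), -np.sin(-delta)], [np.sin(-delta), np.cos(-delta)]]
        )
        for eye in (eyeL[0], eyeR[0]):
            p = rot @ (eye * scene.px_per_cm - center) + half
            # eyes end up on the horizontal line through the center
            assert p[1] == pytest.approx(half, abs=1e-6)

    def test_global_scene_rotation_equivariance(self, scene):
        """Rotating animal and axis together leaves the crop unchanged."""
        outs = []
        for axis in (20.0, 110.0):
            truth = syn.simulate_motion(
                "stationary",
                duration_s=0.1,
                seed=3,
                scene=scene,
                params={"arm_jitter_deg": 0.0, "body_axis_deg": axis},
            )
            frame = syn.render_octopus_frames(
                scene, truth, noise_amplitude=0.0, texture_amplitude=0.0
            )[0]
            c = truth.true_center_cm[0] * scene.px_per_cm
            outs.append(arms.crop_and_rotate(frame.astype(float), c, axis, size=260))
        inner = (slice(30, 230), slice(30, 230))
        diff = np.abs(outs[0][inner] - outs[1][inner])
        assert diff.mean() < 1.5  # interpolation tolerance on 0..255 images


class TestAverageAndGeometry:
    def test_single_image_normalized_to_unit_max(self):
        img = np.zeros((50, 50))
        img[25, 25] = 4.0
        avg = arms.average_body_image(img)
        assert avg.max() == pytest.approx(1.0)
        assert avg[25, 25] == 1.0

    def test_repeated_image_equals_single(self):
        rng = np.random.default_rng(4)
        img = rng.random((30, 30))
        single = arms.average_body_image(img)
        stacked = arms.average_body_image(np.stack([img] * 7))
        assert np.allclose(single, stacked)

    def test_all_zero_stack_raises(self):
        with pytest.raises(ValueError):
            arms.average_body_image(np.zeros((3, 10, 10)))

    def test_gaussian_blob_gives_square_rect_and_half_diagonal_circle(self):
        n = 201
        yy, xx = np.mgrid[:n, :n] - n // 2
        img = np.exp(-0.5 * (xx**2 + yy**2) / 20.0**2)
        geom = arms.fit_bounding_geometry(img, mask_threshold="none")
        assert geom.half_width_px == pytest.approx(geom.top_px, abs=2)
        assert geom.half_width_px == pytest.approx(geom.bottom_px, abs=2)
        assert geom.radius_px == pytest.approx(
            np.hypot(geom.half_width_px, max(geom.top_px, geom.bottom_px)), abs=1e-9
        )

    def test_full_fraction_covers_support(self):
        img = np.zeros((41, 41))
        img[15:26, 12:29] = 1.0
        geom = arms.fit_bounding_geometry(img, intensity_fraction=1.0, mask_threshold="none")
        enclosed = img[
            20 - int(geom.top_px) : 20 + int(geom.bottom_px) + 1,
            20 - int(geom.half_width_px) : 20 + int(geom.half_width_px) + 1,
        ].sum()
        assert enclosed == pytest.approx(img.sum())

    def test_stopping_rule_encloses_requested_fraction(self, rendered_frame):
        geom = rendered_frame["geom"]
        assert geom.intensity_fraction == 0.95
        # the fitted rectangle must not be trivially the whole crop
        assert geom.radius_px < 150


class TestRingProfile:
    def test_uniform_image_flat_profile(self):
        img = np.full((100, 100), 3.0)
        prof = arms.ring_profile(img, arms.BodyGeometry(20, 20, 20, 30.0))
        assert np.allclose(prof.bin_means, 3.0)

    def test_single_ray_hits_expected_bin(self):
        img = np.zeros((201, 201))
        geom = arms.BodyGeometry(30, 30, 30, 45.0)
        for ray_deg, want_bin in ((45.0, 12), (45.0 + 3.6, 13)):
            d = arms.standardized_direction(ray_deg)
            for r in np.linspace(5, 90, 300):
                x, y = 100.5 + r * d[0], 100.5 + r * d[1]
                img[int(round(y)), int(round(x))] = 100.0
            prof = arms.ring_profile(img, geom)
            assert int(np.argmax(prof.bin_means)) == want_bin
            img[:] = 0.0

    def test_small_radius_rejected(self):
        with pytest.raises(ValueError):
            arms.ring_profile(np.zeros((50, 50)), arms.BodyGeometry(5, 5, 5, 3.0))


class TestPeakDetection:
    def test_flat_profile_no_peaks(self):
        prof = arms.ArmProfile(bin_means=np.full(100, 2.0))
        assert arms.detect_arm_peaks(prof).size == 0

    def test_eight_arm_render_recovers_all(self, rendered_frame, stationary_truth):
        prof = arms.ring_profile(rendered_frame["std"], rendered_frame["geom"])
        peaks = arms.detect_arm_peaks(prof)
        assert peaks.size == 8
        got = np.sort(wrap_deg(arms.bin_center_deg(peaks)))
        want = np.sort(stationary_truth.true_arm_angles_deg[0])
        assert np.abs(got - want).max() <= arms.BIN_WIDTH_DEG

    def test_wraparound_peak_at_bin_zero_found_once(self):
        x = np.arange(100)
        d = np.minimum(x, 100 - x)  # circular distance to bin 0
        prof = arms.ArmProfile(bin_means=10.0 * np.exp(-0.5 * (d / 1.5) ** 2))
        peaks = arms.detect_arm_peaks(prof)
        assert peaks.tolist() == [0]


class TestHeadingArmOffsets:
    def test_arm_along_heading(self):
        # bin 24 center = 88.2 deg from axis; axis 0, heading 88.2
        offsets, nearest = arms.heading_arm_offsets(np.array([24]), 0.0, 88.2)
        assert nearest == pytest.approx(0.0, abs=1e-9)

    def test_nearest_is_smallest_magnitude(self):
        # arms at bin centers 77.4 and 131.4 deg; heading 87.4 deg puts
        # them at -10 and +44: the smaller magnitude wins
        offsets, nearest = arms.heading_arm_offsets(np.array([21, 36]), 0.0, 87.4)
        assert nearest == pytest.approx(-10.0, abs=1e-9)

    def test_exact_tie_breaks_positive(self):
        # arms at bin centers 88.2 and 106.2 deg; heading 97.2 puts them
        # at exactly -9 and +9: the tie goes to the positive offset
        offsets, nearest = arms.heading_arm_offsets(np.array([24, 29]), 0.0, 97.2)
        assert nearest == pytest.approx(+9.0, abs=1e-9)

    def test_no_peaks_or_heading_undefined(self):
        _, nearest = arms.heading_arm_offsets(np.array([], dtype=int), 0.0, 10.0)
        assert np.isnan(nearest)
        _, nearest = arms.heading_arm_offsets(np.array([3]), 0.0, np.nan)
        assert np.isnan(nearest)


def test_rotational_equivariance_of_bin_means(scene):
    """Rotating the scene and the axis together leaves the profile fixed."""
    profiles = []
    for axis in (0.0, 135.0):
        truth = syn.simulate_motion(
            "stationary",
            duration_s=0.1,
            seed=3,
            scene=scene,
            params={"arm_jitter_deg": 0.0, "body_axis_deg": axis},
        )
        frame = syn.render_octopus_frames(
            scene, truth, noise_amplitude=0.0, texture_amplitude=0.0
        )[0]
        c = truth.true_center_cm[0] * scene.px_per_cm
        std = arms.crop_and_rotate(frame.astype(float), c, axis, size=300)
        geom = arms.fit_bounding_geometry(arms.average_body_image(std))
        profiles.append(arms.ring_profile(std, geom).bin_means)
    assert np.abs(profiles[0] - profiles[1]).max() < 5.0  # of ~90 peak amplitude
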