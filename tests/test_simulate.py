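"""Simulator: texture generation, rendering, motion model, overlap stats."""

import numpy as np
import pytest
from dataclasses import replace

from pearlring import focus, simulate as sim


class TestGenerateTexture:
    def test_deterministic_for_fixed_seed(self):
        t1 = sim.generate_texture(texture_resolution=512, seed=5)
        t2 = sim.generate_texture(texture_resolution=512, seed=5)
        assert np.array_equal(t1.texture, t2.texture)
        t3 = sim.generate_texture(texture_resolution=512, seed=6)
        assert not np.array_equal(t1.texture, t3.texture)

    def test_zero_densities_give_uniform_background(self):
        params = {
            name: {**p, "density_per_mm2": 0.0}
            for name, p in sim.DEFAULT_FEATURE_PARAMS.items()
        }
        gt = sim.generate_texture(
            feature_params=params,
            texture_resolution=512,
            seed=1,
            background_noise=0.0,
        )
        assert np.all(gt.texture == gt.texture[0, 0])

    def test_full_circumference_stripe_spans_all_longitudes(self):
        circ = 2 * np.pi * 1.0
        params = {
            "stripe": {
                "density_per_mm2": 0.3,
                "size_mm": (circ, None),
                "width_mm": 0.03,
                "contrast": 60.0,
            }
        }
        gt = sim.generate_texture(
            feature_params=params,
            texture_resolution=512,
            seed=2,
            semi_axes=(1.0, 1.0),
            background_noise=0.0,
        )
        off_background = gt.texture != gt.texture[0, 0]
        rows_fully_covered = off_background.all(axis=1)
        assert rows_fully_covered.any()

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            sim.generate_texture(texture_resolution=128)
        with pytest.raises(ValueError):
            sim.generate_texture(
                feature_params={
                    "stain": {"density_per_mm2": 1.0, "size_mm": (0.0, 0.1),
                              "contrast": 10.0}
                },
                texture_resolution=512,
            )

    def test_seamless_at_longitude_wrap(self):
        gt = sim.generate_texture(texture_resolution=512, seed=9)
        left = gt.texture[:, 0].astype(float)
        right = gt.texture[:, -1].astype(float)
        # wrap-continuous: adjacent columns across the seam stay close
        assert np.mean(np.abs(left - right)) < 3 * np.mean(
            np.abs(np.diff(gt.texture.astype(float), axis=1))
        )


class TestRenderView:
    def test_uniform_texture_renders_constant_footprint(self, optics):
        gt = sim.SphereGroundTruth(
            semi_axes=(1.0, 1.0), texture=np.full((256, 512), 90, dtype=np.uint8)
        )
        from pearlring import geometry as geo

        pose = geo.build_ring_poses(
            [0.0], 1.0, optics.resolved_working_distance, optics
        )[0]
        img = sim.render_view(gt, pose, optics)
        assert np.all(img == 90)

    def test_blur_scale_zero_removes_focus_dependence(self, small_texture, optics):
        from pearlring import geometry as geo

        o = replace(optics, blur_scale=0.0)
        pose = geo.build_ring_poses([0.0], 1.0, o.resolved_working_distance, o)[0]
        wd = o.resolved_working_distance
        img1 = sim.render_view(small_texture, pose, o, focus_depth=wd)
        img2 = sim.render_view(small_texture, pose, o, focus_depth=wd + 0.5)
        assert np.array_equal(img1, img2)

    def test_in_focus_render_scores_sharper_than_defocused(
        self, small_texture, optics
    ):
        from pearlring import geometry as geo

        pose = geo.build_ring_poses(
            [0.0], 1.0, optics.resolved_working_distance, optics
        )[0]
        wd = optics.resolved_working_distance
        sharp = sim.render_view(small_texture, pose, optics, focus_depth=wd)
        blurred = sim.render_view(
            small_texture, pose, optics, focus_depth=wd + 3 * optics.dof_half_width
        )
        h, w = sharp.shape
        crop = (slice(h // 3, 2 * h // 3), slice(w // 3, 2 * w // 3))
        assert (
            focus.focus_measure_gras(sharp[crop]).value
            > focus.focus_measure_gras(blurred[crop]).value
        )

    def test_pose_missing_sphere_is_an_error(self, small_texture, optics):
        from pearlring import geometry as geo

        pose = geo.build_ring_poses(
            [0.0], 1.0, optics.resolved_working_distance, optics
        )[0]
        away = geo.CameraPose(
            center=pose.center,
            rotation=geo.ring_rotation_matrix(np.pi),  # looking away
            focal_length=pose.focal_length,
            pixel_pitch=pose.pixel_pitch,
            principal_point=pose.principal_point,
        )
        with pytest.raises(ValueError):
            sim.render_view(small_texture, away, optics)

    def test_illumination_gradient_darkens_one_side(self, optics):
        gt = sim.SphereGroundTruth(
            semi_axes=(1.0, 1.0), texture=np.full((256, 512), 200, dtype=np.uint8)
        )
        from pearlring import geometry as geo

        lit = replace(optics, illumination_gradient=0.4, blur_scale=0.0)
        pose = geo.build_ring_poses(
            [0.0], 1.0, lit.resolved_working_distance, lit
        )[0]
        img = sim.render_view(gt, pose, lit)
        assert img[:, :32].mean() > img[:, -32:].mean() + 20

    def test_center_crop_fraction(self):
        img = np.arange(100, dtype=np.uint8).reshape(10, 10)
        assert sim.center_crop(img, 1.0) is img
        cropped = sim.center_crop(img, 0.5)
        assert cropped.shape == (5, 5)
        assert cropped[0, 0] == img[2, 2]
        with pytest.raises(ValueError):
            sim.center_crop(img, 0.0)

    def test_on_object_pixel_scale_matches_fov_formula(self, optics):
        """A tangent-plane segment of one FOV width spans the sensor."""
        from pearlring import geometry as geo

        wd = optics.resolved_working_distance
        pose = geo.build_ring_poses([0.0], 1.0, wd, optics)[0]
        fov_w = optics.fov_mm[0]
        tangent_point = np.array([1.0, 0.0, 0.0])
        travel = np.array([0.0, 1.0, 0.0])
        ends = np.vstack(
            [tangent_point - 0.5 * fov_w * travel, tangent_point + 0.5 * fov_w * travel]
        )
        uv = pose.project(ends)
        width_px = abs(uv[1, 0] - uv[0, 0])
        assert abs(width_px - optics.sensor_px[0]) <= 1.0


class TestSimulateRing:
    def test_noiseless_uniform_steps_give_exact_angles(self, small_texture, optics):
        o = replace(optics, sensor_px=(64, 64))
        n = 8
        circumference = 2 * np.pi * 1.0
        motion = sim.MotionModel(
            efficiency=1.0,
            step_mm=circumference / n,
            arc_noise_sd=0.0,
            lateral_sd=0.0,
        )
        _z, _p, manifest = sim.simulate_ring(
            small_texture, o, motion, n_frames=n + 1, z_plan=(0.0,), seed=0
        )
        angles = np.array(manifest["true_angles_deg"])
        expected = np.arange(n + 1) * 360.0 / n
        assert np.allclose(angles, expected, atol=1e-9)

    def test_commanded_32mm_rolls_one_full_ring_of_8mm_pearl(self, optics):
        """~32 mm commanded at ~0.785 efficiency closes the ring of an 8 mm
        sphere (circumference 25 mm to the millimetre)."""
        gt = sim.SphereGroundTruth(
            semi_axes=(4.0, 4.0), texture=np.full((256, 512), 100, np.uint8)
        )
        o = replace(optics, sensor_px=(32, 32))
        n = 9  # 8 steps of 4 mm = 32 mm commanded
        motion = sim.MotionModel(step_mm=4.0, arc_noise_sd=0.0, lateral_sd=0.0)
        _z, _p, manifest = sim.simulate_ring(
            gt, o, motion, n_frames=n, z_plan=(0.0,), seed=0
        )
        total = manifest["true_angles_deg"][-1]
        assert total == pytest.approx(360.0, abs=1.0)
        assert round(32.0 * motion.efficiency) == 25  # circumference, mm

    def test_circumference_consistency(self, optics):
        """Commanded total T at efficiency eta spans T*eta/R radians."""
        gt = sim.SphereGroundTruth(
            semi_axes=(2.0, 2.0), texture=np.full((256, 512), 100, np.uint8)
        )
        o = replace(optics, sensor_px=(32, 32))
        motion = sim.MotionModel(
            efficiency=0.9, step_mm=0.5, arc_noise_sd=0.0, lateral_sd=0.0
        )
        n = 7
        _z, _p, manifest = sim.simulate_ring(
            gt, o, motion, n_frames=n, z_plan=(0.0,), seed=0
        )
        expected = np.rad2deg((n - 1) * 0.5 * 0.9 / 2.0)
        assert manifest["true_angles_deg"][-1] == pytest.approx(
            expected, rel=1e-9
        )

    def test_determinism_and_seed_sensitivity(self, small_texture, optics):
        o = replace(optics, sensor_px=(64, 64))
        motion = sim.MotionModel(seed=4)
        za, _pa, ma = sim.simulate_ring(
            small_texture, o, motion, n_frames=3, z_plan=(0.0, 0.02), seed=4
        )
        zb, _pb, mb = sim.simulate_ring(
            small_texture, o, motion, n_frames=3, z_plan=(0.0, 0.02), seed=4
        )
        assert ma == mb
        for sa, sb in zip(za, zb):
            for fa, fb in zip(sa.frames, sb.frames):
                assert np.array_equal(fa, fb)
        _zc, _pc, mc = sim.simulate_ring(
            small_texture, o, motion, n_frames=3, z_plan=(0.0, 0.02), seed=5
        )
        assert mc["true_angles_deg"] != ma["true_angles_deg"]

    def test_overfull_ring_warns_but_does_not_fail(self, optics):
        gt = sim.SphereGroundTruth(
            semi_axes=(0.5, 0.5), texture=np.full((256, 512), 100, np.uint8)
        )
        o = replace(optics, sensor_px=(32, 32))
        motion = sim.MotionModel(step_mm=1.0, arc_noise_sd=0.0, lateral_sd=0.0)
        with pytest.warns(UserWarning, match="full ring"):
            _z, _p, manifest = sim.simulate_ring(
                gt, o, motion, n_frames=6, z_plan=(0.0,), seed=0
            )
        assert manifest["warnings"]

    def test_lateral_noise_produces_vertical_shifts(self, noisy_consecutive_dy):
        assert abs(noisy_consecutive_dy) > 0.25


@pytest.fixture(scope="session")
def noisy_consecutive_dy(small_texture, optics):
    """Median |dy| between consecutive frames of a ring with lateral slip."""
    from pearlring import match as m

    motion = sim.MotionModel(
        step_mm=0.36, arc_noise_sd=0.0, lateral_sd=0.02, seed=12
    )
    zstacks, _p, _m = sim.simulate_ring(
        small_texture, optics, motion, n_frames=4, z_plan=(0.0,), seed=12
    )
    dys = []
    for i in range(3):
        mset = m.detect_and_match(zstacks[i].frames[0], zstacks[i + 1].frames[0])
        est = m.estimate_shift(mset)
        dys.append(est.dy)
    return float(np.median(np.abs(dys)))


class TestOverlapStats:
    def test_uniform_steps_at_32_percent_of_fov(self, optics):
        fov_w = optics.fov_mm[0]
        radius = 4.15
        step_deg = np.rad2deg(0.32 * fov_w / radius)
        angles = np.arange(10) * step_deg
        mean, sd = sim.overlap_stats(angles, optics, radius)
        assert mean == pytest.approx(68.0, abs=1e-9)
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_step_of_full_fov_gives_zero_overlap(self, optics):
        radius = 4.15
        step_deg = np.rad2deg(optics.fov_mm[0] / radius)
        angles = np.arange(5) * step_deg
        mean, _sd = sim.overlap_stats(angles, optics, radius)
        assert mean == pytest.approx(0.0, abs=1e-9)

    def test_noisy_ring_has_positive_sd(self, optics):
        rng = np.random.default_rng(0)
        angles = np.cumsum(np.abs(rng.normal(4.0, 0.5, 20)))
        _mean, sd = sim.overlap_stats(angles, optics, 4.15)
        assert sd > 0

    def test_single_frame_rejected(self, optics):
        with pytest.raises(ValueError):
            sim.overlap_stats([0.0], optics, 4.15)


class TestDatasetIO:
    def test_save_load_round_trip(self, tmp_path, small_texture, optics):
        o = replace(optics, sensor_px=(64, 64))
        motion = sim.MotionModel(seed=1)
        zstacks, _p, manifest = sim.simulate_ring(
            small_texture, o, motion, n_frames=3, z_plan=(0.0, 0.02), seed=1
        )
        sim.save_dataset(tmp_path / "ring", zstacks, manifest)
        loaded, loaded_manifest = sim.load_dataset(tmp_path / "ring")
        assert loaded_manifest["true_angles_deg"] == manifest["true_angles_deg"]
        assert len(loaded) == 3
        for sa, sb in zip(zstacks, loaded):
            for fa, fb in zip(sa.frames, sb.frames):
                assert np.array_equal(fa, fb)

    def test_missing_manifest_is_an_error(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            sim.load_dataset(tmp_path)


class TestInvariants:
    def test_optics_validation(self):
        with pytest.raises(ValueError):
            sim.Optics(magnification=0)
        with pytest.raises(ValueError):
            sim.Optics(working_distance=-1.0)

    def test_motion_validation(self):
        with pytest.raises(ValueError):
            sim.MotionModel(efficiency=0.0)
        with pytest.raises(ValueError):
            sim.MotionModel(arc_noise_sd=-0.1)

    def test_zstack_validation(self):
        img = np.zeros((4, 4), np.uint8)
        with pytest.raises(ValueError):
            sim.ZStack(frames=[img, img], z_positions=[0.0], stage_position=0.0,
                       frame_index=0)
        with pytest.raises(ValueError):
            sim.ZStack(frames=[img, img], z_positions=[0.1, 0.0],
                       stage_position=0.0, frame_index=0)
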