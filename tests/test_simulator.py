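"""Simulator behavior: gaze kinematics, observation, sessions, sweeps."""

from dataclasses import replace

import numpy as np
import pytest

import gazekit as gk
from gazekit.simulator import batch_observe, grid_targets, sweep_positions


class TestGazeAt:
    def test_straight_ahead_without_kappa(self):
        eye = gk.EyeModel(kappa=(0.0, 0.0))
        st = gk.gaze_at(eye, (0.0, 200.0))
        assert np.allclose(st.optical_axis, [0.0, 0.0, -1.0], atol=1e-12)
        assert np.allclose(
            st.pupil_center_world, eye.center + eye.pupil_distance * np.array([0, 0, -1.0])
        )

    def test_mirrored_targets_give_mirrored_axes(self):
        eye = gk.EyeModel(kappa=(0.0, 0.0))
        a = gk.gaze_at(eye, (120.0, 250.0)).optical_axis
        b = gk.gaze_at(eye, (-120.0, 250.0)).optical_axis
        assert np.allclose(a * np.array([-1, 1, 1]), b, atol=1e-12)

    def test_kappa_angle_matches_composed_rotation_oracle(self):
        """Angle between visual and optical axis equals the brute-force angle
        of the composed horizontal-then-vertical kappa rotation."""
        ka, kb = np.deg2rad(6.0), np.deg2rad(2.0)
        rx = np.array(
            [[1, 0, 0], [0, np.cos(kb), -np.sin(kb)], [0, np.sin(kb), np.cos(kb)]]
        )
        ry = np.array(
            [[np.cos(ka), 0, np.sin(ka)], [0, 1, 0], [-np.sin(ka), 0, np.cos(ka)]]
        )
        v = ry @ rx @ np.array([0.0, 0.0, 1.0])
        expected = np.degrees(np.arccos(v[2]))  # vs the unrotated forward axis
        st = gk.gaze_at(gk.EyeModel(), (0.0, 200.0))
        got = np.degrees(np.arccos(np.dot(st.optical_axis, st.visual_axis)))
        assert got == pytest.approx(expected, abs=1e-9)
        assert got == pytest.approx(6.32, abs=0.02)  # small-angle sqrt(6^2+2^2)

    def test_visual_axis_hits_the_target_through_cornea(self):
        eye = gk.EyeModel()
        target = np.array([150.0, 80.0])
        st = gk.gaze_at(eye, target)
        # ray from corneal center along the visual axis meets z=0 at the target
        lam = -st.cornea_center_world[2] / st.visual_axis[2]
        hit = st.cornea_center_world + lam * st.visual_axis
        assert np.allclose(hit[:2], target, atol=1e-9)

    @pytest.mark.parametrize(
        "target,word",
        [((700.0, 200.0), "horizontal"), ((0.0, 1200.0), "vertical")],
    )
    def test_rotation_limits_raise_naming_the_axis(self, target, word):
        with pytest.raises(gk.RotationLimitError, match=word):
            gk.gaze_at(gk.EyeModel(), target)


class TestEyeModelValidation:
    def test_rejects_nonphysical_parameters(self):
        with pytest.raises(ValueError):
            gk.EyeModel(refraction_index=0.9)
        with pytest.raises(ValueError):
            gk.EyeModel(pupil_distance=20.0)  # outside the corneal sphere
        with pytest.raises(ValueError):
            gk.Scene(camera=gk.Camera(position=(0.0, 200.0, 550.0)))


class TestObservation:
    def test_on_axis_projection_lands_on_principal_point(self, scene_kappa0):
        sc = scene_kappa0.with_camera_at((0.0, 200.0, 0.0))
        st = gk.gaze_at(sc.eye, (0.0, 200.0))
        for refr in (True, False):
            uv = gk.observe_pupil(st, sc, refraction=refr)
            assert np.allclose(uv, [0.0, 0.0], atol=1e-9)

    def test_refraction_displaces_feature_off_axis(self, scene):
        sc = scene.with_camera_at((-150.0, 100.0, 0.0))
        st = gk.gaze_at(sc.eye, (100.0, 300.0))
        on = gk.observe_pupil(st, sc, refraction=True)
        off = gk.observe_pupil(st, sc, refraction=False)
        assert np.linalg.norm(on - off) > 1e-4
        # index -> 1 recovers the unrefracted projection
        sc1 = replace(sc, eye=replace(sc.eye, refraction_index=1.0 + 1e-12))
        st1 = gk.gaze_at(sc1.eye, (100.0, 300.0))
        near = gk.observe_pupil(st1, sc1, refraction=True)
        assert np.allclose(near, off, atol=1e-8)

    def test_depth_scale_law_without_refraction(self, scene_kappa0):
        """On-axis cameras 550 mm apart see the same grid up to one scalar
        scale (residual bounded by the pupil-locus curvature)."""
        near = gk.simulate_session(
            scene_kappa0.with_camera_at((0.0, 200.0, 0.0)), (16, 16), refraction=False
        ).features
        far = gk.simulate_session(
            scene_kappa0.with_camera_at((0.0, 200.0, -550.0)), (16, 16), refraction=False
        ).features
        a = near - near.mean(axis=0)
        b = far - far.mean(axis=0)
        s = float((a * b).sum() / (b * b).sum())
        assert s == pytest.approx(2.0, abs=0.05)  # twice as close -> twice the scale
        spread = np.abs(a).max()
        assert np.abs(a - s * b).max() < 2e-3 * spread  # non-planar locus bound

    def test_glints_follow_led_order_and_symmetry(self, led_scene):
        sc = led_scene.with_camera_at((0.0, 200.0, 0.0))
        sc = replace(sc, eye=replace(sc.eye, kappa=(0.0, 0.0)))
        st = gk.gaze_at(sc.eye, (0.0, 200.0))
        g = gk.observe_glints(st, sc)
        assert g.shape == (4, 2)
        # LEDs at screen corners, centered eye/camera: x-symmetric quad
        assert g[0, 0] == pytest.approx(-g[1, 0], abs=1e-9)
        assert g[0, 1] == pytest.approx(g[1, 1], abs=1e-9)
        assert g[3, 0] == pytest.approx(-g[2, 0], abs=1e-9)

    def test_observe_glints_requires_leds(self, scene):
        st = gk.gaze_at(scene.eye, (0.0, 200.0))
        with pytest.raises(ValueError):
            gk.observe_glints(st, scene)


class TestSession:
    def test_grid_session_has_row_major_records(self, scene, aligned_session):
        assert len(aligned_session) == 441
        tg = grid_targets(scene.screen, 21, 21)
        assert np.array_equal(aligned_session.targets, tg)
        # row-major from top-left: first target is (-200, 350)
        assert np.allclose(tg[0], [-200.0, 350.0])

    def test_single_target_session_equals_observe_pupil(self, scene):
        sc = scene.with_camera_at((50.0, 120.0, 0.0))
        fs = gk.simulate_session(sc, np.array([[30.0, 250.0]]))
        st = gk.gaze_at(sc.eye, (30.0, 250.0))
        assert np.allclose(fs.features[0], gk.observe_pupil(st, sc), atol=1e-9)

    def test_sessions_are_deterministic(self, scene):
        sc = scene.with_camera_at((-100.0, 300.0, 200.0))
        a = gk.simulate_session(sc, (9, 9)).features
        b = gk.simulate_session(sc, (9, 9)).features
        assert np.array_equal(a, b)

    def test_centered_setup_is_x_symmetric(self, scene_kappa0):
        fs = gk.simulate_session(scene_kappa0.with_camera_at((0.0, 200.0, 0.0)), (21, 21))
        f = fs.features.reshape(21, 21, 2)
        assert np.allclose(f[:, :, 0], -f[:, ::-1, 0], atol=1e-9)
        assert np.allclose(f[:, :, 1], f[:, ::-1, 1], atol=1e-9)

    def test_offaxis_camera_skews_the_grid(self, offaxis_session, aligned_session):
        """The off-axis pose shears the feature grid: mean row and column
        directions depart visibly from perpendicular, unlike the aligned
        pose."""

        def shear_deg(fs):
            f = fs.features.reshape(21, 21, 2)
            row = (f[:, -1] - f[:, 0]).mean(axis=0)
            col = (f[-1] - f[0]).mean(axis=0)
            cosang = row @ col / (np.linalg.norm(row) * np.linalg.norm(col))
            return abs(90.0 - np.degrees(np.arccos(cosang)))

        assert shear_deg(offaxis_session) > 3.0
        assert shear_deg(aligned_session) < 0.5


class TestSweep:
    def test_sweep_counts(self, scene):
        pos, shape = sweep_positions((-200, 200, 3), (50, 350, 3), (0, 400, 3))
        assert shape == (3, 3, 3) and len(pos) == 27
        pos_x, _ = sweep_positions((-200, 200, 21), (200, 200, 1), (0, 0, 1))
        assert len(pos_x) == 21
        full, _ = sweep_positions()
        assert len(full) == 9261

    def test_degenerate_sweep_matches_session(self, scene):
        sw = gk.camera_sweep(
            scene, (-100, -100, 1), (250, 250, 1), (0, 0, 1), targets=(5, 5)
        )
        assert len(sw) == 1
        direct = gk.simulate_session(scene.with_camera_at((-100.0, 250.0, 0.0)), (5, 5))
        assert np.allclose(sw.feature_sets[0].features, direct.features, atol=1e-12)

    def test_batch_observe_matches_per_camera_sessions(self, scene):
        cams = np.array([[0.0, 200.0, 0.0], [-150.0, 320.0, 150.0]])
        tg = grid_targets(scene.screen, 4, 4)
        batch = batch_observe(scene, cams, tg)
        for i, cam in enumerate(cams):
            single = gk.simulate_session(scene.with_camera_at(cam), tg)
            assert np.allclose(batch[i], single.features, atol=1e-9)


class TestSceneIO:
    def test_scene_yaml_round_trip(self, tmp_path, led_scene):
        p = tmp_path / "scene.yaml"
        led_scene.save(p)
        again = gk.Scene.load(p)
        assert again == led_scene
        d = led_scene.to_dict()
        assert d["units"] == {"length": "mm", "angle": "deg"}
        assert d["eye"]["cornea_radius"] == 7.8  # defaults recorded in output
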