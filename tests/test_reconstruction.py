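"""Pinhole projection, ray intersection and the bounding-box pseudo-CoM."""
import numpy as np
import pandas as pd
import pytest
from scipy.optimize import least_squares

from mechwork.reconstruction import (
    CameraModel,
    pelvis_proxy,
    project_point,
    pseudo_com_trajectory,
    triangulate_frames,
    triangulate_rays,
)
from mechwork.simulate import default_camera_rig


def _axis_camera(name, center, forward, up=(0, 0, 1), focal=1000.0):
    forward = np.asarray(forward, float)
    forward = forward / np.linalg.norm(forward)
    right = np.cross(forward, np.asarray(up, float))
    right /= np.linalg.norm(right)
    down = np.cross(forward, right)
    R = np.stack([right, down, forward])
    return CameraModel(name, (focal, focal), (960.0, 540.0), R, -R @ np.asarray(center, float))


class TestProjection:
    def test_optical_axis_hits_principal_point(self):
        cam = _axis_camera("c", (0, 0, 0), (0, 1, 0))
        assert np.allclose(project_point(cam, np.array([0.0, 5.0, 0.0])), (960.0, 540.0))

    def test_focal_length_doubles_offset(self):
        cam1 = _axis_camera("a", (0, 0, 0), (0, 1, 0), focal=1000.0)
        cam2 = _axis_camera("b", (0, 0, 0), (0, 1, 0), focal=2000.0)
        p = np.array([0.3, 5.0, -0.2])
        off1 = project_point(cam1, p) - (960.0, 540.0)
        off2 = project_point(cam2, p) - (960.0, 540.0)
        assert np.allclose(off2, 2 * off1)

    def test_point_behind_camera_errors(self):
        cam = _axis_camera("c", (0, 0, 0), (0, 1, 0))
        with pytest.raises(ValueError, match="behind"):
            project_point(cam, np.array([0.0, -1.0, 0.0]))

    def test_rotation_validated(self):
        with pytest.raises(ValueError, match="rotation"):
            CameraModel("bad", (1000, 1000), (960, 540), np.eye(3) * 2, np.zeros(3))


class TestTriangulation:
    def test_two_orthogonal_views_exact(self):
        cams = [
            _axis_camera("a", (0, -5, 1.2), (0, 1, 0)),
            _axis_camera("b", (-5, 2, 1.2), (1, 0, 0)),
        ]
        truth = np.array([1.0, 2.0, 1.2])
        obs = {c.name: project_point(c, truth) for c in cams}
        result = triangulate_rays(cams, obs)
        assert np.allclose(result.point, truth, atol=1e-9)
        assert all(r < 1e-9 for r in result.residuals.values())

    def test_roundtrip_many_points(self, camera_rig, rng):
        cams = list(camera_rig.values())
        for _ in range(20):
            truth = np.array([rng.uniform(-2, 2), rng.uniform(0, 9), rng.uniform(0.3, 1.8)])
            obs = {c.name: project_point(c, truth) for c in cams}
            result = triangulate_rays(cams, obs)
            assert np.linalg.norm(result.point - truth) < 1e-6

    def test_outlier_view_rejected(self, camera_rig):
        cams = list(camera_rig.values())
        truth = np.array([0.5, 4.0, 1.0])
        obs = {c.name: project_point(c, truth) for c in cams}
        obs["cam3"] = obs["cam3"] + np.array([50.0, 0.0])
        result = triangulate_rays(cams, obs, outlier_threshold=0.1)
        assert "cam3" not in result.used
        assert len(result.used) == 7  # only the corrupted view is dropped
        assert np.linalg.norm(result.point - truth) < 1e-6
        assert all(r < 1e-9 for r in result.residuals.values())

    def test_noisy_agrees_with_reprojection_minimiser(self, rng):
        """Linear ray intersection vs nonlinear pixel-reprojection LSQ."""
        centers = [(-8, -3, 3), (8, -3, 3), (-8, 10, 3), (8, 10, 3),
                   (0, -5, 4), (0, 12, 4), (-9, 4, 2.5), (9, 4, 2.5)]
        cams = [
            _axis_camera(f"c{i}", c, np.array([0.0, 4.5, 1.0]) - np.asarray(c, float),
                         focal=2000.0)
            for i, c in enumerate(centers)
        ]
        for _ in range(10):
            truth = np.array([rng.uniform(-1, 1), rng.uniform(3, 6), rng.uniform(0.5, 1.5)])
            obs = {
                c.name: project_point(c, truth) + rng.normal(0, 1.0, 2) for c in cams
            }
            linear = triangulate_rays(cams, obs, outlier_threshold=1.0).point

            def reproj(p):
                return np.concatenate(
                    [project_point(c, p) - obs[c.name] for c in cams]
                )

            init = np.array([0.0, 4.5, 1.0])  # coarse court-centre start
            nonlinear = least_squares(reproj, init).x
            assert np.linalg.norm(linear - nonlinear) < 5e-3

    def test_parallel_rays_degenerate(self):
        cams = [
            _axis_camera("a", (0, 0, 0), (0, 1, 0)),
            _axis_camera("b", (0, -1, 0), (0, 1, 0)),
        ]
        obs = {"a": np.array([960.0, 540.0]), "b": np.array([960.0, 540.0])}
        with pytest.raises(ValueError, match="degenerate|threshold"):
            triangulate_rays(cams, obs)

    def test_fewer_than_two_views(self, camera_rig):
        cams = list(camera_rig.values())
        with pytest.raises(ValueError, match="2"):
            triangulate_rays(cams, {"cam1": np.array([960.0, 540.0])})

    def test_rigid_transform_equivariance(self, rng):
        cams = [
            _axis_camera("a", (0, -5, 1.2), (0, 1, 0)),
            _axis_camera("b", (-5, 2, 1.2), (1, 0, 0)),
            _axis_camera("c", (4, 8, 2.0), (-0.5, -0.8, -0.2)),
        ]
        truth = np.array([0.7, 2.5, 1.1])
        obs = {c.name: project_point(c, truth) for c in cams}
        base = triangulate_rays(cams, obs).point
        theta = 0.7
        Q = np.array(
            [[np.cos(theta), -np.sin(theta), 0], [np.sin(theta), np.cos(theta), 0], [0, 0, 1]]
        )
        shift = np.array([1.0, -2.0, 0.3])
        moved = [
            CameraModel(c.name, c.focal, c.principal, c.rotation @ Q.T,
                        c.translation - c.rotation @ Q.T @ shift)
            for c in cams
        ]
        moved_point = triangulate_rays(moved, obs).point
        assert np.allclose(moved_point, Q @ base + shift, atol=1e-9)

    def test_batched_matches_per_frame(self, camera_rig, rng):
        cams = [camera_rig[k] for k in sorted(camera_rig)]
        points = np.stack(
            [rng.uniform(-2, 2, 30), rng.uniform(0, 9, 30), rng.uniform(0.3, 1.8, 30)],
            axis=1,
        )
        pixels = np.stack([project_point(c, points) for c in cams], axis=1)
        batch = triangulate_frames(cams, pixels)
        assert np.allclose(batch, points, atol=1e-6)


class TestPseudoCom:
    @staticmethod
    def _boxes_from_trajectory(traj, cameras):
        rows = []
        for name in sorted(cameras):
            pix = project_point(cameras[name], traj)
            rows.append(
                pd.DataFrame(
                    {
                        "camera_id": name,
                        "frame": np.arange(len(traj)),
                        "cx": pix[:, 0],
                        "cy": pix[:, 1],
                        "w": 100.0,
                        "h": 200.0,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def test_recovers_known_trajectory(self, camera_rig):
        t = np.arange(600) / 200.0
        traj = np.stack(
            [1.5 * np.sin(2 * np.pi * 0.5 * t), 4.0 + 0.5 * t, 1.0 + 0.05 * np.sin(2 * np.pi * t)],
            axis=1,
        )
        boxes = self._boxes_from_trajectory(traj, camera_rig)
        rec = pseudo_com_trajectory(boxes, camera_rig, rate=200.0, cutoff=6.0)
        rms = np.sqrt(np.mean(np.sum((rec[50:-50] - traj[50:-50]) ** 2, axis=1)))
        assert rms < 5e-3

    def test_static_subject_constant(self, camera_rig):
        traj = np.tile([0.5, 4.0, 1.0], (400, 1))
        boxes = self._boxes_from_trajectory(traj, camera_rig)
        rec = pseudo_com_trajectory(boxes, camera_rig, rate=200.0)
        assert np.allclose(rec, traj, atol=1e-6)

    def test_gap_raises(self, camera_rig):
        traj = np.tile([0.5, 4.0, 1.0], (50, 1))
        boxes = self._boxes_from_trajectory(traj, camera_rig)
        boxes = boxes[~((boxes["frame"] == 20))]  # all views missing at frame 20
        with pytest.raises(ValueError, match="gap"):
            pseudo_com_trajectory(boxes, camera_rig, rate=200.0)

    def test_single_view_frame_raises(self, camera_rig):
        traj = np.tile([0.5, 4.0, 1.0], (50, 1))
        boxes = self._boxes_from_trajectory(traj, camera_rig)
        boxes = boxes[~((boxes["frame"] == 20) & (boxes["camera_id"] != "cam1"))]
        with pytest.raises(ValueError, match="fewer than 2"):
            pseudo_com_trajectory(boxes, camera_rig, rate=200.0)


class TestPelvisProxy:
    def test_offset_pelvis_same_work(self, noiseless_trial, scaled_male):
        from mechwork.energetics import trial_work

        trial, truth = noiseless_trial
        coincident = trial.with_kinematics(pelvis=trial.com.copy())
        offset = trial.with_kinematics(pelvis=trial.com + np.array([0.1, 0.2, 0.0]))
        gs_a, _ = trial_work(coincident, truth.boundaries, scaled_male)
        gs_b, _ = trial_work(offset, truth.boundaries, scaled_male)
        assert gs_a.w_pelvis_pos == pytest.approx(gs_a.w_ext_pos)
        assert gs_b.w_pelvis_pos == pytest.approx(gs_a.w_pelvis_pos, rel=1e-9)

    def test_missing_pelvis_errors(self, noiseless_trial):
        trial, _ = noiseless_trial
        import dataclasses

        bare = dataclasses.replace(trial, pelvis=None)
        with pytest.raises(ValueError, match="pelvis"):
            pelvis_proxy(bare)

    def test_high_frequency_wobble_matches_closed_form(self, scaled_male):
        """Pelvis = CoM + vertical sinusoid inflates work by 2*g*a per period.

        On a constant-velocity CoM the proxy's energy ripple is
        ``g*a*sin`` plus a smaller kinetic term; while the potential term
        dominates, each ripple period adds exactly ``2*g*a`` of positive
        work.
        """
        from mechwork.energetics import trial_work
        from mechwork.segmentation import TrialBoundaries
        from mechwork.trial import MotionTrial

        rate, f, a, g = 200.0, 2.0, 0.01, 9.81
        n = 4001
        t = np.arange(n) / rate
        com = np.stack([2.0 * t, np.zeros(n), np.full(n, 1.0)], axis=1)
        wobble = np.zeros_like(com)
        wobble[:, 2] = a * np.sin(2 * np.pi * f * t)
        trial = MotionTrial(
            rate=rate, com=com,
            segment_positions={}, segment_angular_velocities={},
            subject_mass=77.2, pelvis=com + wobble,
        )
        start, transition, end = 0, 2000, 4000
        gs, sprint = trial_work(trial, TrialBoundaries(start, transition, end), scaled_male)
        for summary, n_periods in ((gs, f * transition / rate), (sprint, f * transition / rate)):
            inflation = summary.w_pelvis_pos - summary.w_ext_pos
            assert inflation == pytest.approx(2 * g * a * n_periods, rel=0.05)
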