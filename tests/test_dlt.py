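"""DLT calibration, projection and triangulation geometry."""

import numpy as np
import pytest

from videba.dlt import dlt_calibrate, project, reconstruct_trajectory, triangulate, triangulate_tracks
from videba.errors import CalibrationError, TriangulationError, ValidationError
from videba.synthetic import CameraRig, pinhole_to_dlt
from videba.types import KEPT, CameraModel, CleanTrack


def cube_points(scale=10.0):
    corners = np.array(
        [[x, y, z] for x in (0, 1) for y in (0, 1) for z in (0, 1)], dtype=float
    ) * scale
    interior = np.array([[0.3, 0.5, 0.7], [0.8, 0.2, 0.4]]) * scale
    return np.vstack([corners, interior])


class TestCalibrate:
    def test_exact_recovery_from_noise_free_projections(self, rig):
        pts = cube_points() + np.array([14, 0, 0])
        for cam in rig.cameras.values():
            px = project(cam, pts)
            est, rms = dlt_calibrate(pts, px)
            assert rms < 1e-9
            assert np.allclose(project(est, pts), px, atol=1e-9)

    def test_noisy_correspondences_give_subpixel_rms(self, rig, rng):
        pts = cube_points() + np.array([14, 0, 0])
        cam = rig.cameras["top"]
        px = project(cam, pts) + rng.normal(0, 0.5, (len(pts), 2))
        _, rms = dlt_calibrate(pts, px)
        assert rms <= 1.0

    def test_coplanar_points_rejected(self, rig):
        pts = np.column_stack([np.arange(6.0), np.arange(6.0) ** 2, np.full(6, 2.0)])
        px = project(rig.cameras["top"], pts)
        with pytest.raises(CalibrationError, match="coplanar"):
            dlt_calibrate(pts, px)

    def test_too_few_points_rejected(self, rig):
        pts = cube_points()[:5]
        with pytest.raises(CalibrationError):
            dlt_calibrate(pts, project(rig.cameras["top"], pts))


class TestProject:
    def test_identity_like_coefficients(self):
        cam = CameraModel(L=np.array([1, 0, 0, 0, 0, 1, 0, 0, 0, 0, 0], dtype=float))
        assert np.allclose(project(cam, np.array([3.0, 4.0, 7.0])), [3.0, 4.0])

    def test_affine_when_denominator_is_constant(self, rng):
        L = np.concatenate([rng.normal(size=8), np.zeros(3)])
        cam = CameraModel(L=L)
        p1, p2 = rng.normal(size=3), rng.normal(size=3)
        lhs = project(cam, (p1 + p2) / 2)
        rhs = (project(cam, p1) + project(cam, p2)) / 2
        assert np.allclose(lhs, rhs, atol=1e-12)


class TestTriangulate:
    def test_noise_free_exact_inverse(self, rig):
        p = np.array([1.0, 2.0, 3.0])
        cams = list(rig.cameras.values())
        px = [project(c, p) for c in cams]
        est, res = triangulate(cams, px)
        assert np.allclose(est, p, atol=1e-9)
        assert res < 1e-9

    def test_noisy_pixels_close_to_nonlinear_oracle(self, rig, rng):
        from scipy.optimize import least_squares

        cams = list(rig.cameras.values())
        pts = rng.uniform([10, 1, 1], [28, 9, 9], (100, 3))
        for p in pts:
            px = [project(c, p) + rng.normal(0, 0.5, 2) for c in cams]
            est, _ = triangulate(cams, px)

            def resid(q):
                return np.concatenate([project(c, q) - x for c, x in zip(cams, px)])

            oracle = least_squares(resid, p).x
            err_lin = np.linalg.norm(est - p)
            err_orc = np.linalg.norm(oracle - p)
            assert err_lin <= err_orc * 1.5 + 1e-9

    def test_missing_pixel_marks_frame_invalid(self, rig):
        cams = list(rig.cameras.values())
        p = np.array([19.0, 5.0, 5.0])
        good = np.array([project(c, p) for c in cams])
        tracks = [np.vstack([g, g]) for g in good]
        tracks[0][1] = np.nan
        pts, res, valid = triangulate_tracks(cams, tracks)
        assert valid[0] and not valid[1]
        assert np.isnan(pts[1]).all()

    def test_single_camera_rejected(self, rig):
        with pytest.raises(TriangulationError):
            triangulate([list(rig.cameras.values())[0]], [np.array([1.0, 1.0])])

    def test_residual_invariant_under_world_axis_relabeling(self, rig, rng):
        # swap x and z in the world: permute point coords and each camera's
        # (L1..L3), (L5..L7), (L9..L11) triplets consistently
        perm = [2, 1, 0]
        cams = list(rig.cameras.values())
        p = rng.uniform([10, 1, 1], [28, 9, 9])
        px = [project(c, p) + rng.normal(0, 0.3, 2) for c in cams]
        _, res = triangulate(cams, px)
        cams_p = []
        for c in cams:
            L = c.L
            cams_p.append(
                CameraModel(np.concatenate([L[0:3][perm], [L[3]], L[4:7][perm], [L[7]], L[8:11][perm]]))
            )
        _, res_p = triangulate(cams_p, px)
        assert res_p == pytest.approx(res, rel=1e-9)


class TestReconstruct:
    def _tracks_from(self, rig, traj_xyz, jitter=0.0, rng=None):
        tracks = {}
        for cam_id, cam in rig.cameras.items():
            px = project(cam, traj_xyz)
            if jitter and rng is not None:
                px = px + rng.normal(0, jitter, px.shape)
            tracks[cam_id] = CleanTrack(
                u=px[:, 0], v=px[:, 1], flags=np.full(len(px), KEPT, np.uint8)
            )
        return tracks

    def test_noise_free_roundtrip_and_full_validity(self, rig):
        t = np.arange(300) / 90.0
        xyz = np.column_stack(
            [19 + np.sin(t), 5 + 0.5 * np.sin(2 * t), 5 + 0.3 * np.cos(t)]
        )
        traj = reconstruct_trajectory(self._tracks_from(rig, xyz), rig.cameras, fps=90.0)
        assert traj.valid.all()
        assert np.max(np.abs(traj.coords() - xyz)) < 1e-8

    def test_halfpixel_noise_keeps_position_error_below_a_millimetre(self, rig, rng):
        t = np.arange(900) / 90.0
        xyz = np.column_stack(
            [19 + np.sin(t), 5 + 0.5 * np.sin(2 * t), 5 + 0.3 * np.cos(t)]
        )
        tracks = self._tracks_from(rig, xyz, jitter=0.5, rng=rng)
        traj = reconstruct_trajectory(tracks, rig.cameras, fps=90.0)
        mae = np.nanmean(np.abs(traj.coords() - xyz))
        assert mae < 0.1  # cm

    def test_swapped_camera_files_blow_up_residuals(self):
        # a rig with the side camera in portrait orientation: swapping the
        # two pose files then routes image axes to the wrong world axes
        centre = np.array([19.0, 5.0, 5.0])
        R_top = np.array([[1.0, 0, 0], [0, -1.0, 0], [0, 0, -1.0]])
        R_side = np.array([[0, 0, 1.0], [-1.0, 0, 0], [0, 1.0, 0]])  # rolled 90 deg
        cams = {
            "top": pinhole_to_dlt(centre + [0, 0, 90], R_top, 4545.0, 960, 540, "top"),
            "side": pinhole_to_dlt(centre + [0, -90, 0], R_side, 4545.0, 960, 540, "side"),
        }
        rig2 = CameraRig(cameras=cams)
        t = np.arange(300) / 90.0
        xyz = np.column_stack([19 + np.sin(t), 5 + 0.5 * np.sin(2 * t), 5 + 0.3 * np.cos(t)])
        tracks = self._tracks_from(rig2, xyz)
        good = reconstruct_trajectory(tracks, rig2.cameras, fps=90.0)
        assert np.nanmax(good.residual) < 1e-6
        swapped = {"top": tracks["side"], "side": tracks["top"]}
        traj = reconstruct_trajectory(swapped, rig2.cameras, fps=90.0)
        frac_bad = np.mean(traj.residual[traj.valid] > 2.0)
        assert frac_bad > 0.5

    def test_frame_axis_mismatch_rejected(self, rig):
        a = CleanTrack(u=np.zeros(10), v=np.zeros(10), flags=np.full(10, KEPT, np.uint8))
        b = CleanTrack(u=np.zeros(11), v=np.zeros(11), flags=np.full(11, KEPT, np.uint8))
        with pytest.raises(ValidationError):
            reconstruct_trajectory({"top": a, "side": b}, rig.cameras, fps=90.0)
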