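"""Direct linear transformation (DLT) camera calibration and triangulation.

The 11-coefficient DLT maps a world point (X, Y, Z) to pixels:

    u = (L1 X + L2 Y + L3 Z + L4) / D
    v = (L5 X + L6 Y + L7 Z + L8) / D,   D = L9 X + L10 Y + L11 Z + 1.

Calibration solves the linearized system from known 3D↔2D correspondences
by least squares; triangulation stacks two linear equations per camera and
solves for the 3D point the same way.  Both are the textbook algebraic
solutions — deterministic, no iterative refinement.
"""

from __future__ import annotations

import numpy as np

from .errors import CalibrationError, ProjectionError, TriangulationError, ValidationError
from .types import CameraModel, CleanTrack, Trajectory3D

__all__ = ["dlt_calibrate", "project", "triangulate", "triangulate_tracks", "reconstruct_trajectory"]

_DENOM_EPS = 1e-12


def dlt_calibrate(points3d: np.ndarray, points2d: np.ndarray, camera_id: str = "") -> tuple[CameraModel, float]:
    """Estimate the 11 DLT coefficients from ≥6 non-coplanar correspondences.

    Returns the camera model and the rms reprojection error in pixels.
    """
    P3 = np.asarray(points3d, dtype=float)
    P2 = np.asarray(points2d, dtype=float)
    if P3.ndim != 2 or P3.shape[1] != 3 or P2.shape != (P3.shape[0], 2):
        raise CalibrationError("need matching (n,3) world and (n,2) pixel arrays")
    n = P3.shape[0]
    if n < 6:
        raise CalibrationError(f"DLT calibration needs >= 6 correspondences, got {n}")
    centered = P3 - P3.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[2] < 1e-9 * max(sv[0], 1.0):
        raise CalibrationError("calibration points are (near-)coplanar; spread them in 3D")

    A = np.zeros((2 * n, 11))
    b = np.empty(2 * n)
    X, Y, Z = P3.T
    u, v = P2.T
    A[0::2, 0:4] = np.column_stack([X, Y, Z, np.ones(n)])
    A[0::2, 8:11] = -u[:, None] * P3
    A[1::2, 4:8] = np.column_stack([X, Y, Z, np.ones(n)])
    A[1::2, 8:11] = -v[:, None] * P3
    b[0::2] = u
    b[1::2] = v
    L, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 11:
        raise CalibrationError(f"rank-deficient calibration design (rank {rank} < 11)")
    cam = CameraModel(L=L, camera_id=camera_id)
    reproj = project(cam, P3)
    rms = float(np.sqrt(np.mean(np.sum((reproj - P2) ** 2, axis=1))))
    return cam, rms


def project(camera: CameraModel, point3d: np.ndarray) -> np.ndarray:
    """Project world point(s) to pixels; accepts (3,) or (n, 3)."""
    P = np.atleast_2d(np.asarray(point3d, dtype=float))
    L = camera.L
    denom = P @ L[8:11] + 1.0
    if np.any(np.abs(denom) < _DENOM_EPS):
        raise ProjectionError("projection denominator vanishes for a point")
    u = (P @ L[0:3] + L[3]) / denom
    v = (P @ L[4:7] + L[7]) / denom
    out = np.column_stack([u, v])
    return out[0] if np.asarray(point3d).ndim == 1 else out


def triangulate(cameras: list[CameraModel], pixels: list[np.ndarray]) -> tuple[np.ndarray, float]:
    """Triangulate one world point from one (u, v) per camera.

    Solves the stacked DLT equations (2 per camera) by least squares and
    returns the point plus the rms reprojection residual in pixels.
    """
    if len(cameras) < 2 or len(pixels) != len(cameras):
        raise TriangulationError("triangulation needs one pixel pair for each of >= 2 cameras")
    rows = []
    rhs = []
    for cam, px in zip(cameras, pixels):
        px = np.asarray(px, dtype=float)
        if px.shape != (2,) or not np.all(np.isfinite(px)):
            raise TriangulationError("invalid pixel pair")
        L = cam.L
        u, v = px
        rows.append([L[0] - u * L[8], L[1] - u * L[9], L[2] - u * L[10]])
        rows.append([L[4] - v * L[8], L[5] - v * L[9], L[6] - v * L[10]])
        rhs.extend([u - L[3], v - L[7]])
    A = np.asarray(rows)
    b = np.asarray(rhs)
    point, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 3:
        raise TriangulationError("degenerate camera geometry (rank < 3)")
    res = []
    for cam, px in zip(cameras, pixels):
        res.append(project(cam, point) - np.asarray(px, dtype=float))
    rms = float(np.sqrt(np.mean(np.concatenate(res) ** 2)))
    return point, rms


def triangulate_tracks(
    cameras: list[CameraModel], pixel_tracks: list[np.ndarray]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-frame triangulation.

    ``pixel_tracks`` holds one (n, 2) array per camera; frames with a
    non-finite pixel in any camera come back invalid.  Returns
    (points (n,3), residual_px (n,), valid (n,)).
    """
    n = pixel_tracks[0].shape[0]
    m = len(cameras)
    if m < 2:
        raise TriangulationError("triangulation needs >= 2 cameras")
    for trk in pixel_tracks:
        if trk.shape != (n, 2):
            raise ValidationError("pixel tracks must share a frame axis")
    valid = np.all([np.all(np.isfinite(t), axis=1) for t in pixel_tracks], axis=0)
    A = np.zeros((n, 2 * m, 3))
    b = np.zeros((n, 2 * m))
    for j, (cam, trk) in enumerate(zip(cameras, pixel_tracks)):
        L = cam.L
        u, v = trk[:, 0], trk[:, 1]
        A[:, 2 * j, :] = np.column_stack([L[0] - u * L[8], L[1] - u * L[9], L[2] - u * L[10]])
        A[:, 2 * j + 1, :] = np.column_stack([L[4] - v * L[8], L[5] - v * L[9], L[6] - v * L[10]])
        b[:, 2 * j] = u - L[3]
        b[:, 2 * j + 1] = v - L[7]
    points = np.full((n, 3), np.nan)
    residual = np.full(n, np.nan)
    if valid.any():
        Av = A[valid]
        bv = b[valid]
        AtA = np.einsum("nij,nik->njk", Av, Av)
        Atb = np.einsum("nij,ni->nj", Av, bv)
        pts = np.linalg.solve(AtA, Atb[..., None])[..., 0]
        points[valid] = pts
        # rms reprojection residual per frame
        res2 = np.zeros(int(valid.sum()))
        for cam, trk in zip(cameras, pixel_tracks):
            L = cam.L
            denom = pts @ L[8:11] + 1.0
            u = (pts @ L[0:3] + L[3]) / denom
            v = (pts @ L[4:7] + L[7]) / denom
            res2 += (u - trk[valid, 0]) ** 2 + (v - trk[valid, 1]) ** 2
        residual[valid] = np.sqrt(res2 / (2 * m))
    return points, residual, valid


def reconstruct_trajectory(
    clean_tracks: dict[str, CleanTrack],
    cameras: dict[str, CameraModel],
    fps: float,
    body_point: str = "eye",
) -> Trajectory3D:
    """Triangulate cleaned two-camera pixel tracks into a 3D trajectory.

    ``clean_tracks`` maps camera_id → CleanTrack (one body point); frames
    invalid in any camera are invalid in 3D.  Per-frame reprojection
    residuals are retained for diagnostics.
    """
    cam_ids = list(clean_tracks)
    if len(cam_ids) < 2:
        raise ValidationError("3D reconstruction needs >= 2 cameras")
    lengths = {len(clean_tracks[c]) for c in cam_ids}
    if len(lengths) != 1:
        raise ValidationError("camera tracks must share a frame axis")
    cams = [cameras[c] for c in cam_ids]
    px = []
    for c in cam_ids:
        trk = clean_tracks[c]
        uv = np.column_stack([trk.u, trk.v]).astype(float)
        uv[~trk.valid] = np.nan
        px.append(uv)
    points, residual, valid = triangulate_tracks(cams, px)
    n = lengths.pop()
    t = np.arange(n) / fps
    return Trajectory3D(
        t=t,
        x=points[:, 0],
        y=points[:, 1],
        z=points[:, 2],
        valid=valid,
        fps=fps,
        body_point=body_point,
        residual=residual,
    )
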