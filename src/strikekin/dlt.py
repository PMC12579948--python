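"""Direct linear transformation (DLT) camera calibration and stereo 3D reconstruction.

The standard 11-parameter DLT maps a world point (x, y, z) to pixel
coordinates (u, v):

    u = (L1 x + L2 y + L3 z + L4) / (L9 x + L10 y + L11 z + 1)
    v = (L5 x + L6 y + L7 z + L8) / (L9 x + L10 y + L11 z + 1)

Calibration solves the linearized system in least squares from >=6
non-coplanar points with known world coordinates; reconstruction solves the
overdetermined 4x3 two-camera system per tracked point. No lens-distortion
terms are modelled. World units are cm, image units are pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import TrackedTrajectory2D, Trajectory3D
from .exceptions import BehindCameraError, DegenerateCalibrationError

__all__ = [
    "CameraDLT",
    "CalibrationSet",
    "calibrate_dlt",
    "reproject",
    "reconstruct_3d",
]

#: Relative singular-value cutoff below which the calibration geometry is
#: treated as degenerate (coplanar / collinear point sets).
_RANK_TOL = 1e-8


@dataclass
class CameraDLT:
    """The 11 DLT coefficients of one camera plus its calibration residual."""

    coefficients: np.ndarray
    calibration_rmse: float = 0.0

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float).ravel()
        if self.coefficients.shape != (11,):
            raise ValueError("CameraDLT requires exactly 11 coefficients")
        if np.allclose(self.coefficients[8:], 0.0):
            raise ValueError("denominator coefficients L9..L11 must not all be zero")


@dataclass
class CalibrationSet:
    """Known 3D points (cm) and their per-camera pixel observations.

    ``observations`` is a list of (n_points, 2) arrays, one per camera;
    missing observations are NaN rows.
    """

    points_3d: np.ndarray
    observations: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.points_3d = np.asarray(self.points_3d, dtype=float)
        self.observations = [np.asarray(o, dtype=float) for o in self.observations]


def _check_noncoplanar(points: np.ndarray) -> None:
    """Raise if the point cloud does not span 3D (needed for a unique DLT)."""
    if points.shape[0] < 6:
        raise DegenerateCalibrationError(
            f"DLT calibration needs >=6 points, got {points.shape[0]}"
        )
    centered = points - points.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    if sv[2] <= _RANK_TOL * sv[0]:
        raise DegenerateCalibrationError("calibration points are coplanar/collinear")


def calibrate_dlt(calib: CalibrationSet, camera_index: int) -> CameraDLT:
    """Least-squares DLT calibration for one camera.

    Points with missing observations for this camera are dropped; the
    remaining set must contain >=6 non-coplanar points. The reported
    ``calibration_rmse`` is the root-mean-square reprojection residual in
    pixels over the points used.
    """
    obs = calib.observations[camera_index]
    keep = np.all(np.isfinite(obs), axis=1)
    pts = calib.points_3d[keep]
    uv = obs[keep]
    _check_noncoplanar(pts)

    n = pts.shape[0]
    A = np.zeros((2 * n, 11))
    b = np.zeros(2 * n)
    x, y, z = pts.T
    u, v = uv.T
    A[0::2, 0:4] = np.column_stack([x, y, z, np.ones(n)])
    A[0::2, 8:11] = -np.column_stack([u * x, u * y, u * z])
    A[1::2, 4:8] = np.column_stack([x, y, z, np.ones(n)])
    A[1::2, 8:11] = -np.column_stack([v * x, v * y, v * z])
    b[0::2] = u
    b[1::2] = v

    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 11:
        raise DegenerateCalibrationError("DLT system is rank deficient")

    cam = CameraDLT(sol)
    pred = reproject(cam, pts)
    rmse = float(np.sqrt(np.mean(np.sum((pred - uv) ** 2, axis=1))))
    cam.calibration_rmse = rmse
    return cam


def reproject(dlt: CameraDLT, points_3d: np.ndarray) -> np.ndarray:
    """Project 3D world points through a DLT camera; returns (n, 2) pixels.

    Raises :class:`BehindCameraError` for points on the camera's principal
    plane, where the projection denominator vanishes.
    """
    pts = np.atleast_2d(np.asarray(points_3d, dtype=float))
    L = dlt.coefficients
    denom = pts @ L[8:11] + 1.0
    scale = max(1.0, float(np.nanmax(np.abs(pts))) * float(np.max(np.abs(L[8:11]))))
    bad = np.abs(denom) < 1e-12 * scale
    if np.any(bad & np.all(np.isfinite(pts), axis=1)):
        raise BehindCameraError("3D point lies on the camera's principal plane")
    u = (pts @ L[0:3] + L[3]) / denom
    v = (pts @ L[4:7] + L[7]) / denom
    out = np.column_stack([u, v])
    if np.asarray(points_3d).ndim == 1:
        return out[0]
    return out


def _triangulate(uv1: np.ndarray, uv2: np.ndarray,
                 L1: np.ndarray, L2: np.ndarray) -> np.ndarray:
    """Solve the 4x3 two-camera DLT system for a single point pair."""
    A = np.empty((4, 3))
    b = np.empty(4)
    for row, (uv, L) in enumerate(((uv1, L1), (uv2, L2))):
        u, v = uv
        A[2 * row] = [L[0] - u * L[8], L[1] - u * L[9], L[2] - u * L[10]]
        A[2 * row + 1] = [L[4] - v * L[8], L[5] - v * L[9], L[6] - v * L[10]]
        b[2 * row] = u - L[3]
        b[2 * row + 1] = v - L[7]
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    return sol


def reconstruct_3d(
    track_cam1: TrackedTrajectory2D,
    track_cam2: TrackedTrajectory2D,
    dlt1: CameraDLT,
    dlt2: CameraDLT,
) -> Trajectory3D:
    """Stereo least-squares 3D reconstruction of two tracked 2D trajectories.

    Landmarks missing (NaN) in either view at a frame yield NaN 3D values for
    that frame; other frames are unaffected. Per-trial mean and max
    reprojection errors (pixels) are recorded on the result.
    """
    if track_cam1.points.shape != track_cam2.points.shape:
        raise ValueError("camera tracks must share frame count and landmark set")
    if track_cam1.labels != track_cam2.labels:
        raise ValueError("camera tracks must share landmark labels")

    F, Lm, _ = track_cam1.points.shape
    out = np.full((F, Lm, 3), np.nan)
    errs: list[float] = []
    L1 = dlt1.coefficients
    L2 = dlt2.coefficients
    for f in range(F):
        for m in range(Lm):
            uv1 = track_cam1.points[f, m]
            uv2 = track_cam2.points[f, m]
            if not (np.all(np.isfinite(uv1)) and np.all(np.isfinite(uv2))):
                continue
            p = _triangulate(uv1, uv2, L1, L2)
            out[f, m] = p
            r1 = reproject(dlt1, p) - uv1
            r2 = reproject(dlt2, p) - uv2
            errs.append(float(np.sqrt((np.sum(r1**2) + np.sum(r2**2)) / 2.0)))

    mean_err = float(np.mean(errs)) if errs else float("nan")
    max_err = float(np.max(errs)) if errs else float("nan")
    return Trajectory3D(
        coords=out,
        frame_rate=track_cam1.frame_rate,
        labels=track_cam1.labels,
        reconstruction_error_mean=mean_err,
        reconstruction_error_max=max_err,
    )
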