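"""Rotation and rigid-body utilities.

All user-facing angles are in degrees.  Rotations follow the intrinsic ZYZ
convention used throughout paramagnetic NMR tensor reporting: the matrix

    R = Rz(alpha) @ Ry(beta) @ Rz(gamma)

is the *active* rotation taking tensor-frame axes into the molecular frame
(the columns of R are the tensor principal axes expressed in molecular
coordinates).  A worked matrix for (30, 40, 50) is given in docs/methods.md.
"""

from __future__ import annotations

import numpy as np

from .errors import DegenerateGeometryError, InvalidArgumentError

__all__ = [
    "rotation_from_euler",
    "euler_from_rotation",
    "axis_angle_rotation",
    "rotation_axis_angle",
    "kabsch_superpose",
    "apply_rigid",
]


def _rz(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _ry(a: float) -> np.ndarray:
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def rotation_from_euler(alpha: float, beta: float, gamma: float) -> np.ndarray:
    """Rotation matrix from intrinsic ZYZ Euler angles in degrees."""
    angles = np.asarray([alpha, beta, gamma], dtype=float)
    if not np.all(np.isfinite(angles)):
        raise InvalidArgumentError(f"non-finite Euler angles: {angles}")
    a, b, g = np.deg2rad(angles)
    return _rz(a) @ _ry(b) @ _rz(g)


def _check_rotation(R: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3):
        raise InvalidArgumentError(f"expected 3x3 matrix, got shape {R.shape}")
    if np.linalg.norm(R.T @ R - np.eye(3)) > tol or np.linalg.det(R) < 0:
        raise InvalidArgumentError("matrix is not a proper rotation")
    return R


def euler_from_rotation(R: np.ndarray) -> tuple[float, float, float]:
    """Canonical ZYZ Euler angles (degrees) of a proper rotation matrix.

    Returns beta in [0, 180) and alpha, gamma in [0, 360).  At the gimbal
    singularities (beta ~ 0 or ~ 180) gamma is fixed to 0 by convention.
    Round-trips through :func:`rotation_from_euler` to better than 1e-8 on
    the matrix.
    """
    R = _check_rotation(R)
    cb = float(np.clip(R[2, 2], -1.0, 1.0))
    beta = np.arccos(cb)
    if np.sin(beta) > 1e-9:
        alpha = np.arctan2(R[1, 2], R[0, 2])
        gamma = np.arctan2(R[2, 1], -R[2, 0])
    elif cb > 0:  # beta ~ 0: R = Rz(alpha + gamma)
        alpha = np.arctan2(R[1, 0], R[0, 0])
        gamma = 0.0
    else:  # beta ~ 180: R = Rz(alpha - gamma) @ Ry(pi)
        alpha = np.arctan2(-R[1, 0], -R[0, 0])
        gamma = 0.0
    deg = np.rad2deg([alpha, beta, gamma])
    alpha, gamma = deg[0] % 360.0, deg[2] % 360.0
    beta = deg[1] % 360.0
    if beta >= 180.0:  # numerically beta stays in [0, 180] from arccos
        beta -= 360.0
    return float(alpha), float(beta), float(gamma)


def axis_angle_rotation(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation by ``angle_deg`` about ``axis`` (Rodrigues)."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if not np.isfinite(n) or n < 1e-12:
        raise InvalidArgumentError("rotation axis must be a nonzero vector")
    k = axis / n
    t = np.deg2rad(angle_deg)
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(t) * K + (1.0 - np.cos(t)) * (K @ K)


def rotation_axis_angle(R: np.ndarray) -> tuple[np.ndarray, float]:
    """Axis (unit vector) and angle in degrees of a proper rotation.

    The identity returns angle 0 with an arbitrary z axis.
    """
    R = _check_rotation(R)
    # rotation vector via the quaternion-free route: antisymmetric part
    w = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    s = np.linalg.norm(w) / 2.0
    c = (np.trace(R) - 1.0) / 2.0
    angle = np.arctan2(s, c)
    if s > 1e-9:
        axis = w / (2.0 * s)
    elif c > 0:
        return np.array([0.0, 0.0, 1.0]), 0.0
    else:  # angle ~ 180: axis from the symmetric part
        B = (R + np.eye(3)) / 2.0
        axis = np.sqrt(np.clip(np.diag(B), 0.0, None))
        # fix signs using the largest component
        i = int(np.argmax(axis))
        axis[(i + 1) % 3] = B[i, (i + 1) % 3] / axis[i] if axis[i] > 0 else 0.0
        axis[(i + 2) % 3] = B[i, (i + 2) % 3] / axis[i] if axis[i] > 0 else 0.0
        axis = axis / np.linalg.norm(axis)
    return axis, float(np.rad2deg(angle))


def kabsch_superpose(
    moving: np.ndarray, fixed: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of paired point sets.

    Returns ``(R, t, rmsd)`` such that ``R @ moving[i] + t`` best matches
    ``fixed[i]``.  Reflections are excluded (proper rotation, det +1).

    Raises
    ------
    DegenerateGeometryError
        Fewer than 3 points, length mismatch, or (near-)collinear points.
    """
    P = np.asarray(moving, dtype=float)
    Q = np.asarray(fixed, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise DegenerateGeometryError(
            f"point sets must be paired (n,3) arrays, got {P.shape} vs {Q.shape}"
        )
    if P.shape[0] < 3:
        raise DegenerateGeometryError("need at least 3 point pairs")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    scale = max(S[0], np.linalg.norm(P0) * np.linalg.norm(Q0) / P.shape[0], 1e-30)
    if S[1] / scale < 1e-9:
        raise DegenerateGeometryError("point set is (near-)collinear; superposition is ill-defined")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    rmsd = float(np.sqrt(np.mean(np.sum((P0 @ R.T - Q0) ** 2, axis=1))))
    return R, t, rmsd


def apply_rigid(R: np.ndarray, t: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Apply the rigid transform x -> R x + t to one point or an (n,3) array."""
    coords = np.asarray(coords, dtype=float)
    return coords @ np.asarray(R).T + np.asarray(t)
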