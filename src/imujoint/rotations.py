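"""Rotation algebra for DCM-based attitude/heading estimation.

Conventions
-----------
A direction cosine matrix ``R`` is stored with *rows* equal to the inertial
unit axes written in sensor coordinates, ``R = [X_S, Y_S, Z_S]^T``, so that
``R @ v_sensor`` gives the coordinates of ``v`` in the inertial frame.  The
third row ``Z_S`` is the attitude vector (inertial vertical seen from the
sensor) and the first row ``X_S`` is the heading vector.  Joint angles use
the Z-Y-X Euler convention ``R = R_z(alpha) R_y(beta) R_x(gamma)`` with
alpha = yaw, beta = pitch, gamma = roll.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DegenerateInputError",
    "EulerZyx",
    "skew",
    "rodrigues",
    "dcm_from_attitude_heading",
    "euler_zyx_from_dcm",
    "euler_zyx_to_dcm",
    "relative_dcm",
    "is_valid_dcm",
    "orthonormalize",
]

#: tolerance below which heading is undefined (attitude ∥ heading)
DEGENERACY_TOL = 1e-8
#: |beta - pi/2| below this counts as gimbal lock
GIMBAL_TOL = 1e-7


class DegenerateInputError(ValueError):
    """Raised when a DCM cannot be built (attitude and heading parallel)."""


@dataclass(frozen=True)
class EulerZyx:
    """Z-Y-X Euler angles in radians: yaw ``alpha``, pitch ``beta``, roll ``gamma``.

    ``gimbal_lock`` flags |beta| = pi/2 where the yaw/roll split is not unique;
    there the convention gamma := 0 is applied so recomposition stays exact.
    """

    alpha: float
    beta: float
    gamma: float
    gimbal_lock: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([self.alpha, self.beta, self.gamma])


def skew(v: np.ndarray) -> np.ndarray:
    """Skew-symmetric cross-product matrix: ``skew(v) @ w == cross(v, w)``."""
    x, y, z = np.asarray(v, dtype=float)
    return np.array([[0.0, -z, y], [z, 0.0, -x], [-y, x, 0.0]])


def rodrigues(phi: np.ndarray) -> np.ndarray:
    """Rotation matrix ``exp(skew(phi))`` for a rotation vector ``phi`` (rad)."""
    phi = np.asarray(phi, dtype=float)
    angle = float(np.linalg.norm(phi))
    if angle < 1e-12:
        return np.eye(3) + skew(phi)
    k = skew(phi / angle)
    return np.eye(3) + np.sin(angle) * k + (1.0 - np.cos(angle)) * (k @ k)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def dcm_from_attitude_heading(Z: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Assemble a DCM from an attitude vector ``Z`` and heading vector ``X``.

    ``Z`` is trusted: it is normalized first and forms the third row exactly.
    ``X`` is projected orthogonal to ``Z`` and normalized (first row), and the
    second row completes the right-handed triad, ``Y = Z x X``.  Invariant to
    positive rescaling of either input.

    Raises
    ------
    DegenerateInputError
        If ``Z`` and ``X`` are (anti)parallel within tolerance — the heading
        is then undefined.
    """
    Z = np.asarray(Z, dtype=float)
    X = np.asarray(X, dtype=float)
    if np.linalg.norm(Z) == 0.0 or np.linalg.norm(X) == 0.0:
        raise DegenerateInputError("attitude/heading vector has zero norm")
    z = _unit(Z)
    x_in = _unit(X)
    if np.linalg.norm(np.cross(z, x_in)) < DEGENERACY_TOL:
        raise DegenerateInputError(
            "attitude and heading vectors are parallel; heading undefined"
        )
    x = _unit(x_in - (x_in @ z) * z)
    y = np.cross(z, x)
    return np.vstack([x, y, z])


def euler_zyx_from_dcm(R: np.ndarray) -> EulerZyx:
    """Extract Z-Y-X Euler angles from ``R = R_z(a) R_y(b) R_x(g)``.

    Away from gimbal lock the recomposition reproduces ``R`` to ~1e-9.  At
    gimbal lock (|beta| = pi/2) gamma is set to 0 by convention and the
    returned ``gimbal_lock`` flag is set.
    """
    R = np.asarray(R, dtype=float)
    beta = -np.arcsin(np.clip(R[2, 0], -1.0, 1.0))
    if abs(abs(beta) - np.pi / 2) < GIMBAL_TOL:
        # R[0,1] = -sin(a±g)·…, collapse onto gamma = 0
        alpha = np.arctan2(-R[0, 1], R[1, 1])
        return EulerZyx(_wrap(alpha), float(beta), 0.0, gimbal_lock=True)
    alpha = np.arctan2(R[1, 0], R[0, 0])
    gamma = np.arctan2(R[2, 1], R[2, 2])
    return EulerZyx(_wrap(alpha), float(beta), _wrap(gamma), gimbal_lock=False)


def euler_zyx_to_dcm(alpha: float, beta: float, gamma: float) -> np.ndarray:
    """Compose ``R = R_z(alpha) R_y(beta) R_x(gamma)``."""
    ca, sa = np.cos(alpha), np.sin(alpha)
    cb, sb = np.cos(beta), np.sin(beta)
    cg, sg = np.cos(gamma), np.sin(gamma)
    rz = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1]], dtype=float)
    ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]], dtype=float)
    rx = np.array([[1, 0, 0], [0, cg, -sg], [0, sg, cg]], dtype=float)
    return rz @ ry @ rx


def relative_dcm(R_i: np.ndarray, R_j: np.ndarray) -> np.ndarray:
    """Relative orientation ``R_ij = R_i^T R_j`` (frame j expressed in frame i)."""
    return np.asarray(R_i).T @ np.asarray(R_j)


def is_valid_dcm(R: np.ndarray, tol: float = 1e-9) -> bool:
    """True if ``R`` is orthonormal with det +1 within ``tol``."""
    R = np.asarray(R, dtype=float)
    if R.shape != (3, 3) or not np.all(np.isfinite(R)):
        return False
    return (
        np.max(np.abs(R @ R.T - np.eye(3))) <= tol
        and abs(np.linalg.det(R) - 1.0) <= tol
    )


def orthonormalize(R: np.ndarray) -> np.ndarray:
    """Project a near-rotation matrix onto SO(3) (polar decomposition via SVD)."""
    u, _, vt = np.linalg.svd(np.asarray(R, dtype=float))
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, 1.0, d]) @ vt


def _wrap(a: float) -> float:
    """Wrap an angle to (-pi, pi]."""
    a = float((a + np.pi) % (2.0 * np.pi) - np.pi)
    return np.pi if a == -np.pi else a
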