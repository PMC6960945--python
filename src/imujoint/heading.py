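"""Heading-vector Kalman filter corrected by a spherical-joint constraint.

This module implements the magnetometer-free heading estimation at the core
of the package.  Both links' heading vectors X_S (the inertial x-axis in
sensor coordinates) are predicted by strapdown gyro integration; the
*following* link's heading is then corrected using the acceleration-level
kinematic constraint of the connecting spherical joint: the joint-center
acceleration computed from either link's IMU must agree in the inertial
frame,

    R_i (a_i + (skew(wdot_i) + skew(w_i)^2) p_i)
        = R_j (a_j + (skew(wdot_j) + skew(w_j)^2) p_j),

where p is the constant sensor-to-joint-center vector.  Written with the
measurable vector C = y_A + (skew(ydot_G) + skew(y_G)^2) p and the DCM rows
(X, Y = Z x X, Z), two scalar equations linear in X_j follow — a 2-vector
measurement z with a 2x3 observation matrix H.  The 2x2 measurement-noise
covariance M propagates the accelerometer noise, gyro noise, gyro-derivative
noise (through the lever-arm matrices lambda_1 = skew(p)skew(y_G)
- 2 skew(y_G)skew(p) and lambda_2 = -skew(p)) and the a posteriori attitude
covariances of both links; products of error terms are neglected.

The constraint carries heading information only while the joint accelerates:
a static joint makes the measurement rows collinear with gravity and yields
no yaw information, so updates are skipped (with a flag) whenever both links'
measured joint acceleration is indistinguishable from gravity, or the
innovation covariance is numerically singular.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .attitude import _symmetrize, _transition
from .rotations import skew

__all__ = [
    "HeadingState",
    "ConstraintInputs",
    "ConstraintMeasurement",
    "heading_predict",
    "compute_C",
    "differentiate_gyro",
    "lambda_matrices",
    "build_measurement",
    "error_covariance",
    "measurement_noise_cov",
    "constraint_measurement",
    "heading_update",
    "is_dynamic",
]

logger = logging.getLogger(__name__)

#: innovation-covariance condition number above which the update is skipped
COND_MAX = 1e12
#: default ||C - g*Z|| (m/s^2) below which the joint counts as static
DYNAMIC_ACCEL_THRESHOLD = 0.2


class TooShortSeriesError(ValueError):
    """Raised when a gyro series is too short to differentiate."""


@dataclass
class HeadingState:
    """Heading vector (unit norm) and its covariance."""

    X: np.ndarray  # (3,)
    P: np.ndarray  # (3, 3)


@dataclass
class ConstraintInputs:
    """Everything the constraint correction consumes at one time step.

    ``C_*`` are the measured joint-acceleration vectors; ``lam1_*``/``lam2_*``
    the lever-arm matrices multiplying gyro and gyro-derivative noise;
    ``Z_*``/``P_Z*`` the a posteriori attitude estimates and covariances;
    ``X_i`` the preceding link's a priori heading and ``X_j`` the following
    link's a priori heading (used only inside the noise covariance).
    """

    C_i: np.ndarray
    C_j: np.ndarray
    lam1_i: np.ndarray
    lam2_i: np.ndarray
    lam1_j: np.ndarray
    lam2_j: np.ndarray
    Z_i: np.ndarray
    Z_j: np.ndarray
    P_Zi: np.ndarray
    P_Zj: np.ndarray
    X_i: np.ndarray
    X_j: np.ndarray


@dataclass
class ConstraintMeasurement:
    """Linearized constraint correction: z = H X_j + v with cov(v) = M."""

    z: np.ndarray  # (2,)
    H: np.ndarray  # (2, 3)
    M: np.ndarray  # (2, 2)


def heading_predict(
    state: HeadingState,
    y_G: np.ndarray,
    dt: float,
    sigma_g: float,
    transition: str = "exact",
    process_noise_dt_power: int = 2,
) -> HeadingState:
    """Strapdown prediction of the heading vector.

    X^- = Phi X^+ renormalized, P^- = Phi P Phi^T + Q with
    Q = dt^q sigma_g^2 skew(X) skew(X)^T — the covariance of the discrete
    process noise w = dt (-skew(X)) n_G for q = 2.
    """
    phi = _transition(y_G, dt, transition)
    Xs = skew(state.X)
    q = dt**process_noise_dt_power * sigma_g**2 * (Xs @ Xs.T)
    X = phi @ state.X
    X = X / np.linalg.norm(X)
    return HeadingState(X=X, P=_symmetrize(phi @ state.P @ phi.T + q))


def compute_C(
    y_A: np.ndarray, y_G: np.ndarray, y_Gdot: np.ndarray, p: np.ndarray
) -> np.ndarray:
    """Measured joint-center acceleration in sensor coordinates.

    C = y_A + (skew(y_Gdot) + skew(y_G)^2) p.  Includes gravity through y_A;
    gravity cancels between the two links when the constraint is formed.
    """
    w = skew(y_G)
    return np.asarray(y_A, float) + (skew(y_Gdot) + w @ w) @ np.asarray(p, float)


def differentiate_gyro(y_G: np.ndarray, dt: float) -> np.ndarray:
    """Numerical time-derivative of a gyro series (rad/s^2).

    Central differences at interior samples, first-order one-sided at the two
    endpoints (``np.gradient``).  Requires at least 3 samples.
    """
    y_G = np.asarray(y_G, dtype=float)
    if len(y_G) < 3:
        raise TooShortSeriesError("need at least 3 samples to differentiate")
    if dt <= 0:
        raise ValueError("dt must be positive")
    return np.gradient(y_G, dt, axis=0, edge_order=1)


def lambda_matrices(y_G: np.ndarray, p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Lever-arm matrices mapping gyro noise into the C error.

    lambda_1 = skew(p) skew(y_G) - 2 skew(y_G) skew(p) multiplies n_G;
    lambda_2 = -skew(p) multiplies the gyro-derivative noise.
    """
    ps = skew(p)
    ws = skew(y_G)
    return ps @ ws - 2.0 * ws @ ps, -ps


def build_measurement(ci: ConstraintInputs) -> tuple[np.ndarray, np.ndarray]:
    """Measurement vector z and observation matrix H of the constraint.

    z = [C_i . X_i ;  C_i . (Z_i x X_i)],  H = [C_j^T ;  C_j^T skew(Z_j)].
    The first row matches the heading components of the joint acceleration
    seen from either link; the second matches the Y (= Z x X) components.
    """
    z = np.array(
        [
            float(ci.C_i @ ci.X_i),
            float(ci.C_i @ (skew(ci.Z_i) @ ci.X_i)),
        ]
    )
    H = np.vstack([ci.C_j, ci.C_j @ skew(ci.Z_j)])
    return z, H


def error_covariance(
    sigma_a: float,
    sigma_g: float,
    sigma_gdot: float,
    lam1: np.ndarray,
    lam2: np.ndarray,
    gdot_term_uses_lambda1: bool = False,
) -> np.ndarray:
    """3x3 covariance of the C error, eps = n_A + lambda_1 n_G + lambda_2 ndot_G.

    Sigma = sigma_a^2 I + sigma_g^2 lambda_1 lambda_1^T
          + sigma_gdot^2 lambda_2 lambda_2^T.
    ``gdot_term_uses_lambda1`` switches the derivative-noise term onto
    lambda_1 lambda_1^T (an alternative printed convention); the default
    follows the error decomposition, which assigns ndot_G to lambda_2.
    """
    lam_d = lam1 if gdot_term_uses_lambda1 else lam2
    return (
        sigma_a**2 * np.eye(3)
        + sigma_g**2 * (lam1 @ lam1.T)
        + sigma_gdot**2 * (lam_d @ lam_d.T)
    )


def measurement_noise_cov(
    ci: ConstraintInputs,
    sigma_a: float,
    sigma_g: float,
    sigma_gdot: float,
    gdot_term_uses_lambda1: bool = False,
    eig_floor_rel: float = 1e-12,
) -> np.ndarray:
    """Assemble the 2x2 measurement-noise covariance M of the constraint.

    The first measurement row carries v1 = eps_i.X_i - eps_j.X_j; the second
    carries the attitude-error projections +/- C.(skew(X) Z_eps) of both links
    plus eps.(skew(Z)X) terms.  All error sources are mutually uncorrelated,
    so M is a sum of per-source quadratic forms; the i/j cross-covariance
    enters only the off-diagonal through the shared eps terms.
    """
    sig_i = error_covariance(sigma_a, sigma_g, sigma_gdot, ci.lam1_i, ci.lam2_i,
                             gdot_term_uses_lambda1)
    sig_j = error_covariance(sigma_a, sigma_g, sigma_gdot, ci.lam1_j, ci.lam2_j,
                             gdot_term_uses_lambda1)
    yi = skew(ci.Z_i) @ ci.X_i  # Y-axis direction terms, link i
    yj = skew(ci.Z_j) @ ci.X_j
    xsi = skew(ci.X_i)
    xsj = skew(ci.X_j)

    m11 = float(ci.X_i @ sig_i @ ci.X_i + ci.X_j @ sig_j @ ci.X_j)
    m12 = float(ci.X_i @ sig_i @ yi + ci.X_j @ sig_j @ yj)
    # attitude-error projections: -C^T skew(X) P_Z skew(X) C (skew^T = -skew)
    att_i = float(-ci.C_i @ xsi @ ci.P_Zi @ xsi @ ci.C_i)
    att_j = float(-ci.C_j @ xsj @ ci.P_Zj @ xsj @ ci.C_j)
    m22 = float(yi @ sig_i @ yi + yj @ sig_j @ yj) + att_i + att_j
    M = np.array([[m11, m12], [m12, m22]])

    # guard: floor eigenvalues so the innovation covariance stays PSD
    tr = np.trace(M)
    if tr > 0:
        w, V = np.linalg.eigh(M)
        floor = eig_floor_rel * tr
        if w[0] < floor:
            M = V @ np.diag(np.maximum(w, floor)) @ V.T
    return _symmetrize(M)


def constraint_measurement(
    ci: ConstraintInputs,
    sigma_a: float,
    sigma_g: float,
    sigma_gdot: float,
    gdot_term_uses_lambda1: bool = False,
) -> ConstraintMeasurement:
    """Convenience: build z, H and M in one call."""
    z, H = build_measurement(ci)
    M = measurement_noise_cov(ci, sigma_a, sigma_g, sigma_gdot, gdot_term_uses_lambda1)
    return ConstraintMeasurement(z=z, H=H, M=M)


def is_dynamic(
    C_i: np.ndarray,
    C_j: np.ndarray,
    Z_i: np.ndarray,
    Z_j: np.ndarray,
    g: float = 9.81,
    threshold: float = DYNAMIC_ACCEL_THRESHOLD,
) -> bool:
    """True when the joint acceleration is distinguishable from gravity alone.

    A static joint gives C = g Z on both links, which makes the constraint
    rows orthogonal to every yaw perturbation — the update would only inject
    noise.  ``threshold`` (m/s^2) is compared against ||C - g Z|| per link.
    """
    return (
        np.linalg.norm(np.asarray(C_i, float) - g * np.asarray(Z_i, float)) > threshold
        or np.linalg.norm(np.asarray(C_j, float) - g * np.asarray(Z_j, float)) > threshold
    )


def heading_update(
    state: HeadingState,
    meas: ConstraintMeasurement,
    cond_max: float = COND_MAX,
) -> tuple[HeadingState, bool]:
    """Kalman correction of the following link's heading by the constraint.

    K = P H^T (H P H^T + M)^-1, X^+ = X^- + K (z - H X^-) renormalized,
    P^+ = (I - K H) P^- symmetrized.  Returns ``(state, skipped)``: the
    update is skipped (prediction returned unchanged) when the innovation
    covariance is numerically singular — e.g. a static joint with parallel
    C vectors, where the constraint carries no heading information.
    """
    S = meas.H @ state.P @ meas.H.T + meas.M
    cond = np.linalg.cond(S)
    if not np.isfinite(cond) or cond > cond_max:
        logger.warning(
            "heading update skipped: innovation covariance ill-conditioned "
            "(cond=%.3g); joint not in a dynamic condition?", cond
        )
        return state, True
    K = state.P @ meas.H.T @ np.linalg.inv(S)
    X = state.X + K @ (meas.z - meas.H @ state.X)
    n = np.linalg.norm(X)
    if n == 0 or not np.all(np.isfinite(X)):
        logger.warning("heading update skipped: degenerate corrected state")
        return state, True
    X = X / n
    P = _symmetrize((np.eye(3) - K @ meas.H) @ state.P)
    return HeadingState(X=X, P=P), False
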