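"""Attitude-vector Kalman filter with Gauss-Markov external-acceleration compensation.

Estimates the attitude vector Z_S (the inertial vertical expressed in sensor
coordinates) for one link.  Prediction is strapdown integration of the gyro;
correction uses the accelerometer, with the external acceleration modelled as
a first-order Gauss-Markov process: the a priori external-acceleration
estimate decays as ``a_hat^- = c_a1 * a_hat^+`` and the measurement-noise
variance is inflated by ``c_a2^2 ||y_A - g Z^- - a_hat^-||^2`` so that large
unexplained accelerations reduce the accelerometer gain.

The joint-angle pipeline consumes only the a posteriori ``Z`` and its
covariance ``P``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .rotations import rodrigues, skew

__all__ = [
    "GmParams",
    "AttitudeState",
    "initial_attitude_state",
    "attitude_predict",
    "attitude_update",
]


@dataclass(frozen=True)
class GmParams:
    """Gauss-Markov external-acceleration model parameters (dimensionless).

    ``c_a1`` is the per-step AR(1) decay of the external-acceleration
    estimate; ``c_a2`` scales the innovation-driven measurement-noise
    inflation.
    """

    c_a1: float = 0.1
    c_a2: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.c_a1 < 1.0:
            raise ValueError("c_a1 must be in [0, 1)")
        if self.c_a2 < 0.0:
            raise ValueError("c_a2 must be non-negative")


@dataclass
class AttitudeState:
    """Attitude vector (unit norm), its covariance, and the GM acceleration estimate."""

    Z: np.ndarray  # (3,) unit attitude vector
    P: np.ndarray  # (3, 3) covariance of the attitude-vector error
    a_hat: np.ndarray = field(default_factory=lambda: np.zeros(3))  # m/s^2


def initial_attitude_state(
    y_A0: np.ndarray, sigma_deg: float = 5.0, a_hat0: np.ndarray | None = None
) -> AttitudeState:
    """Static-start initialization: Z from the first accelerometer sample.

    ``sigma_deg`` sets an isotropic initial attitude uncertainty (default 5
    degrees, appropriate for a roughly static first sample).
    """
    y = np.asarray(y_A0, dtype=float)
    n = np.linalg.norm(y)
    if n == 0:
        raise ValueError("cannot initialize attitude from a zero accelerometer sample")
    sig = np.deg2rad(sigma_deg)
    return AttitudeState(
        Z=y / n,
        P=sig**2 * np.eye(3),
        a_hat=np.zeros(3) if a_hat0 is None else np.asarray(a_hat0, float),
    )


def _symmetrize(P: np.ndarray) -> np.ndarray:
    return 0.5 * (P + P.T)


def _transition(y_G: np.ndarray, dt: float, kind: str) -> np.ndarray:
    """State-transition matrix for a frame-fixed vector under body rate y_G.

    ``exact``: Rodrigues rotation exp(-dt * skew(y_G)) — exact for a constant
    rate over the step.  ``first_order``: I - dt * skew(y_G), the linearized
    form; its renormalized iteration has a secular direction error ~(dt|w|)^2/2
    per step, so ``exact`` is the default throughout the package.
    """
    if kind == "exact":
        return rodrigues(-dt * np.asarray(y_G, dtype=float))
    if kind == "first_order":
        return np.eye(3) - dt * skew(y_G)
    raise ValueError(f"unknown transition kind: {kind!r}")


def attitude_predict(
    state: AttitudeState,
    y_G: np.ndarray,
    dt: float,
    sigma_g: float,
    gm: GmParams = GmParams(),
    transition: str = "exact",
    process_noise_dt_power: int = 2,
) -> AttitudeState:
    """Strapdown prediction of the attitude vector and its covariance.

    Z^- = Phi Z^+, renormalized, with Phi the (exact or first-order) rotation
    by -dt*y_G; P^- = Phi P Phi^T + dt^q sigma_g^2 skew(Z)skew(Z)^T (q = 2 for
    the discrete-white-noise convention, q = 1 for the PSD convention); the
    external-acceleration estimate decays by the GM factor c_a1.
    """
    phi = _transition(y_G, dt, transition)
    Zs = skew(state.Z)
    q = dt**process_noise_dt_power * sigma_g**2 * (Zs @ Zs.T)
    Z = phi @ state.Z
    Z = Z / np.linalg.norm(Z)
    P = _symmetrize(phi @ state.P @ phi.T + q)
    return AttitudeState(Z=Z, P=P, a_hat=gm.c_a1 * state.a_hat)


def attitude_update(
    state: AttitudeState,
    y_A: np.ndarray,
    sigma_a: float,
    gm: GmParams = GmParams(),
    g: float = 9.81,
    return_details: bool = False,
):
    """Accelerometer correction with GM external-acceleration compensation.

    Measurement model: y_A - a_hat^- = g Z + n, with effective noise variance
    R = sigma_a^2 + c_a2^2 ||y_A - g Z^- - a_hat^-||^2 per axis (isotropic).
    After the update the external-acceleration estimate is re-anchored as
    a_hat^+ = y_A - g Z^+.
    """
    y_A = np.asarray(y_A, dtype=float)
    innov = y_A - state.a_hat - g * state.Z
    r = sigma_a**2 + gm.c_a2**2 * float(innov @ innov)
    # H = g I, S = g^2 P + r I
    S = g**2 * state.P + r * np.eye(3)
    K = g * state.P @ np.linalg.inv(S)
    Z = state.Z + K @ innov
    Z = Z / np.linalg.norm(Z)
    P = _symmetrize((np.eye(3) - g * K) @ state.P)
    new = AttitudeState(Z=Z, P=P, a_hat=y_A - g * Z)
    if return_details:
        return new, {"gain": K, "innovation": innov, "meas_var": r}
    return new
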