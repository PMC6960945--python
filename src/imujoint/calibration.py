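"""Identification of the sensor-to-joint-center vectors from IMU data.

For a spherical joint, the joint-center acceleration expressed in the
inertial frame is the same whichever link's IMU computes it.  Its *norm* is
frame-invariant, so with C(p) = y_A + (skew(ydot_G) + skew(y_G)^2) p the
constant sensor-to-joint vectors (p_i, p_j) minimize

    sum_t ( ||C_i(t; p_i)|| - ||C_j(t; p_j)|| )^2

— no orientation estimates are needed during calibration.  The residual is a
norm difference of functions affine in p, so the problem is solved by
Levenberg-damped Gauss-Newton with an analytic Jacobian.  Requires dynamic
excitation: with the joint at rest every p yields ||C|| = ||g Z|| and the
problem is unidentifiable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .heading import differentiate_gyro
from .simulate import ImuSeries, rotational_term

__all__ = ["CalibrationResult", "estimate_joint_vectors", "InsufficientExcitationError"]


class InsufficientExcitationError(ValueError):
    """Raised when the trial lacks the angular motion needed for identification."""


@dataclass
class CalibrationResult:
    """Estimated sensor-to-joint-center vectors and solver diagnostics."""

    p_i: np.ndarray  # (3,) m
    p_j: np.ndarray  # (3,) m
    residual_rms: float  # m/s^2
    iterations: int
    converged: bool
    cost_trace: list[float]  # objective value at each accepted iterate

    def as_dict(self) -> dict:
        return {
            "p_i_m": [float(v) for v in self.p_i],
            "p_j_m": [float(v) for v in self.p_j],
            "residual_rms_ms2": float(self.residual_rms),
            "iterations": int(self.iterations),
            "converged": bool(self.converged),
        }


def _design(series: ImuSeries, smooth_window: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample affine map C(p) = y_A + W p with W = skew(ydot_G) + skew(y_G)^2.

    Calibration is a batch procedure, so the gyro derivative uses a
    Savitzky-Golay filter (cubic, ``smooth_window`` samples) instead of raw
    central differences — the derivative noise otherwise dominates the
    residual at 100 Hz.  ``smooth_window <= 2`` falls back to central
    differences.
    """
    if smooth_window > 2 and len(series.gyro) > smooth_window:
        gdot = savgol_filter(
            series.gyro, smooth_window, 3, deriv=1, delta=series.dt, axis=0
        )
    else:
        gdot = differentiate_gyro(series.gyro, series.dt)
    W = rotational_term(series.gyro, gdot)
    return series.acc, W


def estimate_joint_vectors(
    series_i: ImuSeries,
    series_j: ImuSeries,
    init: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 50,
    min_excitation: float = 0.3,
    smooth_window: int = 15,
) -> CalibrationResult:
    """Estimate (p_i, p_j) by damped Gauss-Newton on the norm-difference residual.

    Parameters
    ----------
    init : optional (6,) start [p_i, p_j]; default zeros.
    tol : convergence threshold on the step norm (m).
    max_iter : maximum accepted Gauss-Newton iterations; on hitting it the
        best iterate is returned with ``converged=False``.
    min_excitation : minimum mean ||y_G|| (rad/s) required on both links.
    """
    for name, s in (("i", series_i), ("j", series_j)):
        if np.mean(np.linalg.norm(s.gyro, axis=1)) < min_excitation:
            raise InsufficientExcitationError(
                f"link {name}: mean angular rate below {min_excitation} rad/s; "
                "calibration needs a dynamic trial"
            )
    y_i, W_i = _design(series_i, smooth_window)
    y_j, W_j = _design(series_j, smooth_window)

    def residual_and_jac(theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        p_i, p_j = theta[:3], theta[3:]
        C_i = y_i + W_i @ p_i
        C_j = y_j + W_j @ p_j
        n_i = np.linalg.norm(C_i, axis=1)
        n_j = np.linalg.norm(C_j, axis=1)
        r = n_i - n_j
        # d||C||/dp = (C/||C||)^T W; guard vanishing norms
        ui = C_i / np.maximum(n_i, 1e-12)[:, None]
        uj = C_j / np.maximum(n_j, 1e-12)[:, None]
        J = np.hstack(
            [np.einsum("na,nab->nb", ui, W_i), -np.einsum("na,nab->nb", uj, W_j)]
        )
        return r, J

    theta = np.zeros(6) if init is None else np.asarray(init, float).copy()
    r, J = residual_and_jac(theta)
    cost = float(r @ r)
    cost_trace = [cost]
    mu = 1e-3
    converged = False
    iterations = 0
    for _ in range(max_iter):
        g = J.T @ r
        JtJ = J.T @ J
        step = None
        # Levenberg damping with multiplicative adaptation: retry with larger
        # mu until the step reduces the objective
        for _ in range(30):
            try:
                cand = np.linalg.solve(JtJ + mu * np.diag(np.diag(JtJ) + 1e-12), -g)
            except np.linalg.LinAlgError:
                mu *= 10.0
                continue
            r_new, J_new = residual_and_jac(theta + cand)
            cost_new = float(r_new @ r_new)
            if cost_new < cost:
                step = cand
                mu = max(mu / 3.0, 1e-12)
                break
            mu *= 3.0
        if step is None:
            break  # no descent step found: stop at the best iterate
        theta = theta + step
        r, J, cost = r_new, J_new, cost_new
        cost_trace.append(cost)
        iterations += 1
        if np.linalg.norm(step) < tol:
            converged = True
            break
    return CalibrationResult(
        p_i=theta[:3],
        p_j=theta[3:],
        residual_rms=float(np.sqrt(cost / len(r))),
        iterations=iterations,
        converged=converged,
        cost_trace=cost_trace,
    )
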