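"""End-to-end joint-angle estimation pipeline.

Per time step and per link: attitude predict + accelerometer update, heading
predict; then the spherical-joint constraint corrects the *following* link's
heading; DCMs are assembled from (Z, X) pairs and the joint angle extracted
as Z-Y-X Euler angles of the relative DCM.  Three estimator variants are
provided:

``proposed``
    The constraint-corrected filter (the package's core method).
``prediction_only``
    No heading correction at all — shows how the relative yaw drifts under
    gyro bias/noise when neither a magnetometer nor a constraint is used.
``oracle_attitude``
    Attitude vectors are supplied externally (e.g. from an optical reference
    or simulator truth) while headings follow the proposed estimator —
    isolates the heading-estimation error from the attitude error.

The chain extension applies the same correction recursively: link 1's
heading is prediction-only, and each subsequent link is corrected against
its predecessor's current heading estimate.

Timing: the gyro derivative entering the constraint uses central differences,
so the estimate at step t consumes sample t+1 — the pipeline is causal up to
a one-sample (10 ms at 100 Hz) latency.  Passing analytic angular
accelerations via ``gyro_dot`` removes both the latency and the
differentiation error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .attitude import AttitudeState, GmParams, attitude_predict, attitude_update, initial_attitude_state
from .heading import (
    COND_MAX,
    DYNAMIC_ACCEL_THRESHOLD,
    ConstraintInputs,
    HeadingState,
    compute_C,
    constraint_measurement,
    differentiate_gyro,
    heading_predict,
    heading_update,
    is_dynamic,
    lambda_matrices,
)
from .rotations import dcm_from_attitude_heading, euler_zyx_from_dcm, relative_dcm
from .simulate import ImuSeries

__all__ = ["PipelineConfig", "JointAngleSeries", "run", "run_chain", "METHODS"]

METHODS = ("proposed", "prediction_only", "oracle_attitude")


@dataclass(frozen=True)
class PipelineConfig:
    """Filter configuration for one joint (a pair of adjacent links).

    Noise standard deviations are those of the *sensors* (SI units); ``gm``
    parametrizes the external-acceleration compensation of the attitude
    stage.  ``init_*`` optionally fix the initial attitude/heading vectors
    (otherwise Z comes from the first accelerometer sample and X from the
    inertial x-axis projected orthogonal to Z); ``init_*_sigma_deg`` set the
    corresponding initial 1-sigma uncertainties in degrees.
    """

    p_i: tuple[float, float, float] = (0.498, -0.001, -0.031)
    p_j: tuple[float, float, float] = (0.512, 0.001, -0.027)
    dt: float = 0.01
    sigma_a: float = 14.8e-3
    sigma_g: float = 1.5e-3
    sigma_gdot: float = 25.3e-3
    #: gyro-rate uncertainty driving the process noise Q; defaults to
    #: ``sigma_g``.  Inflate it (e.g. to sqrt(sigma_g^2 + bias^2)) when a
    #: gyro bias is expected — the filters carry no bias state, so Q must
    #: absorb it for the constraint correction to track the resulting drift.
    sigma_g_process: float | None = None
    gm: GmParams = field(default_factory=GmParams)
    gravity: float = 9.81
    method: str = "proposed"
    init_Z_i: tuple[float, float, float] | None = None
    init_X_i: tuple[float, float, float] | None = None
    init_Z_j: tuple[float, float, float] | None = None
    init_X_j: tuple[float, float, float] | None = None
    init_attitude_sigma_deg: float = 5.0
    init_heading_sigma_deg: float = 10.0
    transition: str = "exact"
    #: gyro integral over (t-1, t] driving the propagation: "quadratic" fits
    #: the last three samples (plus the two-sample coning term) — causal with
    #: strapdown drift ~1e-4 deg/min at 100 Hz; "midpoint" is the two-sample
    #: trapezoid + coning; "left" is the literal first-order discretization.
    gyro_timing: str = "quadratic"
    process_noise_dt_power: int = 2
    gdot_term_uses_lambda1: bool = False
    oracle_zero_attitude_cov: bool = True
    dynamic_accel_threshold: float = DYNAMIC_ACCEL_THRESHOLD
    cond_max: float = COND_MAX

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {self.method!r}")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


@dataclass
class JointAngleSeries:
    """Joint Euler-angle estimates plus per-link diagnostics and flags."""

    t: np.ndarray
    alpha: np.ndarray  # yaw, rad
    beta: np.ndarray  # pitch, rad
    gamma: np.ndarray  # roll, rad
    yaw_i: np.ndarray  # per-link yaw diagnostics, rad
    yaw_j: np.ndarray
    skipped: np.ndarray  # bool: constraint update skipped at this step
    gimbal: np.ndarray  # bool: joint Euler extraction hit gimbal lock

    def euler(self) -> np.ndarray:
        """(n, 3) array with columns [alpha, beta, gamma]."""
        return np.column_stack([self.alpha, self.beta, self.gamma])


class SeriesMismatchError(ValueError):
    """Raised when the IMU series are not synchronized/uniform as required."""


def _check_series(series: list[ImuSeries], dt: float) -> int:
    n = len(series[0])
    for s in series:
        if len(s) != n:
            raise SeriesMismatchError("IMU series must have equal length")
        if abs(s.dt - dt) > 1e-9:
            raise SeriesMismatchError(
                f"series rate {1.0 / s.dt:.6g} Hz does not match config {1.0 / dt:.6g} Hz"
            )
        if np.max(np.abs(s.t - series[0].t)) > 1e-9:
            raise SeriesMismatchError("IMU series timestamps are not synchronized")
    return n


def _init_states(
    series: ImuSeries,
    cfg: PipelineConfig,
    init_Z: tuple | None,
    init_X: tuple | None,
) -> tuple[AttitudeState, HeadingState]:
    if init_Z is not None:
        sig = np.deg2rad(cfg.init_attitude_sigma_deg)
        att = AttitudeState(
            Z=np.asarray(init_Z, float) / np.linalg.norm(init_Z),
            P=sig**2 * np.eye(3),
        )
    else:
        att = initial_attitude_state(series.acc[0], cfg.init_attitude_sigma_deg)
    if init_X is not None:
        x0 = np.asarray(init_X, float)
    else:
        # inertial x-axis projected orthogonal to Z0 (absolute heading of the
        # base link is unobservable anyway; only relative heading matters)
        x0 = np.array([1.0, 0.0, 0.0]) - att.Z[0] * att.Z
        if np.linalg.norm(x0) < 1e-6:
            x0 = np.array([0.0, 1.0, 0.0]) - att.Z[1] * att.Z
    x0 = x0 / np.linalg.norm(x0)
    sig = np.deg2rad(cfg.init_heading_sigma_deg)
    return att, HeadingState(X=x0, P=sig**2 * np.eye(3))


def run(
    series_i: ImuSeries,
    series_j: ImuSeries,
    cfg: PipelineConfig,
    true_Z_i: np.ndarray | None = None,
    true_Z_j: np.ndarray | None = None,
    gyro_dot_i: np.ndarray | None = None,
    gyro_dot_j: np.ndarray | None = None,
) -> JointAngleSeries:
    """Estimate the joint-angle time series for a two-link pair.

    ``true_Z_*`` (required for ``method="oracle_attitude"``) supply external
    attitude sequences; ``gyro_dot_*`` optionally replace the numerical gyro
    derivative with analytic angular accelerations.
    """
    if cfg.method == "oracle_attitude" and (true_Z_i is None or true_Z_j is None):
        raise ValueError("oracle_attitude requires true_Z_i and true_Z_j")
    out = run_chain(
        [series_i, series_j],
        [cfg],
        true_Z=[true_Z_i, true_Z_j] if true_Z_i is not None else None,
        gyro_dot=[gyro_dot_i, gyro_dot_j]
        if gyro_dot_i is not None or gyro_dot_j is not None
        else None,
    )
    return out[0]


def run_chain(
    series: list[ImuSeries],
    cfgs: list[PipelineConfig],
    true_Z: list[np.ndarray] | None = None,
    gyro_dot: list[np.ndarray] | None = None,
    init: list[tuple[np.ndarray, np.ndarray] | None] | None = None,
) -> list[JointAngleSeries]:
    """Estimate all joint angles of an n-link chain (n-1 joints).

    ``cfgs`` holds one configuration per joint; link-level settings (noise,
    initialization, method) are taken from the first config.  ``init``
    optionally supplies per-link initial ``(Z0, X0)`` pairs — useful for
    links beyond the second, which the two-link ``init_*`` config fields do
    not address.  The first link's heading is prediction-only; each
    following link's heading is corrected against its predecessor, so the
    correction propagates recursively along the chain.
    """
    n_links = len(series)
    if n_links < 2:
        raise SeriesMismatchError("need at least 2 links")
    if len(cfgs) != n_links - 1:
        raise SeriesMismatchError("need one config per joint (n_links - 1)")
    cfg0 = cfgs[0]
    method = cfg0.method
    if method == "oracle_attitude" and true_Z is None:
        raise ValueError("oracle_attitude requires true attitude sequences")
    n = _check_series(series, cfg0.dt)
    dt = cfg0.dt
    g = cfg0.gravity

    # sensor-to-joint vectors per link: link k uses p_i of joint k (towards its
    # following joint) and p_j of joint k-1 (towards its preceding joint).
    p_to_next = [np.asarray(c.p_i, float) for c in cfgs] + [None]
    p_to_prev = [None] + [np.asarray(c.p_j, float) for c in cfgs]

    # gyro derivatives (central differences unless supplied analytically)
    gdot = []
    for k, s in enumerate(series):
        if gyro_dot is not None and gyro_dot[k] is not None:
            gdot.append(np.asarray(gyro_dot[k], float))
        else:
            gdot.append(differentiate_gyro(s.gyro, dt))

    # initial states; init_* config fields address links 0 and 1
    att: list[AttitudeState] = []
    head: list[HeadingState] = []
    for k, s in enumerate(series):
        iz = (cfg0.init_Z_i, cfg0.init_Z_j)[k] if k < 2 else None
        ix = (cfg0.init_X_i, cfg0.init_X_j)[k] if k < 2 else None
        if init is not None and init[k] is not None:
            iz, ix = init[k]
        a, h = _init_states(s, cfg0, iz, ix)
        att.append(a)
        head.append(h)

    if method == "oracle_attitude":
        for k in range(n_links):
            att[k] = AttitudeState(
                Z=np.asarray(true_Z[k][0], float),
                P=np.zeros((3, 3)) if cfg0.oracle_zero_attitude_cov else att[k].P,
                a_hat=np.zeros(3),
            )

    n_joints = n_links - 1
    res = [
        JointAngleSeries(
            t=series[0].t.copy(),
            alpha=np.empty(n),
            beta=np.empty(n),
            gamma=np.empty(n),
            yaw_i=np.empty(n),
            yaw_j=np.empty(n),
            skipped=np.zeros(n, dtype=bool),
            gimbal=np.zeros(n, dtype=bool),
        )
        for _ in range(n_joints)
    ]

    def record(step: int) -> None:
        dcms = []
        for k in range(n_links):
            dcms.append(dcm_from_attitude_heading(att[k].Z, head[k].X))
        for q in range(n_joints):
            e = euler_zyx_from_dcm(relative_dcm(dcms[q], dcms[q + 1]))
            r = res[q]
            r.alpha[step], r.beta[step], r.gamma[step] = e.alpha, e.beta, e.gamma
            r.gimbal[step] = e.gimbal_lock
            r.yaw_i[step] = euler_zyx_from_dcm(dcms[q]).alpha
            r.yaw_j[step] = euler_zyx_from_dcm(dcms[q + 1]).alpha

    if cfg0.gyro_timing not in ("quadratic", "midpoint", "left"):
        raise ValueError(f"unknown gyro_timing: {cfg0.gyro_timing!r}")
    sig_gp = cfg0.sigma_g if cfg0.sigma_g_process is None else cfg0.sigma_g_process

    def _prop_gyro(s: ImuSeries, step: int) -> np.ndarray:
        """Equivalent constant rate over (t-1, t] for the chosen scheme."""
        if cfg0.gyro_timing == "left":
            return s.gyro[step - 1]
        w0, w1 = s.gyro[step - 1], s.gyro[step]
        coning = dt / 12.0 * np.cross(w0, w1)
        if cfg0.gyro_timing == "quadratic" and step >= 2:
            # quadratic through the last three samples, integrated over the step
            return (-s.gyro[step - 2] + 8.0 * w0 + 5.0 * w1) / 12.0 + coning
        return 0.5 * (w0 + w1) + coning

    record(0)
    for step in range(1, n):
        w_prop = [_prop_gyro(s, step) for s in series]
        # --- attitude stage (both/all links) ---
        for k in range(n_links):
            if method == "oracle_attitude":
                att[k] = replace(
                    att[k],
                    Z=np.asarray(true_Z[k][step], float),
                    P=np.zeros((3, 3)) if cfg0.oracle_zero_attitude_cov else att[k].P,
                )
            else:
                att[k] = attitude_predict(
                    att[k], w_prop[k], dt, sig_gp, cfg0.gm,
                    cfg0.transition, cfg0.process_noise_dt_power,
                )
                att[k] = attitude_update(
                    att[k], series[k].acc[step], cfg0.sigma_a, cfg0.gm, g
                )
        # --- heading prediction (all links) ---
        for k in range(n_links):
            head[k] = heading_predict(
                head[k], w_prop[k], dt, sig_gp,
                cfg0.transition, cfg0.process_noise_dt_power,
            )
        # --- constraint correction, sequentially along the chain ---
        if method != "prediction_only":
            for q in range(n_joints):
                cfg = cfgs[q]
                a_lnk, b_lnk = q, q + 1
                C_a = compute_C(
                    series[a_lnk].acc[step], series[a_lnk].gyro[step],
                    gdot[a_lnk][step], p_to_next[a_lnk],
                )
                C_b = compute_C(
                    series[b_lnk].acc[step], series[b_lnk].gyro[step],
                    gdot[b_lnk][step], p_to_prev[b_lnk],
                )
                if not is_dynamic(
                    C_a, C_b, att[a_lnk].Z, att[b_lnk].Z, g,
                    cfg.dynamic_accel_threshold,
                ):
                    res[q].skipped[step] = True
                    continue
                lam1_a, lam2_a = lambda_matrices(series[a_lnk].gyro[step], p_to_next[a_lnk])
                lam1_b, lam2_b = lambda_matrices(series[b_lnk].gyro[step], p_to_prev[b_lnk])
                ci = ConstraintInputs(
                    C_i=C_a, C_j=C_b,
                    lam1_i=lam1_a, lam2_i=lam2_a, lam1_j=lam1_b, lam2_j=lam2_b,
                    Z_i=att[a_lnk].Z, Z_j=att[b_lnk].Z,
                    P_Zi=att[a_lnk].P, P_Zj=att[b_lnk].P,
                    X_i=head[a_lnk].X, X_j=head[b_lnk].X,
                )
                meas = constraint_measurement(
                    ci, cfg.sigma_a, cfg.sigma_g, cfg.sigma_gdot,
                    cfg.gdot_term_uses_lambda1,
                )
                head[b_lnk], skipped = heading_update(head[b_lnk], meas, cfg.cond_max)
                res[q].skipped[step] = skipped
        record(step)
    return res
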