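"""Synthetic two-link and n-link spherical-joint motion with IMU signals.

The simulator produces ground truth that satisfies the spherical-joint
acceleration constraint *exactly*.  In the default "bounded" mode all
orientations derive analytically from bounded Euler-angle sinusoids (a base
link that rocks without tumbling, joints that swing within a mechanical
range); in "independent" mode each link's orientation is integrated from a
sum-of-sinusoids body angular-velocity profile.  Either way the shared joint
center follows a smooth translating trajectory and each sensor's external
acceleration is computed analytically from the joint-center acceleration and
the link's angular rates.  IMU measurements are then the noiseless signal
model (gyro = angular rate, accelerometer = gravity along the attitude vector
plus external acceleration) with additive white Gaussian noise.

Defaults reproduce the conditions of the validation experiments this package
targets: 100 Hz sampling, 180 s trials of random 3D rotation, sensor-to-joint
vectors of roughly half a metre, accelerometer noise 14.8 mm/s^2, gyro noise
1.5 mrad/s, and external-acceleration magnitudes of a few m/s^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rotations import euler_zyx_from_dcm, orthonormalize, relative_dcm, skew

__all__ = [
    "ConfigError",
    "SimConfig",
    "MotionProfile",
    "ImuSeries",
    "LinkTruth",
    "TwoLinkTruth",
    "ChainTruth",
    "simulate_truth",
    "simulate_chain",
    "synthesize_imu",
    "constraint_residual",
    "rotational_term",
]

GRAVITY = 9.81


class ConfigError(ValueError):
    """Raised for an invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Conditions of a simulated spherical-joint trial.

    Each link's body angular velocity is an independent sum of
    ``omega_components`` sinusoids per axis with amplitudes and frequencies
    drawn from the given ranges (rad/s, Hz); the joint center translates along
    an analogous sum-of-sinusoids path (m).  ``p_i``/``p_j`` are the constant
    sensor-to-joint-center vectors in each sensor frame (m).  ``gyro_bias_*``
    add a constant rate offset (rad/s; default zero, i.e. the white-noise-only
    sensor model).
    """

    duration: float = 180.0
    sample_rate: float = 100.0
    gravity: float = GRAVITY
    omega_components: int = 4
    omega_amp_range: tuple[float, float] = (0.3, 0.8)
    omega_freq_range: tuple[float, float] = (0.1, 1.2)
    #: "bounded": joint Euler angles follow bounded sinusoids (a connected
    #: joint with a mechanical range of motion, clear of the Euler
    #: singularity); "independent": every link rotates independently.
    joint_motion: str = "bounded"
    joint_angle_components: int = 3
    joint_angle_amp_range_deg: tuple[float, float] = (5.0, 15.0)
    joint_angle_freq_range: tuple[float, float] = (0.15, 0.55)
    #: bounded mode: per-component Euler-angle amplitudes of the base link's
    #: rocking motion about a random fixed yaw (deg) — hand-held links swing
    #: through tens of degrees but do not tumble
    base_angle_amp_range_deg: tuple[float, float] = (8.0, 18.0)
    traj_components: int = 3
    traj_amp_range: tuple[float, float] = (0.04, 0.10)
    traj_freq_range: tuple[float, float] = (0.3, 0.9)
    #: seconds over which the motion amplitude ramps smoothly from rest; a
    #: static start lets estimators initialize attitude from the first
    #: accelerometer samples, as in a physical trial. 0 disables the ramp.
    ramp_time: float = 5.0
    p_i: tuple[float, float, float] = (0.498, -0.001, -0.031)
    p_j: tuple[float, float, float] = (0.512, 0.001, -0.027)
    sigma_a: float = 14.8e-3
    sigma_g: float = 1.5e-3
    gyro_bias_i: tuple[float, float, float] = (0.0, 0.0, 0.0)
    gyro_bias_j: tuple[float, float, float] = (0.0, 0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ConfigError("duration must be positive")
        if self.sample_rate <= 0:
            raise ConfigError("sample_rate must be positive")
        if self.sigma_a < 0 or self.sigma_g < 0:
            raise ConfigError("noise standard deviations must be non-negative")
        if self.omega_components < 1 or self.traj_components < 1:
            raise ConfigError("need at least one sinusoid component")
        if self.joint_motion not in ("bounded", "independent"):
            raise ConfigError(f"unknown joint_motion mode: {self.joint_motion!r}")

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sample_rate)) + 1


@dataclass(frozen=True)
class MotionProfile:
    """Sum-of-sinusoids vector signal with analytic derivatives.

    value(t) = sum_k A[:, k] * sin(2 pi f_k t + phi[:, k])
    """

    amplitudes: np.ndarray  # (3, K)
    freqs_hz: np.ndarray  # (K,)
    phases: np.ndarray  # (3, K)

    @classmethod
    def random(
        cls,
        rng: np.random.Generator,
        n_components: int,
        amp_range: tuple[float, float],
        freq_range: tuple[float, float],
    ) -> "MotionProfile":
        amps = rng.uniform(*amp_range, size=(3, n_components))
        freqs = rng.uniform(*freq_range, size=n_components)
        phases = rng.uniform(0.0, 2.0 * np.pi, size=(3, n_components))
        return cls(amps, freqs, phases)

    @classmethod
    def zero(cls) -> "MotionProfile":
        return cls(np.zeros((3, 1)), np.zeros(1), np.zeros((3, 1)))

    def _arg(self, t: np.ndarray) -> np.ndarray:
        return (
            2.0 * np.pi * self.freqs_hz[None, None, :] * t[:, None, None]
            + self.phases[None, :, :]
        )

    def value(self, t) -> np.ndarray:
        tt = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.sum(self.amplitudes[None, :, :] * np.sin(self._arg(tt)), axis=2)
        return out[0] if np.ndim(t) == 0 else out

    def derivative(self, t) -> np.ndarray:
        tt = np.atleast_1d(np.asarray(t, dtype=float))
        w = 2.0 * np.pi * self.freqs_hz
        out = np.sum((self.amplitudes * w)[None, :, :] * np.cos(self._arg(tt)), axis=2)
        return out[0] if np.ndim(t) == 0 else out

    def second_derivative(self, t) -> np.ndarray:
        tt = np.atleast_1d(np.asarray(t, dtype=float))
        w = 2.0 * np.pi * self.freqs_hz
        out = -np.sum((self.amplitudes * w**2)[None, :, :] * np.sin(self._arg(tt)), axis=2)
        return out[0] if np.ndim(t) == 0 else out


@dataclass(frozen=True)
class RampedProfile:
    """A motion profile scaled by a C^2 start-up envelope (smootherstep).

    The envelope e(t) = 6s^5 - 15s^4 + 10s^3 with s = clip(t/T, 0, 1) rises
    from exact rest (e = e' = e'' = 0 at t = 0) to 1 at t = T, so enveloped
    signals and their first two analytic derivatives stay consistent.
    """

    base: MotionProfile
    ramp_time: float

    def _env(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        T = self.ramp_time
        s = np.clip(np.asarray(t, dtype=float) / T, 0.0, 1.0)
        e = 6 * s**5 - 15 * s**4 + 10 * s**3
        ed = (30 * s**4 - 60 * s**3 + 30 * s**2) / T
        edd = (120 * s**3 - 180 * s**2 + 60 * s) / T**2
        return e, ed, edd

    def value(self, t) -> np.ndarray:
        tt = np.atleast_1d(np.asarray(t, dtype=float))
        e, _, _ = self._env(tt)
        out = e[:, None] * self.base.value(tt)
        return out[0] if np.ndim(t) == 0 else out

    def derivative(self, t) -> np.ndarray:
        tt = np.atleast_1d(np.asarray(t, dtype=float))
        e, ed, _ = self._env(tt)
        out = ed[:, None] * self.base.value(tt) + e[:, None] * self.base.derivative(tt)
        return out[0] if np.ndim(t) == 0 else out

    def second_derivative(self, t) -> np.ndarray:
        tt = np.atleast_1d(np.asarray(t, dtype=float))
        e, ed, edd = self._env(tt)
        out = (
            edd[:, None] * self.base.value(tt)
            + 2.0 * ed[:, None] * self.base.derivative(tt)
            + e[:, None] * self.base.second_derivative(tt)
        )
        return out[0] if np.ndim(t) == 0 else out


@dataclass
class ImuSeries:
    """Uniformly sampled triaxial gyro (rad/s) + accelerometer (m/s^2) streams."""

    t: np.ndarray  # (n,)
    gyro: np.ndarray  # (n, 3)
    acc: np.ndarray  # (n, 3)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.gyro = np.asarray(self.gyro, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        if not (len(self.t) == len(self.gyro) == len(self.acc)):
            raise ValueError("t, gyro and acc must have equal lengths")
        if len(self.t) >= 2:
            steps = np.diff(self.t)
            if np.max(np.abs(steps - steps[0])) > 1e-9:
                raise ValueError("timestamps must be uniformly spaced")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class LinkTruth:
    """Ground truth for one link: orientation, rates and external acceleration."""

    R: np.ndarray  # (n, 3, 3) DCMs with rows [X, Y, Z]; maps sensor -> inertial
    omega: np.ndarray  # (n, 3) body angular velocity, rad/s
    omega_dot: np.ndarray  # (n, 3) analytic angular acceleration, rad/s^2
    acc: np.ndarray  # (n, 3) external (non-gravitational) acceleration, body frame

    @property
    def Z(self) -> np.ndarray:
        """Attitude-vector sequence (third DCM row)."""
        return self.R[:, 2, :]

    @property
    def X(self) -> np.ndarray:
        """Heading-vector sequence (first DCM row)."""
        return self.R[:, 0, :]


@dataclass
class ChainTruth:
    """Truth for an n-link chain: per-link kinematics + per-joint geometry/angles."""

    t: np.ndarray
    links: list[LinkTruth]
    #: per joint k: (sensor->joint vector of link k, sensor->joint vector of link k+1)
    joint_vectors: list[tuple[np.ndarray, np.ndarray]]
    joint_euler: list[np.ndarray]  # per joint: (n, 3) columns [alpha, beta, gamma]
    joint_acc: np.ndarray  # (n_joints, n, 3) inertial joint-center accelerations
    config: SimConfig

    @property
    def n_links(self) -> int:
        return len(self.links)


@dataclass
class TwoLinkTruth:
    """Ground truth for the canonical two-link spherical-joint trial."""

    t: np.ndarray
    link_i: LinkTruth
    link_j: LinkTruth
    joint_euler: np.ndarray  # (n, 3)
    joint_acc: np.ndarray  # (n, 3) inertial joint-center acceleration
    config: SimConfig


def rotational_term(omega: np.ndarray, omega_dot: np.ndarray) -> np.ndarray:
    """``skew(omega_dot) + skew(omega)^2`` as an (n, 3, 3) stack, vectorized.

    Applied to a sensor-to-joint vector this gives the rigid-body (tangential
    + centripetal) acceleration of the joint center relative to the sensor,
    in body coordinates.
    """
    omega = np.atleast_2d(omega)
    omega_dot = np.atleast_2d(omega_dot)
    n = len(omega)
    W = np.zeros((n, 3, 3))
    Wd = np.zeros((n, 3, 3))
    for m, v in ((W, omega), (Wd, omega_dot)):
        m[:, 0, 1], m[:, 0, 2] = -v[:, 2], v[:, 1]
        m[:, 1, 0], m[:, 1, 2] = v[:, 2], -v[:, 0]
        m[:, 2, 0], m[:, 2, 1] = -v[:, 1], v[:, 0]
    return Wd + W @ W


def _integrate_orientation(
    profile: MotionProfile, t: np.ndarray, R0: np.ndarray
) -> np.ndarray:
    """Integrate dR/dt = R skew(omega(t)) with fixed-step RK4, re-orthonormalized.

    The truth integrator must be far more accurate than any estimator under
    test, hence 4th order with continuous (analytic) angular-velocity samples.
    """
    n = len(t)
    dt = float(t[1] - t[0]) if n > 1 else 0.0
    out = np.empty((n, 3, 3))
    R = orthonormalize(R0)
    out[0] = R
    for k in range(n - 1):
        tk = float(t[k])
        s1 = skew(profile.value(tk))
        s2 = skew(profile.value(tk + 0.5 * dt))
        s4 = skew(profile.value(tk + dt))
        k1 = R @ s1
        k2 = (R + 0.5 * dt * k1) @ s2
        k3 = (R + 0.5 * dt * k2) @ s2
        k4 = (R + dt * k3) @ s4
        R = orthonormalize(R + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4))
        out[k + 1] = R
    return out


def _euler_zyx_dcms(angles: np.ndarray) -> np.ndarray:
    """Vectorized R_z(a) R_y(b) R_x(g) for (n, 3) angle rows [a, b, g]."""
    a, b, g = angles[:, 0], angles[:, 1], angles[:, 2]
    ca, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    cg, sg = np.cos(g), np.sin(g)
    R = np.empty((len(a), 3, 3))
    R[:, 0, 0] = ca * cb
    R[:, 0, 1] = ca * sb * sg - sa * cg
    R[:, 0, 2] = ca * sb * cg + sa * sg
    R[:, 1, 0] = sa * cb
    R[:, 1, 1] = sa * sb * sg + ca * cg
    R[:, 1, 2] = sa * sb * cg - ca * sg
    R[:, 2, 0] = -sb
    R[:, 2, 1] = cb * sg
    R[:, 2, 2] = cb * cg
    return R


def _euler_rates_to_body(angles: np.ndarray, rates: np.ndarray) -> np.ndarray:
    """Body angular velocity of R_z(a)R_y(b)R_x(g) from Euler angle rates."""
    _, b, g = angles[:, 0], angles[:, 1], angles[:, 2]
    ad, bd, gd = rates[:, 0], rates[:, 1], rates[:, 2]
    sb, cb = np.sin(b), np.cos(b)
    sg, cg = np.sin(g), np.cos(g)
    return np.column_stack(
        [gd - sb * ad, cg * bd + sg * cb * ad, -sg * bd + cg * cb * ad]
    )


def _euler_rates_to_body_dot(
    angles: np.ndarray, rates: np.ndarray, accels: np.ndarray
) -> np.ndarray:
    """Analytic time-derivative of ``_euler_rates_to_body`` (product rule)."""
    _, b, g = angles[:, 0], angles[:, 1], angles[:, 2]
    ad, bd, gd = rates[:, 0], rates[:, 1], rates[:, 2]
    add, bdd, gdd = accels[:, 0], accels[:, 1], accels[:, 2]
    sb, cb = np.sin(b), np.cos(b)
    sg, cg = np.sin(g), np.cos(g)
    wx = gdd - cb * bd * ad - sb * add
    wy = (
        -sg * gd * bd + cg * bdd
        + cg * gd * cb * ad - sg * sb * bd * ad + sg * cb * add
    )
    wz = (
        -cg * gd * bd - sg * bdd
        - sg * gd * cb * ad - cg * sb * bd * ad + cg * cb * add
    )
    return np.column_stack([wx, wy, wz])


def _random_dcm(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation (QR of a Gaussian matrix, sign-fixed)."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 2] *= -1
    return q


def simulate_chain(n_links: int, cfg: SimConfig) -> ChainTruth:
    """Simulate an ``n_links`` chain of rigid links joined by spherical joints.

    The first joint's inertial trajectory is the configured sum-of-sinusoids
    path; subsequent joint centers follow from the links' rigid geometry, so
    every adjacent pair satisfies the acceleration-level joint constraint
    exactly (to roundoff).  With ``n_links=2`` this is the two-link trial.
    """
    if n_links < 2:
        raise ConfigError("a chain needs at least 2 links")
    rng = np.random.default_rng(cfg.seed)
    t = np.arange(cfg.n_samples) * cfg.dt
    n = len(t)

    p_i = np.asarray(cfg.p_i, dtype=float)
    p_j = np.asarray(cfg.p_j, dtype=float)
    # sensor->joint vectors: link k has p_next[k] to joint k (k <= n-2) and
    # p_prev[k] to joint k-1 (k >= 1).  The first joint reproduces the
    # two-link geometry (p_i, p_j); interior links extend it mirrored.
    p_next = [p_i] + [-p_j] * (n_links - 1)
    p_prev = [None] + [p_j] * (n_links - 1)

    def _ramp(profile: MotionProfile):
        return RampedProfile(profile, cfg.ramp_time) if cfg.ramp_time > 0 else profile

    traj = _ramp(
        MotionProfile.random(
            rng, cfg.traj_components, cfg.traj_amp_range, cfg.traj_freq_range
        )
    )

    links: list[LinkTruth] = []
    if cfg.joint_motion == "independent":
        for k in range(n_links):
            profile = _ramp(
                MotionProfile.random(
                    rng, cfg.omega_components, cfg.omega_amp_range, cfg.omega_freq_range
                )
            )
            R = _integrate_orientation(profile, t, _random_dcm(rng))
            links.append(
                LinkTruth(
                    R=R,
                    omega=profile.value(t),
                    omega_dot=profile.derivative(t),
                    acc=np.zeros((n, 3)),  # filled below
                )
            )
    else:
        # bounded mode: all orientations derive from bounded Euler-angle
        # sinusoids, fully analytically.  The base link rocks about a random
        # fixed yaw without tumbling (as a hand-moved link does); each
        # joint's Euler angles follow bounded sinusoids and the following
        # link's kinematics are derived exactly (R_next = R_prev @ R_rel,
        # omega_next = R_rel^T omega_prev + omega_rel, likewise for the
        # derivative), so the joint constraint holds to roundoff.
        base_range = tuple(np.deg2rad(cfg.base_angle_amp_range_deg))
        bp = _ramp(
            MotionProfile.random(
                rng, cfg.joint_angle_components, base_range,
                cfg.joint_angle_freq_range,
            )
        )
        ang, rate, accel = bp.value(t), bp.derivative(t), bp.second_derivative(t)
        Rz0 = _euler_zyx_dcms(np.array([[rng.uniform(0.0, 2.0 * np.pi), 0.0, 0.0]]))[0]
        links.append(
            LinkTruth(
                R=Rz0 @ _euler_zyx_dcms(ang),
                omega=_euler_rates_to_body(ang, rate),
                omega_dot=_euler_rates_to_body_dot(ang, rate, accel),
                acc=np.zeros((n, 3)),
            )
        )
        amp_lo, amp_hi = np.deg2rad(cfg.joint_angle_amp_range_deg[0]), np.deg2rad(
            cfg.joint_angle_amp_range_deg[1]
        )
        for k in range(1, n_links):
            jp = _ramp(
                MotionProfile.random(
                    rng, cfg.joint_angle_components, (amp_lo, amp_hi),
                    cfg.joint_angle_freq_range,
                )
            )
            ang, rate, accel = jp.value(t), jp.derivative(t), jp.second_derivative(t)
            R_rel = _euler_zyx_dcms(ang)
            w_rel = _euler_rates_to_body(ang, rate)
            wd_rel = _euler_rates_to_body_dot(ang, rate, accel)
            prev = links[k - 1]
            w_prev_in_rel = np.einsum("nba,nb->na", R_rel, prev.omega)
            wd_prev_in_rel = np.einsum("nba,nb->na", R_rel, prev.omega_dot)
            links.append(
                LinkTruth(
                    R=prev.R @ R_rel,
                    omega=w_prev_in_rel + w_rel,
                    omega_dot=wd_prev_in_rel - np.cross(w_rel, w_prev_in_rel) + wd_rel,
                    acc=np.zeros((n, 3)),
                )
            )

    joint_vectors: list[tuple[np.ndarray, np.ndarray]] = []
    joint_euler: list[np.ndarray] = []
    joint_acc = np.empty((n_links - 1, n, 3))

    acc_joint = traj.second_derivative(t)  # joint 0, inertial frame
    for k, link in enumerate(links):
        rot = rotational_term(link.omega, link.omega_dot)
        p_ref = p_next[0] if k == 0 else p_prev[k]
        # rows of R are inertial axes in body coords => v_I = R v_S and
        # v_S = R^T v_I; einsum 'nba,nb->na' applies R^T to acc_joint.
        link.acc = np.einsum("nba,nb->na", link.R, acc_joint) - np.einsum(
            "nab,b->na", rot, p_ref
        )
        if k >= 1:
            joint_vectors.append((p_next[k - 1], p_prev[k]))
            eul = np.empty((n, 3))
            for s in range(n):
                e = euler_zyx_from_dcm(relative_dcm(links[k - 1].R[s], link.R[s]))
                eul[s] = (e.alpha, e.beta, e.gamma)
            joint_euler.append(eul)
            joint_acc[k - 1] = acc_joint
        if 1 <= k <= n_links - 2:
            # propagate to joint k: r_joint_k = r_joint_{k-1} + R_k (p_next - p_prev)
            d = p_next[k] - p_prev[k]
            rigid_body = np.einsum("nab,b->na", rot, d)  # body frame
            acc_joint = acc_joint + np.einsum("nab,nb->na", link.R, rigid_body)

    return ChainTruth(
        t=t,
        links=links,
        joint_vectors=joint_vectors,
        joint_euler=joint_euler,
        joint_acc=joint_acc,
        config=cfg,
    )


def simulate_truth(cfg: SimConfig) -> TwoLinkTruth:
    """Simulate the canonical two-link spherical-joint trial."""
    chain = simulate_chain(2, cfg)
    return TwoLinkTruth(
        t=chain.t,
        link_i=chain.links[0],
        link_j=chain.links[1],
        joint_euler=chain.joint_euler[0],
        joint_acc=chain.joint_acc[0],
        config=cfg,
    )


def synthesize_imu(
    truth: TwoLinkTruth | ChainTruth, cfg: SimConfig | None = None
) -> tuple[ImuSeries, ...]:
    """Generate noisy IMU streams from ground truth, one per link.

    gyro = omega + bias + n_G and acc = g * Z_S + a_S + n_A with iid zero-mean
    Gaussian noise at the configured standard deviations.  The noise stream is
    seeded from ``cfg.seed``, so a fixed seed gives bitwise-identical output.
    """
    cfg = cfg or truth.config
    links = (
        truth.links if isinstance(truth, ChainTruth) else [truth.link_i, truth.link_j]
    )
    rng = np.random.default_rng([cfg.seed, 0xB10])
    biases = [np.asarray(cfg.gyro_bias_i, float), np.asarray(cfg.gyro_bias_j, float)]
    out = []
    for k, link in enumerate(links):
        bias = biases[k] if k < 2 else np.zeros(3)
        n_g = rng.normal(0.0, cfg.sigma_g, size=link.omega.shape) if cfg.sigma_g else 0.0
        n_a = rng.normal(0.0, cfg.sigma_a, size=link.acc.shape) if cfg.sigma_a else 0.0
        gyro = link.omega + bias + n_g
        acc = cfg.gravity * link.Z + link.acc + n_a
        out.append(ImuSeries(t=truth.t.copy(), gyro=gyro, acc=acc))
    return tuple(out)


def constraint_residual(truth: TwoLinkTruth | ChainTruth, joint: int = 0) -> np.ndarray:
    """Spherical-joint acceleration residual on the truth, per sample (m/s^2).

    For the adjacent links a, b at ``joint`` this evaluates
    ``|| R_a (acc_a + (skew(omega_dot_a) + skew(omega_a)^2) p_a)
       - R_b (acc_b + (...) p_b) ||``
    with the *analytic* angular accelerations, so the oracle carries no
    numerical-differentiation error.  Zero to roundoff by construction.
    """
    if isinstance(truth, TwoLinkTruth):
        links = [truth.link_i, truth.link_j]
        p_a = np.asarray(truth.config.p_i, float)
        p_b = np.asarray(truth.config.p_j, float)
        if joint != 0:
            raise IndexError("two-link truth has a single joint")
    else:
        links = truth.links[joint : joint + 2]
        p_a, p_b = truth.joint_vectors[joint]
    a, b = links
    lhs = np.einsum(
        "nba,nb->na",
        np.transpose(a.R, (0, 2, 1)),
        a.acc + np.einsum("nab,b->na", rotational_term(a.omega, a.omega_dot), p_a),
    )
    rhs = np.einsum(
        "nba,nb->na",
        np.transpose(b.R, (0, 2, 1)),
        b.acc + np.einsum("nab,b->na", rotational_term(b.omega, b.omega_dot), p_b),
    )
    return np.linalg.norm(lhs - rhs, axis=1)
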