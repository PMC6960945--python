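import numpy as np
import pytest

from imujoint.heading import (
    ConstraintInputs,
    ConstraintMeasurement,
    HeadingState,
    TooShortSeriesError,
    build_measurement,
    compute_C,
    differentiate_gyro,
    error_covariance,
    heading_predict,
    heading_update,
    is_dynamic,
    lambda_matrices,
    measurement_noise_cov,
)
from imujoint.rotations import rodrigues, skew

SA, SG, SGD = 14.8e-3, 1.5e-3, 25.3e-3


def truth_inputs(trial, k):
    """Constraint inputs built from noiseless simulator truth (analytic wdot)."""
    cfg, truth, imu_i, imu_j = trial
    li, lj = truth.link_i, truth.link_j
    C_i = compute_C(imu_i.acc[k], imu_i.gyro[k], li.omega_dot[k], cfg.p_i)
    C_j = compute_C(imu_j.acc[k], imu_j.gyro[k], lj.omega_dot[k], cfg.p_j)
    lam1_i, lam2_i = lambda_matrices(imu_i.gyro[k], cfg.p_i)
    lam1_j, lam2_j = lambda_matrices(imu_j.gyro[k], cfg.p_j)
    return ConstraintInputs(
        C_i=C_i, C_j=C_j,
        lam1_i=lam1_i, lam2_i=lam2_i, lam1_j=lam1_j, lam2_j=lam2_j,
        Z_i=li.Z[k], Z_j=lj.Z[k], P_Zi=np.zeros((3, 3)), P_Zj=np.zeros((3, 3)),
        X_i=li.X[k], X_j=lj.X[k],
    )


class TestPredict:
    def test_zero_rate_is_noop(self):
        st = HeadingState(X=np.array([1.0, 0, 0]), P=0.01 * np.eye(3))
        out = heading_predict(st, np.zeros(3), 0.01, SG)
        assert np.allclose(out.X, st.X)

    def test_process_noise_matches_monte_carlo(self):
        # Q = E(w w^T) for w = dt * (-skew(X)) n_G
        rng = np.random.default_rng(21)
        X = np.array([0.6, -0.3, 0.2])
        X /= np.linalg.norm(X)
        dt = 0.01
        n = rng.normal(0.0, SG, size=(100_000, 3))
        w = dt * (-np.cross(np.broadcast_to(X, n.shape), n))
        q_mc = w.T @ w / len(w)
        xs = skew(X)
        q = dt**2 * SG**2 * (xs @ xs.T)
        assert np.linalg.norm(q - q_mc) / np.linalg.norm(q_mc) < 0.05

    def test_constant_rate_tracks_closed_form(self):
        w = np.array([0.0, 0.0, 1.2])
        dt = 0.01
        st = HeadingState(X=np.array([1.0, 0, 0]), P=np.eye(3) * 1e-4)
        for _ in range(200):
            st = heading_predict(st, w, dt, SG)
        expected = rodrigues(-2.0 * w) @ np.array([1.0, 0, 0])
        assert np.linalg.norm(st.X - expected) < 1e-10


class TestComputeC:
    def test_reduces_to_accelerometer_without_rotation(self):
        y_A = np.array([1.0, 2.0, 3.0])
        assert np.array_equal(compute_C(y_A, np.zeros(3), np.zeros(3), [0.5, 0, 0]), y_A)
        assert np.array_equal(
            compute_C(y_A, [1.0, 2, 3], [0.1, 0, 0], np.zeros(3)), y_A
        )

    def test_centripetal_term(self):
        C = compute_C(np.zeros(3), [0, 0, 1.0], np.zeros(3), [1.0, 0, 0])
        assert np.allclose(C, [-1.0, 0, 0])


class TestDifferentiateGyro:
    def test_constant_series_gives_zero(self):
        y = np.tile([0.3, -0.2, 0.1], (10, 1))
        assert np.allclose(differentiate_gyro(y, 0.01), 0.0)

    def test_linear_series_exact_at_interior(self):
        t = np.arange(20) * 0.01
        y = np.outer(t, [2.0, -1.0, 0.5])
        d = differentiate_gyro(y, 0.01)
        assert np.allclose(d, [2.0, -1.0, 0.5], atol=1e-10)

    def test_sinusoid_against_analytic_derivative(self):
        t = np.arange(0, 2.0, 0.01)
        y = np.column_stack([np.sin(2 * np.pi * t)] * 3)
        d = differentiate_gyro(y, 0.01)
        exact = np.column_stack([2 * np.pi * np.cos(2 * np.pi * t)] * 3)
        assert np.abs(d[1:-1] - exact[1:-1]).max() < 1e-2

    def test_too_short_series_rejected(self):
        with pytest.raises(TooShortSeriesError):
            differentiate_gyro(np.zeros((2, 3)), 0.01)


class TestMeasurementModel:
    def test_residual_zero_at_true_state(self, noiseless_trial):
        for k in (800, 1200, 1800):
            ci = truth_inputs(noiseless_trial, k)
            z, H = build_measurement(ci)
            resid = z - H @ noiseless_trial[1].link_j.X[k]
            assert np.abs(resid).max() < 1e-8

    def test_zero_joint_acceleration_gives_null_measurement(self):
        ci = ConstraintInputs(
            C_i=np.zeros(3), C_j=np.zeros(3),
            lam1_i=np.zeros((3, 3)), lam2_i=np.zeros((3, 3)),
            lam1_j=np.zeros((3, 3)), lam2_j=np.zeros((3, 3)),
            Z_i=np.array([0, 0, 1.0]), Z_j=np.array([0, 0, 1.0]),
            P_Zi=np.zeros((3, 3)), P_Zj=np.zeros((3, 3)),
            X_i=np.array([1.0, 0, 0]), X_j=np.array([1.0, 0, 0]),
        )
        z, H = build_measurement(ci)
        assert np.all(z == 0) and np.all(H == 0)

    def test_static_gravity_only_residual_zero(self):
        # both links at rest: C = g Z, and z - H X vanishes at the truth
        rng = np.random.default_rng(13)
        for _ in range(5):
            Ri = rodrigues(rng.normal(size=3))
            Rj = rodrigues(rng.normal(size=3))
            ci = ConstraintInputs(
                C_i=9.81 * Ri[2], C_j=9.81 * Rj[2],
                lam1_i=np.zeros((3, 3)), lam2_i=np.zeros((3, 3)),
                lam1_j=np.zeros((3, 3)), lam2_j=np.zeros((3, 3)),
                Z_i=Ri[2], Z_j=Rj[2], P_Zi=np.zeros((3, 3)), P_Zj=np.zeros((3, 3)),
                X_i=Ri[0], X_j=Rj[0],
            )
            z, H = build_measurement(ci)
            assert np.abs(z - H @ Rj[0]).max() < 1e-12
            assert not is_dynamic(ci.C_i, ci.C_j, ci.Z_i, ci.Z_j)


class TestNoiseCovariance:
    def test_zero_noise_zero_attitude_cov_gives_zero(self, noiseless_trial):
        ci = truth_inputs(noiseless_trial, 1000)
        M = measurement_noise_cov(ci, 0.0, 0.0, 0.0)
        assert np.abs(M).max() < 1e-15

    def test_collocated_sensors_give_twice_accel_variance(self):
        # p = 0 kills the lever-arm terms; unit-norm headings leave 2 sigma_a^2
        z = np.array([0.0, 0, 1])
        x = np.array([1.0, 0, 0])
        ci = ConstraintInputs(
            C_i=np.array([1.0, 2, 9.0]), C_j=np.array([0.5, -1, 9.5]),
            lam1_i=np.zeros((3, 3)), lam2_i=np.zeros((3, 3)),
            lam1_j=np.zeros((3, 3)), lam2_j=np.zeros((3, 3)),
            Z_i=z, Z_j=z, P_Zi=np.zeros((3, 3)), P_Zj=np.zeros((3, 3)),
            X_i=x, X_j=x,
        )
        M = measurement_noise_cov(ci, SA, SG, SGD)
        assert M[0, 0] == pytest.approx(2 * SA**2, rel=1e-9)

    def test_matches_monte_carlo(self, noiseless_trial):
        rng = np.random.default_rng(99)
        ci = truth_inputs(noiseless_trial, 1500)
        ci.P_Zi = 1e-4 * np.eye(3)
        ci.P_Zj = 2e-4 * np.eye(3)
        M = measurement_noise_cov(ci, SA, SG, SGD)
        N = 100_000
        def eps(lam1, lam2):
            return (
                rng.normal(0, SA, (N, 3))
                + rng.normal(0, SG, (N, 3)) @ lam1.T
                + rng.normal(0, SGD, (N, 3)) @ lam2.T
            )
        e_i, e_j = eps(ci.lam1_i, ci.lam2_i), eps(ci.lam1_j, ci.lam2_j)
        ze_i = rng.multivariate_normal(np.zeros(3), ci.P_Zi, N)
        ze_j = rng.multivariate_normal(np.zeros(3), ci.P_Zj, N)
        v1 = e_i @ ci.X_i - e_j @ ci.X_j
        v2 = (
            np.cross(ze_i, ci.X_i) @ ci.C_i
            + e_i @ (skew(ci.Z_i) @ ci.X_i)
            - np.cross(ze_j, ci.X_j) @ ci.C_j
            - e_j @ (skew(ci.Z_j) @ ci.X_j)
        )
        V = np.vstack([v1, v2])
        M_mc = V @ V.T / N
        assert np.linalg.norm(M - M_mc) / np.linalg.norm(M_mc) < 0.05


class TestUpdate:
    def _meas(self, z, H, M):
        return ConstraintMeasurement(z=np.asarray(z, float), H=np.asarray(H, float),
                                     M=np.asarray(M, float))

    def test_zero_innovation_is_noop(self):
        st = HeadingState(X=np.array([1.0, 0, 0]), P=0.01 * np.eye(3))
        H = np.array([[0.0, 3.0, 1.0], [0.5, -1.0, 2.0]])
        meas = self._meas(H @ st.X, H, 1e-4 * np.eye(2))
        out, skipped = heading_update(st, meas)
        assert not skipped
        assert np.allclose(out.X, st.X, atol=1e-12)

    def test_uninformative_measurement_leaves_state(self):
        st = HeadingState(X=np.array([1.0, 0, 0]), P=0.01 * np.eye(3))
        H = np.array([[0.0, 3.0, 1.0], [0.5, -1.0, 2.0]])
        meas = self._meas([5.0, -2.0], H, 1e12 * np.eye(2))
        out, skipped = heading_update(st, meas)
        assert not skipped
        assert np.linalg.norm(out.X - st.X) < 1e-6

    def test_correction_reduces_yaw_error(self, noiseless_trial):
        cfg, truth, _, _ = noiseless_trial
        k = 1500
        ci = truth_inputs(noiseless_trial, k)
        X_true = truth.link_j.X[k]
        Z_j = truth.link_j.Z[k]
        X_off = rodrigues(np.deg2rad(5.0) * Z_j) @ X_true  # 5 deg yaw offset
        ci.X_j = X_off
        z, H = build_measurement(ci)
        M = measurement_noise_cov(ci, SA, SG, SGD)
        st = HeadingState(X=X_off, P=np.deg2rad(5.0) ** 2 * np.eye(3))
        out, skipped = heading_update(st, ConstraintMeasurement(z=z, H=H, M=M))
        assert not skipped
        err_before = np.arccos(np.clip(X_off @ X_true, -1, 1))
        err_after = np.arccos(np.clip(out.X @ X_true, -1, 1))
        assert err_after < err_before

    def test_singular_innovation_skipped_with_warning(self, caplog):
        st = HeadingState(X=np.array([1.0, 0, 0]), P=np.zeros((3, 3)))
        meas = self._meas([0.1, 0.2], np.zeros((2, 3)), np.zeros((2, 2)))
        with caplog.at_level("WARNING", logger="imujoint.heading"):
            out, skipped = heading_update(st, meas)
        assert skipped
        assert np.array_equal(out.X, st.X)
        assert any("skipped" in r.message for r in caplog.records)

    def test_static_joint_flagged_not_dynamic(self):
        z = np.array([0.0, 0, 1.0])
        assert not is_dynamic(9.81 * z + 0.05, 9.81 * z - 0.05, z, z)
        assert is_dynamic(9.81 * z + np.array([1.0, 0, 0]), 9.81 * z, z, z)


def test_error_covariance_lambda_switch():
    lam1 = np.diag([1.0, 2.0, 3.0])
    lam2 = -np.eye(3)
    s_default = error_covariance(SA, SG, SGD, lam1, lam2)
    s_alt = error_covariance(SA, SG, SGD, lam1, lam2, gdot_term_uses_lambda1=True)
    assert np.allclose(
        s_alt - s_default, SGD**2 * (lam1 @ lam1.T - lam2 @ lam2.T)
    )
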