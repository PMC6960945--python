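import numpy as np
import pytest

from imujoint.pipeline import PipelineConfig
from imujoint.simulate import SimConfig, simulate_truth, synthesize_imu


@pytest.fixture(scope="session")
def noiseless_trial():
    """Short noiseless dynamic two-link trial with its IMU streams."""
    cfg = SimConfig(duration=20.0, sigma_a=0.0, sigma_g=0.0, seed=11)
    truth = simulate_truth(cfg)
    imu_i, imu_j = synthesize_imu(truth)
    return cfg, truth, imu_i, imu_j


@pytest.fixture(scope="session")
def noisy_trial():
    """Short trial at the reference sensor-noise levels."""
    cfg = SimConfig(duration=30.0, seed=12)
    truth = simulate_truth(cfg)
    imu_i, imu_j = synthesize_imu(truth)
    return cfg, truth, imu_i, imu_j


def exact_init_config(cfg: SimConfig, truth, **overrides) -> PipelineConfig:
    """Pipeline config with initial states taken from simulator truth."""
    defaults = dict(
        p_i=cfg.p_i,
        p_j=cfg.p_j,
        dt=cfg.dt,
        init_Z_i=tuple(truth.link_i.Z[0]),
        init_X_i=tuple(truth.link_i.X[0]),
        init_Z_j=tuple(truth.link_j.Z[0]),
        init_X_j=tuple(truth.link_j.X[0]),
    )
    defaults.update(overrides)
    return PipelineConfig(**defaults)


def max_angle_err_deg(est_series, truth_euler: np.ndarray) -> float:
    """Largest wrapped per-angle error (deg) over a joint-angle series."""
    errs = []
    for est, tru in (
        (est_series.alpha, truth_euler[:, 0]),
        (est_series.beta, truth_euler[:, 1]),
        (est_series.gamma, truth_euler[:, 2]),
    ):
        d = (np.asarray(est) - tru + np.pi) % (2 * np.pi) - np.pi
        errs.append(np.rad2deg(np.abs(d)).max())
    return max(errs)
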