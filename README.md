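# imujoint

Magnetometer-free 3-D joint-angle estimation from a pair of body-worn IMUs.

Estimating 3-D joint angles (knee, elbow, shoulder, or any ball-and-socket
linkage) from inertial sensors normally needs a magnetometer to pin down
heading — and magnetometers fail wherever the magnetic field is disturbed:
indoors, near motors, tools, wheelchairs, exoskeletons. `imujoint`
implements a sequential DCM-based orientation Kalman filter in which the
magnetometer is replaced by the *kinematic constraint of the joint itself*:
for a spherical joint, the joint-center acceleration computed from either
link's IMU must agree,

```
R_i (a_i + (ω̇̃_i + ω̃_i ω̃_i) p_i)  =  R_j (a_j + (ω̇̃_j + ω̃_j ω̃_j) p_j)
```

where `p` is the constant sensor-to-joint-center vector and `R` the link
DCM with rows `[X_S, Y_S, Z_S]` (heading, lateral, attitude). Per link and
time step the filter runs

1. an **attitude KF** for `Z_S`: gyro strapdown prediction, accelerometer
   update with a first-order Gauss–Markov external-acceleration model
   (`c_a1 = 0.1`, `c_a2 = 0.05`);
2. a **heading KF** for `X_S`: strapdown prediction
   `X⁻ = (I − Δt ω̃)X`, and — for the following link only — a correction from
   the constraint written as a 2-D linear measurement `z = H X_j + v`,
   `z = [C_i·X_i⁻ ; C_i·(Z̃_i⁺X_i⁻)]`, `H = [C_jᵀ ; C_jᵀ Z̃_j⁺]` with
   `C = y_A + (ω̇̃ + ω̃ω̃)p` and a fully propagated 2×2 noise covariance.

The joint angle is the Z-Y-X Euler triplet (yaw α, pitch β, roll γ) of
`R_ij = R_iᵀ R_j`. Per-link yaw is free to drift (absolute heading is
unobservable without a magnetometer); the *joint* angle is drift-free as
long as the joint is in motion. The package targets biomechanists and
robotics engineers who need drift-free relative orientation in arbitrary
magnetic environments, and ships with:

* a kinematically exact two-link / n-link motion and IMU simulator
  (`imujoint.simulate`) — the constraint holds to machine precision on the
  generated truth, making every stage testable without hardware;
* least-squares identification of the sensor-to-joint vectors from a
  dynamic trial (`imujoint.calibration`);
* three estimator variants for controlled comparison: `proposed`,
  `prediction_only` (no heading correction — shows the drift), and
  `oracle_attitude` (externally supplied attitude — isolates heading error);
* an n-link chain mode that propagates the correction recursively along the
  chain;
* RMSE evaluation, CSV/YAML/JSON I/O, and a CLI
  (`imujoint simulate|estimate|calibrate|evaluate`).

## Worked example

A 180 s simulated trial at 100 Hz with realistic sensor noise
(accelerometer 14.8 mm/s², gyro 1.5 mrad/s) and a constant 0.2 °/s gyro
bias — the situation in which a magnetometer-free method must prove itself:

```python
import numpy as np
from imujoint import (PipelineConfig, SimConfig, estimate_joint_vectors,
                      rmse_euler, simulate_truth, synthesize_imu)
from imujoint.pipeline import run

bias = np.deg2rad(0.2)          # 0.2 deg/s constant gyro bias on both links
cfg = SimConfig(duration=180.0, seed=42,
                gyro_bias_i=( bias/np.sqrt(3),)*3,
                gyro_bias_j=(-bias/np.sqrt(3),)*3)
truth = simulate_truth(cfg)
imu_i, imu_j = synthesize_imu(truth)

sgp = float(np.sqrt(cfg.sigma_g**2 + bias**2))   # Q absorbs the known bias
for method in ("proposed", "prediction_only"):
    pcfg = PipelineConfig(p_i=cfg.p_i, p_j=cfg.p_j, dt=cfg.dt,
                          method=method, sigma_g_process=sgp)
    est = run(imu_i, imu_j, pcfg)
    rep = rmse_euler(est, truth.joint_euler)
    print(f"{method:15s} joint RMSE: roll {rep.roll:.2f}  pitch {rep.pitch:.2f}  "
          f"yaw {rep.yaw:.2f}  average {rep.average:.2f} deg")

cal = estimate_joint_vectors(imu_i, imu_j)
print("calibrated p_i (m):", np.round(cal.p_i, 4), " true:", cfg.p_i)
```

Output:

```
proposed        joint RMSE: roll 2.33  pitch 1.75  yaw 1.28  average 1.79 deg
prediction_only joint RMSE: roll 5.91  pitch 5.85  yaw 20.82  average 10.86 deg
calibrated p_i (m): [ 0.498  -0.001  -0.0309]  true: (0.498, -0.001, -0.031)
```

Without the constraint correction the relative yaw drifts with the gyro bias
(20.8° RMSE over three minutes); with it, the joint angle stays within a few
degrees — while both links' *absolute* yaws drift by tens of degrees, which
is by design. The calibration recovers the half-metre sensor-to-joint
vectors to well under a millimetre.

The same workflow from the shell:

```sh
imujoint simulate --out trial/ --seed 42
imujoint calibrate --imu-i trial/imu_i.csv --imu-j trial/imu_j.csv --out calib.json
imujoint estimate  --imu-i trial/imu_i.csv --imu-j trial/imu_j.csv \
                   --method proposed --out angles.csv
imujoint evaluate  --est angles.csv --truth trial/truth_angles.csv --out report.json
```

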