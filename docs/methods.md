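# Methods

## Problem and model

Two rigid links are joined by a spherical (ball-and-socket) joint. Each link
carries an IMU (triaxial gyroscope + accelerometer) whose frame is taken to
coincide with the link frame. The sensor models are

    y_G = ω + n_G            (rad/s)
    y_A = g·Z_S + a + n_A    (m/s², Z-up inertial frame)

with white Gaussian noises n_G, n_A, body angular rate ω, external (i.e.
non-gravitational) acceleration a, and Z_S the attitude vector — the inertial
vertical written in sensor coordinates. Orientations are direction cosine
matrices stored as `R = [X_S, Y_S, Z_S]^T`, rows being the inertial axes in
sensor coordinates, so `R v_sensor = v_inertial`. The first row X_S is the
heading vector; the 3-D joint angle is the Z-Y-X Euler decomposition
(yaw α, pitch β, roll γ) of the relative DCM `R_ij = R_i^T R_j`.

The estimator is a *sequential* DCM-based Kalman filter per link: an attitude
filter for Z_S, then a heading filter for X_S. The point of the method is the
heading correction: instead of a magnetometer (useless in magnetically
disturbed environments), it uses the kinematic constraint that the joint
center's acceleration is the same whichever link's IMU computes it:

    R_i (a_i + (skew(ω̇_i) + skew(ω_i)²) p_i)
      = R_j (a_j + (skew(ω̇_j) + skew(ω_j)²) p_j),

where p is the constant sensor-to-joint-center vector. Substituting the
sensor models gives the measurable vector
`C = y_A + (skew(ẏ_G) + skew(y_G)²) p` with error
`ε = n_A + λ₁ n_G + λ₂ ṅ_G`, `λ₁ = skew(p)skew(y_G) − 2 skew(y_G)skew(p)`,
`λ₂ = −skew(p)`. Projecting the constraint onto the X and Y (= Z×X) rows of
the DCMs yields two scalar equations linear in X_j:

    z = [C_i·X_i⁻ ;  C_i·(Z̃_i⁺ X_i⁻)],   H = [C_j^T ;  C_j^T Z̃_j⁺],

a standard 2-dimensional KF correction `z = H X_j + v`. The 2×2 covariance
M of v propagates both links' ε covariances
(`Σ = σ_A² I + σ_G² λ₁λ₁^T + σ_Ġ² λ₂λ₂^T`) and the a-posteriori attitude
covariances through the terms `−C^T X̃ P_Z X̃ C`; products of error terms are
neglected. Only link *j* is corrected; link *i*'s heading is pure strapdown
prediction. This is deliberate: the absolute heading of the pair is
unobservable without a magnetometer, and only the relative orientation (the
joint angle) matters — per-link yaw may drift while the joint angle does not.
For an n-link chain the same correction propagates recursively: link 1
predicts only, link k+1 is corrected against link k.

## Filter stages and their parameters

**Attitude filter** (per link). Prediction is strapdown integration of the
gyro; the update treats the accelerometer as a gravity reference with a
first-order Gauss–Markov model for the external acceleration:
`a_hat⁻ = c_a1 a_hat⁺`, measurement variance
`σ_A² + c_a2² ‖y_A − g Z⁻ − a_hat⁻‖²` (isotropic), and re-anchoring
`a_hat⁺ = y_A − g Z⁺` after the update. Defaults `c_a1 = 0.1`, `c_a2 = 0.05`.
This variant intentionally avoids state augmentation; it is accurate to a few
tenths of a degree in quiet motion and degrades to 1–4° under sustained
multi-m/s² low-frequency acceleration — which the validation harness
reproduces and which is why the oracle-attitude variant exists as a
reference. A known consequence: the filter must not be *started* mid-motion
with a loose prior, or the first high-gain updates swallow external
acceleration as attitude error; the simulator therefore ramps motion from
rest (see below), matching how physical trials begin.

**Heading filter.** Prediction `X⁻ = Φ X⁺` with
`Q = Δt² σ_G² X̃ X̃^T` (the covariance of `Δt(−X̃)n_G` for discrete white
noise; a `process_noise_dt_power=1` switch selects the spectral-density
convention). The constraint correction is applied only when the joint is
dynamically excited (below).

Default noise parameters (SI): `σ_A = 14.8e-3` m/s², `σ_G = 1.5e-3` rad/s,
`σ_Ġ = 25.3e-3` rad/s². The derivative noise is a direct input, not derived
from the difference scheme. `σ_Ġ` is smaller than the nominal amplification
of central differences at 100 Hz (≈ σ_G·√2/2Δt ≈ 0.1 rad/s²); it behaves as
an effective tuning value and is kept as the reference default.

`sigma_g_process` (default = `σ_G`) sets the gyro-rate uncertainty driving
Q in both filters. The filters carry no gyro-bias state by design; when a
constant bias b is expected, setting
`sigma_g_process = sqrt(σ_G² + ‖b‖²)` lets the correction track the
bias-induced heading drift. The bias-injection studies in the test suite use
exactly this inflation.

## Numerical choices

* **Transition matrix.** `exp(−Δt ỹ_G)` (Rodrigues), not the first-order
  `I − Δt ỹ_G`. The renormalized first-order map drifts secularly toward the
  rotation equator by ≈ (Δt‖ω‖)²/2 per step — ~0.1–0.3°/s at manual-motion
  rates — which would dominate every error budget. The first-order form
  remains available (`transition="first_order"`); the linearization is still
  what the covariance algebra assumes.
* **Gyro integral per step** (`gyro_timing`): default `"quadratic"` — the
  integral of a quadratic fit through samples {t−2Δt, t−Δt, t} over the last
  step, plus the two-sample coning term `Δt²/12 (ω_{k−1} × ω_k)`. Causal, and
  reduces strapdown drift from ~0.09°/min (trapezoid) to ~1e-4 °/min at
  100 Hz. `"midpoint"` and `"left"` are available for comparison.
* **Gyro derivative.** Central differences (`np.gradient`), one-sided at the
  ends. The estimate at step t therefore consumes sample t+1: the pipeline is
  real-time up to one sample (10 ms) of latency. Analytic angular
  accelerations can be supplied (`gyro_dot=`) to remove both latency and
  truncation error; the truth-level consistency checks do this.
* **Renormalization.** Z and X are renormalized after every predict and
  update; covariances are not rescaled. P matrices are symmetrized each step;
  M's eigenvalues are floored at 1e-12·trace.
* **Dynamic-condition gate.** The constraint carries heading information only
  when the joint accelerates: at rest C = g·Z on both links and both
  measurement rows annihilate yaw perturbations. Updates are skipped (flagged,
  logged) when `‖C − g Ẑ⁺‖` is below `dynamic_accel_threshold`
  (default 0.2 m/s²) on both links, or when the innovation covariance's
  condition number exceeds 1e12. Static periods therefore coast on the gyro —
  the method's stated operating limitation; stationary-period aids
  (zero-velocity updates) are out of scope.
* **Gimbal lock.** At |β| = π/2 the Z-Y-X split is not unique; γ := 0 by
  convention and the sample is flagged. Recomposition remains exact.
* **Euler sign conventions.** `R_ij = R_z(α) R_y(β) R_x(γ)` with
  α = atan2(R₂₁, R₁₁), β = −asin(R₃₁), γ = atan2(R₃₂, R₃₃).

## Initialization

Z₀ from the first accelerometer sample (static start), with a 5° isotropic
prior; X₀ as the inertial x-axis projected orthogonal to Z₀, 10° prior. The
absolute heading is unobservable, so an arbitrary X₀ convention is fine for
the joint angle provided the *relative* initial heading is right; trials that
start at rest with zero joint deflection satisfy this automatically. Tests of
noiseless exactness use truth initial states with priors matched to that
knowledge (1e-3°).

## Synthetic data: what it emulates, and what it does not

The generator emulates the validation protocol: a rigid two-link (or n-link)
pendulum pair with ~0.5 m sensor-to-joint vectors
(p_i = [49.8, −0.1, −3.1] cm, p_j = [51.2, 0.1, −2.7] cm), rotated
dynamically for 180 s at 100 Hz while the joint center translates, with white
Gaussian sensor noise at the reference levels and optional constant gyro
bias. Orientations, angular rates, angular accelerations and specific forces
are generated analytically (or by RK4 with re-orthonormalization in the
"independent" mode), so the spherical-joint acceleration identity holds to
roundoff — this exactness is the oracle every downstream test leans on.

Two motion modes:

* `"bounded"` (default): the base link rocks through bounded Euler-angle
  sinusoids (8–18° per component, 0.15–0.55 Hz) about a random fixed yaw, and
  the joint's own Euler angles follow bounded sinusoids (5–15°), with the
  second link's kinematics derived exactly. This mirrors a hand-held rig:
  links swing tens of degrees but do not tumble, and the joint stays clear of
  the β = ±90° Euler singularity where per-angle errors are meaningless.
* `"independent"`: both links tumble freely (integrated sum-of-sinusoids body
  rates). Harsher and less physical for a connected pair; relative pitch then
  visits the Euler singularity.

The joint center translates with 4–10 cm sinusoids at 0.3–0.9 Hz, giving
sensor external accelerations of ~1.5–4 m/s² mean — the magnitude range of
the reference experiments — and, importantly, horizontal joint-center
acceleration of ~1–3 m/s², which is the signal the heading correction
observes yaw through. All motion ramps from exact rest over the first 5 s
(C² smootherstep envelope).

Not modelled: gyro/accelerometer scale-factor and misalignment errors,
bias random walk (only constant bias), soft-tissue artefact, joint-center
migration, magnetic fields (no magnetometer exists in this package),
temperature effects, sampling jitter. Passing tests therefore demonstrate
algorithmic correctness and noise/bias behaviour under ideal rigid-body
kinematics, not end-to-end accuracy on human segments.

## Problem sizes used in validation

Truth-level consistency uses 10 s trials; noiseless recovery 60 s; the
drift/bias comparisons 180 s (the full protocol length); the method-ordering
comparison five 120 s seeds; calibration ten 180 s seeds; Monte-Carlo
covariance checks 1e5 draws. These sizes make every behaviour of interest
(drift growth, lag saturation, sub-mm calibration) clearly visible while the
whole suite stays fast.

## Calibration

`estimate_joint_vectors` identifies (p_i, p_j) from a dynamic trial by
minimizing Σ_t (‖C_i(p_i)‖ − ‖C_j(p_j)‖)² — the norm of the joint-center
acceleration (gravity included) is frame-invariant, so no orientation
estimate is needed. The residual is a norm difference of affine functions of
p; a Levenberg-damped Gauss–Newton iteration with the analytic Jacobian
(init 0, multiplicative damping adaptation, step-norm tolerance 1e-6 m)
converges in ~4 accepted steps. Because calibration is offline, the gyro
derivative uses a Savitzky–Golay filter (cubic, 15 samples); raw central
differences leave several-mm errors at 100 Hz noise levels. Requires mean
‖y_G‖ ≥ 0.3 rad/s on both links (at rest every p fits equally well).
Recovery at the reference conditions: < 0.01 mm noiseless, ~1 mm noisy
worst-case over ten 180 s trials.

## Known limitations

* The simplified (non-augmented) Gauss–Markov attitude stage is the accuracy
  bottleneck under sustained large external acceleration; the
  oracle-attitude variant quantifies the gap (average joint RMSE ~0.5° vs
  ~1.7° at reference conditions with 0.2°/s bias).
* Static or low-acceleration periods provide no heading information; yaw
  coasts and drifts with gyro bias until motion resumes.
* Heading-tracking of a gyro-bias drift has a lag proportional to the bias
  rate and inversely related to the horizontal joint-center acceleration;
  weakly translated joints degrade gracefully but measurably.
* The measurement model treats the attitude error's contribution to the
  constraint as white noise (per-sample covariance propagation), though it is
  in truth slowly varying; this is inherited from the linearized formulation.
* One-sample output latency from the central-difference gyro derivative.
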