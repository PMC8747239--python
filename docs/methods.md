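# Methods

## Problem and model

`gaitlstm` estimates the sagittal-plane hip, knee and ankle angles of a
walking person from a single inertial measurement unit (IMU) strapped to the
lateral shank, sampling at only 23 Hz. The estimator is a single-layer LSTM
that maps a short sliding window (5 samples ≈ 0.22 s) of up to nine IMU
channels — fused attitude (pitch, roll, yaw), 3-axis gyroscope and 3-axis
accelerometer — to the three joint angles at the window's last sample.
Reference kinematics come from a 60 Hz motion-capture-grade source and are
treated as ground truth.

The training loss is a weighted sum of per-joint mean squared errors,

    L = A·MSE_hip + B·MSE_knee + C·MSE_ankle,   (A, B, C) = (3, 1, 4),

optimized with Adam (learning rate 0.001, batch size 256). Input features
are min-max scaled to [0, 1] using statistics of the training fold only;
output angles are regressed in degrees and never normalized.

## Synthetic cohort generator

Because the kind of paired shank-IMU / optical-kinematics dataset this
pipeline consumes is rarely public, the package ships a generator that
produces cohorts with the statistical structure the estimator relies on:

* **Joint-angle templates.** Each joint's cycle-normalized trajectory is a
  6-harmonic Fourier series fitted to normative sagittal gait curves (hip
  roughly −12…30°, knee 3…63°, ankle −14…8°). Fourier form guarantees
  periodicity, so concatenated cycles are seamless.
* **Subjects.** Walking speed ~ N(1.27, 0.13²) m/s and cadence
  ~ N(113.87, 7.32²) steps/min (clipped at 0.5 m/s, 60 steps/min); stride
  length is derived so speed = stride × cadence/120 holds exactly. Each
  subject perturbs every joint template with an amplitude scale
  (σ = 0.08), an offset (σ = 2°) and a phase shift (σ = 0.02 cycles) —
  this inter-subject variability is what separates the three evaluation
  schemes.
* **Forward kinematics.** The leg is a planar two-segment chain with the
  trunk vertical, so thigh inclination equals hip flexion and shank
  inclination is φ = hip − knee. The hip point advances at constant speed
  with 2 cm vertical / 1 cm fore-aft oscillations at stride and
  double-stride frequency. The sensor sits 10 cm below the knee on the
  shank; its specific force (acceleration minus gravity, rotated into the
  sensor frame, in g) and angular rate dφ/dt are computed by central
  finite differences on a 460 Hz internal grid (20× the IMU rate, giving
  ~3·10⁻⁵ relative derivative error), then decimated exactly to 23 Hz.
* **Channel model.** Sensor x is longitudinal (distal), y anterior, z
  mediolateral: pitch = φ + noise (σ 0.5°), gyro z = dφ/dt + noise
  (σ 1 °/s), accel x/y = sagittal specific force + noise (σ 0.02 g). Gyro
  x/y carry 5 %/15 % mounting cross-talk of gyro z; accel z carries a small
  out-of-plane oscillation; roll is a ≤2° phase-locked wobble; yaw is pure
  noise (the designated uninformative channel for feature-selection
  checks). Accelerometer and gyro outputs are quantized to 0.01 g and
  0.05 °/s. Cycle durations jitter multiplicatively (σ = 3 %) and are
  snapped to a whole number of IMU samples so recorded cycle boundaries
  coincide exactly with samples (cadence error < 2 %).

What the generator does **not** emulate: 3-D kinematics, soft-tissue
artifact, sensor-to-segment misalignment, turning or non-steady gait,
ground-reaction events, or any mechanical coupling between ankle angle and
the shank sensor (in a rigid planar model there is none; the ankle is
predictable only through its phase-locking to the other joints, which
mirrors how a statistical estimator actually infers it). Passing tests on
synthetic cohorts therefore demonstrate pipeline correctness and the
qualitative train/test-similarity gradient, not field accuracy on real
recordings.

## Preprocessing

Reference angles are filtered with a zero-phase (forward–backward)
4th-order Butterworth low-pass at 4 Hz; zero-phase is standard for offline
kinematics and avoids shifting labels relative to IMU samples. IMU channels
are smoothed with a 5-sample running median (mirror edge padding), applied
per channel over the whole trial before cutting into cycles. Within each
cycle the 60 Hz labels are resampled to the cycle's IMU sample count; when
both streams share a clock (always true for generated data) the filtered
labels are interpolated at the actual IMU sample times, which avoids the
sub-sample phase offset of cutting at whole kinematic samples. A
count-based resampler on normalized cycle time is provided for clock-free
inputs. An optional segmenter recovers cycle boundaries from the
mediolateral gyro: it finds the prominent swing-phase peak and places the
boundary at the next positive-to-negative zero crossing (maximal forward
shank inclination, i.e. heel strike).

## Feature selection

For each joint, every channel is scored by the absolute Pearson correlation
with that joint's angle over all pooled training samples, normalized by the
per-joint maximum; channels above 30 % relative importance for at least one
joint form the input set (strict inequality, canonical channel order).
Correlations are computed on unnormalized features — Pearson r is
affine-invariant — and refitted inside every cross-validation fold.

## LSTM regressor: numerical choices

* The cell, backpropagation through time and Adam are implemented in NumPy
  (gradients are tested against finite differences). Training is
  single-threaded and fully deterministic given the run seed.
* Windows are left-padded by replicating the first sample so every label
  gets a prediction — the per-cycle NRMSE denominator needs the full
  trace. Hidden state is reset per window; windows never cross cycle
  boundaries.
* Initialization: per-gate Glorot uniform, forget-gate bias 1. The linear
  read-out is parameterized through a fixed per-joint affine target scaling
  (training-label mean and standard deviation) and initialized at its ridge
  least-squares optimum (λ = 10⁻⁵) given the initial hidden features. Both
  choices condition the optimization so that Adam at the fixed 0.001
  learning rate makes meaningful progress within small epoch budgets; the
  loss is always the weighted MSE in degrees, and every parameter remains
  trainable.
* No early stopping; a fixed epoch count (default 500, reducible for
  desk-scale runs). Non-finite losses abort with diagnostics.

## Evaluation

Three splits with k-fold CV (default k = 5): within-one-subject (each
subject's cycles partitioned; per-subject models; unweighted mean across
subjects), intra-subject (all cycles pooled and shuffled) and inter-subject
(disjoint subject groups; requires the subject count divisible by k, e.g.
30 → 5×6). Normalization statistics and feature selection are refitted on
each fold's training cycles only. Metrics per joint: RMSE pooled over a
fold's test samples, R² pooled per fold, and NRMSE computed per test cycle
as 100 × RMSE / (max − min of the *predicted* trace) then averaged
(cycles with zero predicted range are excluded with a warning; a flag
switches the denominator to the reference range). Fold, split and model
seeds are independent and recorded; identical configuration reproduces
reports bit-for-bit.

## Problem sizes used in shipped checks

The package's own end-to-end checks run at desk scale as a deliberate
choice: feature-selection recovery uses 20 seeded default cohorts
(30 subjects each); parameter recovery uses a noise-free cohort of
10 subjects × 16 cycles at 150 epochs; the scheme-ordering comparison and
the reproduction script use 10-subject default-noise cohorts at 60 epochs.
Aggregates are cross-fold (and cross-subject) means, the granularity at
which results are reported throughout.

## Known limitations

* Planar kinematics with a vertical trunk: no trunk lean, pelvis rotation
  or out-of-plane motion beyond the modelled wobble/cross-talk channels.
* The ankle channel of the generator is statistically, not mechanically,
  coupled to the sensor — ankle accuracy on synthetic data reflects
  phase-locking strength, and is the weakest joint, as expected.
* The LSTM is intentionally minimal (one layer, linear head); no
  architecture search or regularization beyond the small ridge in the
  read-out initialization.
* Per-cycle NRMSE with a predicted-range denominator rewards
  over-smoothed predictions slightly; the reference-range variant is one
  flag away.
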