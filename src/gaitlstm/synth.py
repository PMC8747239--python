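"""Synthetic gait cohort generator.

Produces paired recordings for a planar (sagittal-plane) walking model:
a 9-channel shank-mounted IMU stream at a low sampling rate (23 Hz) and a
reference hip/knee/ankle angle stream at motion-capture rate (60 Hz).

Joint-angle trajectories come from periodic Fourier-series templates of
normative gait; the IMU channels are derived from them by planar forward
kinematics of a two-segment leg (thigh + shank) with the sensor fixed on
the shank, 10 cm below the knee. The trunk is assumed vertical, so thigh
inclination from vertical equals hip flexion and shank inclination is
hip minus knee flexion.

Axis convention (fixed): sensor x is longitudinal (pointing distally down
the shank), y is anterior, z is mediolateral. Sagittal rotation therefore
appears on the z gyro, gravity and gait accelerations on the x/y
accelerometer, and shank inclination on the pitch attitude channel. Roll
carries a small phase-locked out-of-plane wobble; yaw is pure sensor noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: canonical 9-channel order used everywhere downstream
CHANNELS = ("pitch", "roll", "yaw", "gx", "gy", "gz", "ax", "ay", "az")
JOINTS = ("hip", "knee", "ankle")

GRAVITY = 9.80665  # m/s^2


# ---------------------------------------------------------------------------
# gait templates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaitTemplate:
    """Truncated Fourier series for one joint angle over normalized phase.

    angle(u) = a0 + sum_k a[k-1] cos(2 pi k u) + b[k-1] sin(2 pi k u), deg.
    Periodic by construction, so cycle boundaries are seamless.
    """

    joint: str
    a0: float
    a: tuple[float, ...]
    b: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.a) != len(self.b):
            raise ValueError("a and b must have the same number of harmonics")
        if self.joint not in JOINTS:
            raise ValueError(f"unknown joint {self.joint!r}")

    @property
    def n_harmonics(self) -> int:
        return len(self.a)

    def __call__(self, u: np.ndarray | float) -> np.ndarray | float:
        return joint_angle_template(u, self)


def joint_angle_template(u, template: GaitTemplate):
    """Evaluate a joint-angle template at phase ``u`` in [0, 1)."""
    u_arr = np.asarray(u, dtype=float)
    if np.any(u_arr < 0) or np.any(u_arr >= 1):
        raise ValueError("phase u must lie in [0, 1); wrap before calling")
    if not np.all(np.isfinite([template.a0, *template.a, *template.b])):
        raise ValueError("template coefficients must be finite")
    out = np.full_like(u_arr, template.a0, dtype=float)
    for k in range(1, template.n_harmonics + 1):
        w = 2 * np.pi * k * u_arr
        out = out + template.a[k - 1] * np.cos(w) + template.b[k - 1] * np.sin(w)
    if np.isscalar(u) or u_arr.ndim == 0:
        return float(out)
    return out


# Default templates: normative sagittal kinematics, phase 0 at heel strike.
# Hip stays within [-20, 40] deg, knee within [-5, 75], ankle within [-25, 20].
DEFAULT_TEMPLATES: dict[str, GaitTemplate] = {
    "hip": GaitTemplate("hip", 9.0, (21.0, 0.0, 0.0, 0.0, 0.0, 0.0),
                        (4.0, 0.0, 0.0, 0.0, 0.0, 0.0)),
    "knee": GaitTemplate(
        "knee", 16.028,
        (-0.390, -13.107, 3.203, 1.875, -1.984, -0.310),
        (-15.905, 8.745, 9.183, -2.835, -1.441, 0.287)),
    "ankle": GaitTemplate(
        "ankle", 0.284,
        (-1.655, 0.838, -2.645, 2.013, -0.926, -0.110),
        (3.625, -4.527, 1.545, -0.212, -1.655, 0.769)),
}


def template_derivative(u, template: GaitTemplate, period_s: float):
    """Analytic time derivative (deg/s) of a template traversed in ``period_s``."""
    u_arr = np.asarray(u, dtype=float)
    out = np.zeros_like(u_arr)
    for k in range(1, template.n_harmonics + 1):
        w = 2 * np.pi * k
        out = out + w * (-template.a[k - 1] * np.sin(w * u_arr)
                         + template.b[k - 1] * np.cos(w * u_arr))
    return out / period_s


# ---------------------------------------------------------------------------
# cohort configuration and subject profiles
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Cohort-level simulation settings.

    Defaults reproduce the acquisition setup being emulated: 30 subjects,
    16-20 overground gait cycles each, a 23 Hz 9-channel shank IMU with
    0.01 g / 0.05 deg/s resolution, and 60 Hz reference kinematics. Walking
    speed and cadence are drawn per subject around 1.27 +/- 0.13 m/s and
    113.87 +/- 7.32 steps/min; stride length follows from the identity
    speed = stride * cadence / 120.
    """

    n_subjects: int = 30
    min_cycles: int = 16
    max_cycles: int = 20
    imu_rate_hz: float = 23.0
    kin_rate_hz: float = 60.0
    accel_resolution_g: float = 0.01
    gyro_resolution_dps: float = 0.05
    seed: int = 0

    speed_mean_mps: float = 1.27
    speed_sd_mps: float = 0.13
    cadence_mean_spm: float = 113.87
    cadence_sd_spm: float = 7.32

    thigh_mean_m: float = 0.42
    thigh_sd_m: float = 0.02
    shank_mean_m: float = 0.40
    shank_sd_m: float = 0.02

    # per-joint template perturbation spreads (zero-mean draws)
    amp_scale_sd: float = 0.08
    offset_sd_deg: float = 2.0
    phase_sd: float = 0.02

    accel_noise_g: float = 0.02
    gyro_noise_dps: float = 1.0
    attitude_noise_deg: float = 0.5
    cycle_jitter: float = 0.03  # multiplicative SD of cycle duration

    oversample: int = 20  # internal grid = oversample * imu_rate

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not (1 <= self.min_cycles <= self.max_cycles):
            raise ValueError("need 1 <= min_cycles <= max_cycles")
        if self.imu_rate_hz <= 0 or self.kin_rate_hz <= 0:
            raise ValueError("sampling rates must be positive")
        if self.accel_resolution_g < 0 or self.gyro_resolution_dps < 0:
            raise ValueError("resolutions must be >= 0")
        if self.oversample < 2:
            raise ValueError("oversample must be >= 2")

    def noise_free(self) -> "CohortConfig":
        """Copy with all sensor noise and cycle-duration jitter removed."""
        d = asdict(self)
        d.update(accel_noise_g=0.0, gyro_noise_dps=0.0,
                 attitude_noise_deg=0.0, cycle_jitter=0.0,
                 accel_resolution_g=0.0, gyro_resolution_dps=0.0)
        return CohortConfig(**d)


@dataclass
class JointPerturbation:
    amp_scale: float = 1.0
    offset_deg: float = 0.0
    phase_shift: float = 0.0


@dataclass
class SubjectProfile:
    """One subject's gait parameters and sensor-noise levels."""

    subject_id: int
    speed_mps: float
    cadence_spm: float
    stride_m: float
    thigh_m: float
    shank_m: float
    sensor_offset_m: float = 0.10
    perturbations: dict[str, JointPerturbation] = field(
        default_factory=lambda: {j: JointPerturbation() for j in JOINTS})
    accel_noise_g: float = 0.02
    gyro_noise_dps: float = 1.0
    attitude_noise_deg: float = 0.5
    cycle_jitter: float = 0.03
    # hip-point oscillation amplitudes (typical normative gait)
    osc_vertical_m: float = 0.02
    osc_foreaft_m: float = 0.01

    def __post_init__(self) -> None:
        for name in ("thigh_m", "shank_m", "sensor_offset_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        expected = self.stride_m * self.cadence_spm / 120.0
        if abs(self.speed_mps - expected) > 1e-9:
            raise ValueError(
                "speed, cadence and stride violate speed = stride*cadence/120")

    @property
    def stride_time_s(self) -> float:
        return 120.0 / self.cadence_spm

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def sample_subject_profile(config: CohortConfig, rng: np.random.Generator,
                           subject_id: int = 0) -> SubjectProfile:
    """Draw one subject from the cohort-level distributions.

    Speed and cadence are normal draws around the cohort means; stride
    length is derived from them so the speed-cadence-stride identity holds
    exactly. Draws are clipped to physical bounds (speed >= 0.5 m/s,
    cadence >= 60 steps/min) and clipping is logged.
    """
    speed = float(rng.normal(config.speed_mean_mps, config.speed_sd_mps))
    cadence = float(rng.normal(config.cadence_mean_spm, config.cadence_sd_spm))
    if speed < 0.5:
        logger.warning("subject %d: speed %.3f clipped to 0.5 m/s",
                       subject_id, speed)
        speed = 0.5
    if cadence < 60.0:
        logger.warning("subject %d: cadence %.2f clipped to 60 steps/min",
                       subject_id, cadence)
        cadence = 60.0
    stride = speed * 120.0 / cadence
    thigh = max(0.25, float(rng.normal(config.thigh_mean_m, config.thigh_sd_m)))
    shank = max(0.25, float(rng.normal(config.shank_mean_m, config.shank_sd_m)))
    perturbations = {}
    for joint in JOINTS:
        perturbations[joint] = JointPerturbation(
            amp_scale=max(0.5, float(rng.normal(1.0, config.amp_scale_sd))),
            offset_deg=float(rng.normal(0.0, config.offset_sd_deg)),
            phase_shift=float(rng.normal(0.0, config.phase_sd)),
        )
    return SubjectProfile(
        subject_id=subject_id,
        speed_mps=speed,
        cadence_spm=cadence,
        stride_m=stride,
        thigh_m=thigh,
        shank_m=shank,
        perturbations=perturbations,
        accel_noise_g=config.accel_noise_g,
        gyro_noise_dps=config.gyro_noise_dps,
        attitude_noise_deg=config.attitude_noise_deg,
        cycle_jitter=config.cycle_jitter,
    )


# ---------------------------------------------------------------------------
# streams and trials
# ---------------------------------------------------------------------------

@dataclass
class ImuSeries:
    """9-channel IMU stream: attitude (deg), gyro (deg/s), accel (g)."""

    t_s: np.ndarray          # (n,)
    data: np.ndarray         # (n, 9) in CHANNELS order

    def __post_init__(self) -> None:
        if self.data.shape != (len(self.t_s), len(CHANNELS)):
            raise ValueError("ImuSeries data must be (n, 9)")

    @property
    def rate_hz(self) -> float:
        return 1.0 / float(np.median(np.diff(self.t_s)))


@dataclass
class KinSeries:
    """Reference hip/knee/ankle sagittal angles (deg)."""

    t_s: np.ndarray          # (n,)
    data: np.ndarray         # (n, 3) in JOINTS order

    def __post_init__(self) -> None:
        if self.data.shape != (len(self.t_s), len(JOINTS)):
            raise ValueError("KinSeries data must be (n, 3)")

    @property
    def rate_hz(self) -> float:
        return 1.0 / float(np.median(np.diff(self.t_s)))


@dataclass
class Trial:
    """One subject's paired recording with exact cycle boundaries.

    ``imu_boundaries``/``kin_boundaries`` have length n_cycles+1; cycle k
    spans the half-open sample range [boundaries[k], boundaries[k+1]).
    """

    subject_id: int
    imu: ImuSeries
    kin: KinSeries
    imu_boundaries: np.ndarray
    kin_boundaries: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        for b in (self.imu_boundaries, self.kin_boundaries):
            if np.any(np.diff(b) <= 0):
                raise ValueError("cycle boundaries must be strictly increasing")
        if np.any(np.diff(self.imu_boundaries) < 2):
            raise ValueError("every cycle needs >= 2 IMU samples")

    @property
    def n_cycles(self) -> int:
        return len(self.imu_boundaries) - 1


# ---------------------------------------------------------------------------
# forward kinematics
# ---------------------------------------------------------------------------

def shank_forward_kinematics(profile: SubjectProfile, t: np.ndarray,
                             hip_deg: np.ndarray, knee_deg: np.ndarray,
                             phase: np.ndarray | None = None):
    """Planar forward kinematics of the shank-mounted sensor.

    Given hip and knee flexion trajectories on a uniform dense time grid,
    returns (shank inclination deg, mediolateral angular velocity deg/s,
    longitudinal specific force g, anterior specific force g) at the sensor
    point. The trunk is vertical, so shank inclination from vertical is
    phi = hip - knee. The hip point advances at constant speed with small
    vertical/fore-aft oscillations at stride and double-stride frequency
    (suppressed when speed is zero, i.e. standing).

    Derivatives use central finite differences on the dense grid, which at
    the internal oversampled rate are accurate to a few 1e-5 relative.
    """
    t = np.asarray(t, dtype=float)
    dt = np.diff(t)
    if len(t) < 3 or np.ptp(dt) > 1e-9 * max(1.0, abs(dt[0])):
        raise ValueError("time grid must be uniform with >= 3 samples")
    hip = np.deg2rad(np.asarray(hip_deg, dtype=float))
    knee = np.deg2rad(np.asarray(knee_deg, dtype=float))
    phi = hip - knee  # shank inclination from vertical, + forward

    if phase is None:
        phase = t / profile.stride_time_s
    phase = np.asarray(phase, dtype=float)

    moving = 1.0 if profile.speed_mps > 0 else 0.0
    # hip-point trajectory: forward progression + pelvis oscillation
    x_hip = (profile.speed_mps * t
             + moving * profile.osc_foreaft_m
             * (np.sin(4 * np.pi * phase + 0.4)
                + 0.2 * np.sin(2 * np.pi * phase)))
    z_hip = moving * profile.osc_vertical_m * (
        np.sin(4 * np.pi * phase - np.pi / 2)
        + 0.2 * np.sin(2 * np.pi * phase + 0.7))

    # knee point = hip point + thigh vector; sensor = knee + offset on shank
    x_s = (x_hip + profile.thigh_m * np.sin(hip)
           + profile.sensor_offset_m * np.sin(phi))
    z_s = (z_hip - profile.thigh_m * np.cos(hip)
           - profile.sensor_offset_m * np.cos(phi))

    ax = np.gradient(np.gradient(x_s, t), t)   # m/s^2, world frame
    az = np.gradient(np.gradient(z_s, t), t)

    # specific force in g units, world frame (gravity points along -z)
    fx_w = ax / GRAVITY
    fz_w = az / GRAVITY + 1.0

    sin_p, cos_p = np.sin(phi), np.cos(phi)
    # sensor x-axis distal along shank, y-axis anterior
    f_long = fx_w * sin_p - fz_w * cos_p
    f_ant = fx_w * cos_p + fz_w * sin_p

    phi_deg = np.rad2deg(phi)
    gyro_z = np.gradient(phi_deg, t)
    return phi_deg, gyro_z, f_long, f_ant


# ---------------------------------------------------------------------------
# trial and cohort simulation
# ---------------------------------------------------------------------------

def _quantize(x: np.ndarray, resolution: float) -> np.ndarray:
    if resolution <= 0:
        return x
    return np.round(x / resolution) * resolution


def _perturbed_angles(profile: SubjectProfile, u: np.ndarray,
                      templates: dict[str, GaitTemplate]) -> np.ndarray:
    """(n, 3) joint angles at phases ``u`` with subject perturbations."""
    out = np.empty((len(u), len(JOINTS)))
    for j, joint in enumerate(JOINTS):
        p = profile.perturbations[joint]
        uj = np.mod(u + p.phase_shift, 1.0)
        base = joint_angle_template(uj, templates[joint])
        tpl = templates[joint]
        out[:, j] = p.offset_deg + tpl.a0 + p.amp_scale * (base - tpl.a0)
    return out


def simulate_trial(profile: SubjectProfile, n_cycles: int, seed: int,
                   imu_rate_hz: float = 23.0, kin_rate_hz: float = 60.0,
                   accel_resolution_g: float = 0.01,
                   gyro_resolution_dps: float = 0.05,
                   oversample: int = 20,
                   templates: dict[str, GaitTemplate] | None = None) -> Trial:
    """Simulate one subject's walking trial.

    The cycle phase advances at the cadence-derived stride frequency with
    multiplicative Gaussian jitter on each cycle's duration. IMU channels
    are sampled by exact decimation of an internal dense grid (oversample x
    the IMU rate); accelerometer and gyro outputs are quantized to the
    sensor resolutions. Reference kinematics are sampled noise-free at the
    kinematic rate. Cycle boundaries are recorded exactly in both streams.
    """
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    templates = templates or DEFAULT_TEMPLATES
    rng = np.random.default_rng(seed)

    base_T = profile.stride_time_s
    jit = profile.cycle_jitter * rng.standard_normal(n_cycles)
    durations = base_T * np.clip(1.0 + jit, 0.7, 1.3)
    # snap each cycle to a whole number of IMU samples so boundaries fall
    # exactly on samples (and jitter-free cycles repeat sample-for-sample)
    durations = np.maximum(2.0, np.round(durations * imu_rate_hz)) / imu_rate_hz
    starts = np.concatenate([[0.0], np.cumsum(durations)])
    total = starts[-1]

    dt = 1.0 / (imu_rate_hz * oversample)
    n_dense = int(np.floor(total / dt - 1e-9)) + 1
    # pad both ends by periodic extension of the first/last cycle so the
    # finite-difference stencils never see a grid edge inside the trial
    pad = 8
    t_dense = (np.arange(-pad, n_dense + pad)) * dt

    # sawtooth phase, exact within each cycle; padded samples wrap around
    cyc_idx = np.clip(np.searchsorted(starts, t_dense, side="right") - 1,
                      0, n_cycles - 1)
    u_ext = (t_dense - starts[cyc_idx]) / durations[cyc_idx]
    u_dense = np.mod(u_ext, 1.0)
    u_dense = np.minimum(u_dense, np.nextafter(1.0, 0.0))
    # continuous stride-phase for pelvis oscillation (cycle count + phase)
    phase_dense = cyc_idx + u_ext

    ang_dense = _perturbed_angles(profile, u_dense, templates)
    phi, gyro_z, f_long, f_ant = shank_forward_kinematics(
        profile, t_dense, ang_dense[:, 0], ang_dense[:, 1], phase=phase_dense)
    sl = slice(pad, pad + n_dense)
    phi, gyro_z, f_long, f_ant = (phi[sl], gyro_z[sl], f_long[sl], f_ant[sl])
    t_dense = t_dense[sl]
    u_dense = u_dense[sl]
    phase_dense = phase_dense[sl]

    # decimate: dense grid is an exact superset of the IMU grid
    imu_idx = np.arange(0, n_dense, oversample)
    n_imu = len(imu_idx)
    t_imu = t_dense[imu_idx]
    u_imu = u_dense[imu_idx]
    ph_imu = phase_dense[imu_idx]

    sn = profile.attitude_noise_deg
    gn = profile.gyro_noise_dps
    an = profile.accel_noise_g

    def noise(scale):
        return scale * rng.standard_normal(n_imu) if scale > 0 else 0.0

    pitch = phi[imu_idx] + noise(sn)
    roll = 2.0 * np.sin(2 * np.pi * ph_imu + 0.3) + noise(sn)
    yaw = np.zeros(n_imu) + noise(sn)  # pure noise channel

    gz = gyro_z[imu_idx] + noise(gn)
    gx = 0.05 * gyro_z[imu_idx] + noise(gn)   # mounting cross-talk
    gy = 0.15 * gyro_z[imu_idx] + noise(gn)

    ax_ = f_long[imu_idx] + noise(an)
    ay_ = f_ant[imu_idx] + noise(an)
    az_ = 0.05 * f_ant[imu_idx] + 0.03 * np.sin(2 * np.pi * ph_imu + 1.1) \
        + noise(an)

    imu_data = np.column_stack([
        pitch, roll, yaw,
        _quantize(gx, gyro_resolution_dps),
        _quantize(gy, gyro_resolution_dps),
        _quantize(gz, gyro_resolution_dps),
        _quantize(ax_, accel_resolution_g),
        _quantize(ay_, accel_resolution_g),
        _quantize(az_, accel_resolution_g),
    ])
    imu = ImuSeries(t_s=t_imu, data=imu_data)

    n_kin = int(np.floor(total * kin_rate_hz - 1e-9)) + 1
    t_kin = np.arange(n_kin) / kin_rate_hz
    kc = np.clip(np.searchsorted(starts, t_kin, side="right") - 1,
                 0, n_cycles - 1)
    u_kin = np.clip((t_kin - starts[kc]) / durations[kc],
                    0.0, np.nextafter(1.0, 0.0))
    kin = KinSeries(t_s=t_kin, data=_perturbed_angles(profile, u_kin, templates))

    imu_b = np.ceil(starts * imu_rate_hz - 1e-9).astype(int)
    imu_b[-1] = n_imu
    kin_b = np.ceil(starts * kin_rate_hz - 1e-9).astype(int)
    kin_b[-1] = n_kin

    return Trial(subject_id=profile.subject_id, imu=imu, kin=kin,
                 imu_boundaries=imu_b, kin_boundaries=kin_b, seed=seed)


def make_cohort(config: CohortConfig,
                templates: dict[str, GaitTemplate] | None = None
                ) -> tuple[list[Trial], dict]:
    """Simulate one trial per subject; returns (trials, manifest).

    Child seeds are derived from the master seed so the whole cohort is
    reproducible from ``config`` alone; the manifest records every profile
    and seed.
    """
    ss = np.random.SeedSequence(config.seed)
    state = ss.generate_state(2 * config.n_subjects, dtype=np.uint32)
    seeds = (state % (2 ** 31)).astype(int)

    trials: list[Trial] = []
    manifest: dict = {"config": asdict(config), "subjects": []}
    for i in range(config.n_subjects):
        prof_rng = np.random.default_rng(int(seeds[2 * i]))
        profile = sample_subject_profile(config, prof_rng, subject_id=i)
        if config.min_cycles == config.max_cycles:
            n_cycles = config.min_cycles
        else:
            n_cycles = int(prof_rng.integers(config.min_cycles,
                                             config.max_cycles + 1))
        trial_seed = int(seeds[2 * i + 1])
        trial = simulate_trial(
            profile, n_cycles, trial_seed,
            imu_rate_hz=config.imu_rate_hz, kin_rate_hz=config.kin_rate_hz,
            accel_resolution_g=config.accel_resolution_g,
            gyro_resolution_dps=config.gyro_resolution_dps,
            oversample=config.oversample, templates=templates)
        trials.append(trial)
        manifest["subjects"].append({
            "subject_id": i,
            "profile_seed": int(seeds[2 * i]),
            "trial_seed": trial_seed,
            "n_cycles": n_cycles,
            "profile": profile.to_dict(),
        })
    return trials, manifest
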