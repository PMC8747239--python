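"""Signal conditioning and cycle-level alignment.

The reference kinematics are low-pass filtered (zero-phase 4th-order
Butterworth, 4 Hz cutoff), the IMU channels are median-smoothed (5-sample
window), and within each gait cycle the higher-rate labels are resampled
onto that cycle's IMU sample grid so features and labels share one clock.
Min-max normalization of the input features (fitted on training data only)
lives here too.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal, ndimage

from .synth import CHANNELS, JOINTS, ImuSeries, Trial

logger = logging.getLogger(__name__)


@dataclass
class Cycle:
    """One aligned gait cycle: features and labels on the IMU grid."""

    subject_id: int
    cycle_id: int
    features: np.ndarray   # (n, 9), CHANNELS order
    labels: np.ndarray     # (n, 3), JOINTS order

    def __post_init__(self) -> None:
        if self.features.shape[0] != self.labels.shape[0]:
            raise ValueError("feature/label sample counts differ")
        if self.features.shape[0] < 2:
            raise ValueError("cycle needs >= 2 samples")
        if self.features.shape[1] != len(CHANNELS):
            raise ValueError("expected 9 feature channels")
        if self.labels.shape[1] != len(JOINTS):
            raise ValueError("expected 3 joint labels")

    @property
    def key(self) -> tuple[int, int]:
        return (self.subject_id, self.cycle_id)

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]


def butterworth_lowpass(x: np.ndarray, fs: float, fc: float = 4.0,
                        order: int = 4) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass filter.

    Length-preserving; the effective magnitude response is |H(f)|^2 of the
    one-pass design because of the bidirectional application.
    """
    x = np.asarray(x, dtype=float)
    if fc >= fs / 2:
        raise ValueError(f"cutoff {fc} Hz must be below Nyquist ({fs / 2} Hz)")
    n = x.shape[0]
    if n < 3 * order:
        raise ValueError(
            f"signal too short for filtering: {n} samples < {3 * order}")
    sos = signal.butter(order, fc, btype="low", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x, axis=0)


def median_smooth(x: np.ndarray, window: int = 5) -> np.ndarray:
    """Running-median smoothing with reflected edge padding."""
    x = np.asarray(x, dtype=float)
    if window % 2 == 0 or window < 1:
        raise ValueError("window must be odd and >= 1")
    if x.shape[0] < window:
        raise ValueError("signal shorter than the median window")
    if x.ndim == 1:
        return ndimage.median_filter(x, size=window, mode="mirror")
    return ndimage.median_filter(x, size=(window, 1), mode="mirror")


def resample_cycle_labels(kin_cycle: np.ndarray, n_imu: int) -> np.ndarray:
    """Resample one cycle's labels onto ``n_imu`` samples.

    Linear interpolation on normalized cycle time [0, 1]; the first and
    last samples are preserved exactly.
    """
    kin_cycle = np.asarray(kin_cycle, dtype=float)
    if kin_cycle.shape[0] < 2:
        raise ValueError("kinematic cycle needs >= 2 samples")
    if n_imu < 2:
        raise ValueError("target sample count must be >= 2")
    src = np.linspace(0.0, 1.0, kin_cycle.shape[0])
    dst = np.linspace(0.0, 1.0, n_imu)
    if kin_cycle.ndim == 1:
        return np.interp(dst, src, kin_cycle)
    return np.column_stack(
        [np.interp(dst, src, kin_cycle[:, j])
         for j in range(kin_cycle.shape[1])])


# ---------------------------------------------------------------------------
# min-max normalization
# ---------------------------------------------------------------------------

@dataclass
class NormStats:
    """Per-feature min/max fitted on training data.

    Features are scaled as (x - xmin) / (xmax - xmin) into [0, 1] on the
    training set; test data may fall outside and is not clamped. Constant
    training features map to 0.
    """

    xmin: np.ndarray
    xmax: np.ndarray
    constant: np.ndarray = field(default=None)  # bool mask

    def __post_init__(self) -> None:
        self.xmin = np.asarray(self.xmin, dtype=float)
        self.xmax = np.asarray(self.xmax, dtype=float)
        if np.any(self.xmax < self.xmin):
            raise ValueError("xmax must be >= xmin per feature")
        if self.constant is None:
            self.constant = self.xmax == self.xmin

    def to_dict(self) -> dict:
        return {"xmin": self.xmin.tolist(), "xmax": self.xmax.tolist(),
                "constant": np.asarray(self.constant).tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "NormStats":
        return cls(np.array(d["xmin"]), np.array(d["xmax"]),
                   np.array(d["constant"], dtype=bool))


def fit_minmax(train_cycles) -> NormStats:
    """Fit per-feature min/max over all samples of the training cycles."""
    cycles = list(train_cycles)
    if not cycles:
        raise ValueError("empty training set")
    X = np.vstack([c.features for c in cycles])
    xmin = X.min(axis=0)
    xmax = X.max(axis=0)
    constant = xmax == xmin
    if np.any(constant):
        idx = np.flatnonzero(constant)
        logger.warning("constant training feature(s) %s map to 0",
                       [CHANNELS[i] for i in idx if i < len(CHANNELS)] or idx)
    return NormStats(xmin=xmin, xmax=xmax, constant=constant)


def apply_minmax(x: np.ndarray, stats: NormStats) -> np.ndarray:
    """Scale features with training-set min/max (no clamping)."""
    x = np.asarray(x, dtype=float)
    denom = np.where(stats.constant, 1.0, stats.xmax - stats.xmin)
    out = (x - stats.xmin) / denom
    if np.any(stats.constant):
        out[..., stats.constant] = 0.0
    return out


def invert_minmax(x: np.ndarray, stats: NormStats) -> np.ndarray:
    """Inverse of :func:`apply_minmax` for non-constant features."""
    denom = np.where(stats.constant, 1.0, stats.xmax - stats.xmin)
    return np.asarray(x, dtype=float) * denom + stats.xmin


# ---------------------------------------------------------------------------
# cycle construction
# ---------------------------------------------------------------------------

def build_cycles(trial: Trial, fc_hz: float = 4.0, order: int = 4,
                 median_window: int = 5) -> list[Cycle]:
    """Cut a trial into aligned cycles.

    Labels are Butterworth-filtered at the kinematic rate over the whole
    trial, IMU channels are median-smoothed over the whole trial, then both
    are cut at the recorded boundaries and the labels are resampled to each
    cycle's IMU sample count. Because the two streams share a clock here,
    the resampling interpolates the filtered labels at the cycle's actual
    IMU sample times, which avoids the sub-sample phase offset that
    cutting at whole kinematic samples would introduce
    (:func:`resample_cycle_labels` covers the clock-free case). Cycles with
    fewer than 2 IMU or kinematic samples are skipped with a warning.
    """
    if trial.n_cycles < 1:
        raise ValueError("trial has no recorded cycles")
    labels = butterworth_lowpass(trial.kin.data, fs=trial.kin.rate_hz,
                                 fc=fc_hz, order=order)
    feats = median_smooth(trial.imu.data, window=median_window)

    cycles: list[Cycle] = []
    for k in range(trial.n_cycles):
        i0, i1 = trial.imu_boundaries[k], trial.imu_boundaries[k + 1]
        j0, j1 = trial.kin_boundaries[k], trial.kin_boundaries[k + 1]
        if i1 - i0 < 2 or j1 - j0 < 2:
            logger.warning("subject %d cycle %d too short, skipped",
                           trial.subject_id, k)
            continue
        t_cycle = trial.imu.t_s[i0:i1]
        lab = np.column_stack([
            np.interp(t_cycle, trial.kin.t_s, labels[:, j])
            for j in range(labels.shape[1])])
        cycles.append(Cycle(subject_id=trial.subject_id, cycle_id=k,
                            features=feats[i0:i1].copy(), labels=lab))
    return cycles


def detect_cycles_gyro(imu: ImuSeries, min_stride_s: float = 0.5,
                       prominence_frac: float = 0.4) -> np.ndarray:
    """Optional gait-cycle segmentation from the mediolateral gyro.

    Finds the prominent positive swing-phase peak of the z gyro (one per
    stride) and places the cycle boundary at the following positive-to-
    negative zero crossing, which coincides with the shank's maximal
    forward inclination at heel strike. Returns an empty array when no
    peaks are found (e.g. constant input).
    """
    fs = imu.rate_hz
    if len(imu.t_s) < 2 * fs:
        raise ValueError("need >= 2 s of data")
    gz = median_smooth(imu.data[:, CHANNELS.index("gz")], window=5)
    span = float(np.ptp(gz))
    if span <= 0:
        return np.array([], dtype=int)
    peaks, _ = signal.find_peaks(
        gz, prominence=prominence_frac * span,
        distance=max(2, int(min_stride_s * fs)))
    boundaries = []
    for p in peaks:
        i = p
        while i + 1 < len(gz) and gz[i + 1] > 0:
            i += 1
        if i + 1 < len(gz):  # crossing between i and i+1
            boundaries.append(i + 1 if abs(gz[i + 1]) < abs(gz[i]) else i)
    return np.unique(np.asarray(boundaries, dtype=int))
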