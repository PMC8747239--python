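"""CSV dialects and manifest files for cohorts.

``imu.csv`` columns: subject_id, trial_id, cycle_id, sample_idx, t_s,
pitch_deg, roll_deg, yaw_deg, gyro_x_dps, gyro_y_dps, gyro_z_dps,
acc_x_g, acc_y_g, acc_z_g.
``kin.csv`` columns: subject_id, trial_id, cycle_id, sample_idx, t_s,
hip_deg, knee_deg, ankle_deg.
UTF-8, header row, '.' decimal separator; all angles in degrees,
accelerations in g, angular velocities in deg/s.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synth import CHANNELS, JOINTS, ImuSeries, KinSeries, Trial

IMU_COLUMNS = ["subject_id", "trial_id", "cycle_id", "sample_idx", "t_s",
               "pitch_deg", "roll_deg", "yaw_deg",
               "gyro_x_dps", "gyro_y_dps", "gyro_z_dps",
               "acc_x_g", "acc_y_g", "acc_z_g"]
KIN_COLUMNS = ["subject_id", "trial_id", "cycle_id", "sample_idx", "t_s",
               "hip_deg", "knee_deg", "ankle_deg"]

_IMU_DATA_COLS = IMU_COLUMNS[5:]
_KIN_DATA_COLS = KIN_COLUMNS[5:]


def _cycle_of(boundaries: np.ndarray, n: int) -> np.ndarray:
    cyc = np.searchsorted(boundaries, np.arange(n), side="right") - 1
    return np.clip(cyc, 0, len(boundaries) - 2)


def trials_to_frames(trials: list[Trial]) -> tuple[pd.DataFrame, pd.DataFrame]:
    imu_rows, kin_rows = [], []
    for trial in trials:
        n_i = len(trial.imu.t_s)
        imu_rows.append(pd.DataFrame({
            "subject_id": trial.subject_id, "trial_id": 0,
            "cycle_id": _cycle_of(trial.imu_boundaries, n_i),
            "sample_idx": np.arange(n_i), "t_s": trial.imu.t_s,
            **{col: trial.imu.data[:, i]
               for i, col in enumerate(_IMU_DATA_COLS)}}))
        n_k = len(trial.kin.t_s)
        kin_rows.append(pd.DataFrame({
            "subject_id": trial.subject_id, "trial_id": 0,
            "cycle_id": _cycle_of(trial.kin_boundaries, n_k),
            "sample_idx": np.arange(n_k), "t_s": trial.kin.t_s,
            **{col: trial.kin.data[:, i]
               for i, col in enumerate(_KIN_DATA_COLS)}}))
    return (pd.concat(imu_rows, ignore_index=True),
            pd.concat(kin_rows, ignore_index=True))


def write_cohort(trials: list[Trial], manifest: dict, out_dir) -> None:
    """Write imu.csv, kin.csv and manifest.json for a cohort."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    imu_df, kin_df = trials_to_frames(trials)
    imu_df.to_csv(out / "imu.csv", index=False, float_format="%.9g")
    kin_df.to_csv(out / "kin.csv", index=False, float_format="%.9g")
    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1)


def _validate(df: pd.DataFrame, columns: list[str], path) -> None:
    missing = set(columns) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    bad = df[columns].isna().any(axis=1)
    if bad.any():
        raise ValueError(f"{path}: NaN cell at row {int(np.flatnonzero(bad)[0])}")
    for (_, _), grp in df.groupby(["subject_id", "trial_id"], sort=True):
        t = grp["t_s"].to_numpy()
        if np.any(np.diff(t) <= 0):
            row = int(grp.index[np.flatnonzero(np.diff(t) <= 0)[0] + 1])
            raise ValueError(f"{path}: non-monotone t_s at row {row}")


def _boundaries(grp: pd.DataFrame) -> np.ndarray:
    cyc = grp["cycle_id"].to_numpy()
    starts = np.flatnonzero(np.diff(cyc) != 0) + 1
    return np.concatenate([[0], starts, [len(cyc)]])


def read_imu_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _validate(df, IMU_COLUMNS, path)
    return df


def read_kin_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _validate(df, KIN_COLUMNS, path)
    return df


def read_cohort(imu_path, kin_path) -> list[Trial]:
    """Reassemble Trials from the CSV pair (one trial per subject/trial id)."""
    imu_df = read_imu_csv(imu_path)
    kin_df = read_kin_csv(kin_path)
    trials = []
    for (sid, tid), g_imu in imu_df.groupby(["subject_id", "trial_id"],
                                            sort=True):
        g_kin = kin_df[(kin_df.subject_id == sid) & (kin_df.trial_id == tid)]
        if g_kin.empty:
            raise ValueError(f"no kinematics for subject {sid} trial {tid}")
        imu = ImuSeries(t_s=g_imu["t_s"].to_numpy(),
                        data=g_imu[_IMU_DATA_COLS].to_numpy())
        kin = KinSeries(t_s=g_kin["t_s"].to_numpy(),
                        data=g_kin[_KIN_DATA_COLS].to_numpy())
        trials.append(Trial(subject_id=int(sid), imu=imu, kin=kin,
                            imu_boundaries=_boundaries(g_imu),
                            kin_boundaries=_boundaries(g_kin), seed=-1))
    return trials


def write_importance(tables, selected: list[str], out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = [row for t in tables for row in t.as_rows()]
    pd.DataFrame(rows).to_csv(out / "importance.csv", index=False)
    with open(out / "selected_features.json", "w", encoding="utf-8") as fh:
        json.dump({"selected": selected}, fh, indent=1)
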