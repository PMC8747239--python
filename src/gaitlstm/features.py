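"""Filter feature selection by Pearson correlation.

Each of the 9 IMU channels is scored against each joint's angle by the
absolute Pearson correlation over all pooled training samples. Scores are
normalized per joint by the maximum score, and every channel whose relative
importance exceeds the threshold (default 30 %) for at least one joint is
selected; the final input set is the union across joints in canonical
channel order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .synth import CHANNELS, JOINTS

logger = logging.getLogger(__name__)


@dataclass
class ImportanceTable:
    """Raw |r| and max-normalized relative importance for one joint."""

    joint: str
    raw: np.ndarray        # (9,) absolute Pearson r
    relative: np.ndarray   # (9,) raw / max(raw), in [0, 1]

    def __post_init__(self) -> None:
        if len(self.raw) != len(CHANNELS) or len(self.relative) != len(CHANNELS):
            raise ValueError("importance tables cover exactly 9 channels")

    def as_rows(self):
        return [{"joint": self.joint, "feature": ch,
                 "raw_r": float(self.raw[i]),
                 "relative_importance": float(self.relative[i])}
                for i, ch in enumerate(CHANNELS)]


def joint_importance(train_cycles, joint: str) -> ImportanceTable:
    """Score all 9 channels against one joint's angle.

    Samples are pooled over all training cycles; features with zero
    variance score 0 (with a warning) since Pearson r is undefined there.
    """
    if joint not in JOINTS:
        raise ValueError(f"unknown joint {joint!r}")
    cycles = list(train_cycles)
    if not cycles:
        raise ValueError("empty training set")
    X = np.vstack([c.features for c in cycles])
    y = np.concatenate([c.labels[:, JOINTS.index(joint)] for c in cycles])
    if len(y) < 2:
        raise ValueError("need >= 2 pooled samples")

    xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((xc ** 2).sum(axis=0))
    sy = np.sqrt((yc ** 2).sum())
    # guard against catastrophic cancellation on constant columns
    tol = 1e-10 * np.sqrt(len(y)) * (1.0 + np.abs(X).max(axis=0))
    sx = np.where(sx <= tol, 0.0, sx)
    raw = np.zeros(len(CHANNELS))
    ok = (sx > 0) & (sy > 0)
    if np.any(~(sx > 0)):
        logger.warning("zero-variance feature(s) %s score 0 for %s",
                       [CHANNELS[i] for i in np.flatnonzero(~(sx > 0))], joint)
    if sy > 0:
        raw[ok] = np.abs(xc[:, ok].T @ yc) / (sx[ok] * sy)
    mx = raw.max()
    if mx <= 0:
        raise ValueError("all features have zero correlation or variance")
    return ImportanceTable(joint=joint, raw=raw, relative=raw / mx)


def select_features(tables, threshold: float = 0.30) -> list[str]:
    """Union of per-joint channels with relative importance > threshold.

    The inequality is strict and the returned list follows the canonical
    9-channel order so downstream column layouts are reproducible.
    """
    tables = list(tables)
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    got = {t.joint for t in tables}
    if got != set(JOINTS):
        raise ValueError(f"need one table per joint, got {sorted(got)}")
    chosen = set()
    for t in tables:
        chosen.update(np.flatnonzero(t.relative > threshold))
    return [CHANNELS[i] for i in sorted(chosen)]


def feature_indices(names) -> np.ndarray:
    """Map channel names to column indices in canonical order."""
    return np.array([CHANNELS.index(n) for n in names], dtype=int)
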