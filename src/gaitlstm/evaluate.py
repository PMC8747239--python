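"""Cross-validated evaluation: split schemes, metrics, experiment driver.

Three train/test division schemes are supported, each under k-fold
cross-validation (default k=5):

* ``within_one_subject`` — each subject's cycles are partitioned into k
  folds; a model is trained and tested per subject, and subject results
  are averaged unweighted.
* ``intra_subject`` — all cycles from all subjects are pooled, shuffled
  and partitioned into k folds.
* ``inter_subject`` — subjects themselves are shuffled and partitioned
  into k disjoint groups; test subjects are never seen in training.

Metrics: RMSE (deg), NRMSE (% — RMSE over the predicted trace's range
within each gait cycle, averaged over test cycles) and the coefficient of
determination R² (pooled over a fold's test samples per joint).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synth import JOINTS
from .preprocess import Cycle, fit_minmax, apply_minmax, NormStats
from .features import joint_importance, select_features, feature_indices
from .synth import CHANNELS
from .lstm import Hyperparams, WindowBatch, build_windows, train, predict

logger = logging.getLogger(__name__)

SCHEMES = ("within_one_subject", "intra_subject", "inter_subject")


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def rmse(y: np.ndarray, yhat: np.ndarray) -> float:
    """Root mean squared error, same units as the inputs."""
    y = np.asarray(y, float).ravel()
    yhat = np.asarray(yhat, float).ravel()
    if len(y) != len(yhat):
        raise ValueError("length mismatch")
    if len(y) < 1:
        raise ValueError("need >= 1 sample")
    return float(np.sqrt(np.mean((yhat - y) ** 2)))


def nrmse_cycle(y: np.ndarray, yhat: np.ndarray,
                use_true_range: bool = False) -> float:
    """Per-cycle normalized RMSE in percent.

    The denominator is the range (max - min) of the predicted trace within
    the cycle; ``use_true_range`` switches to the reference trace's range.
    Returns NaN (flagged) when the chosen range is zero.
    """
    y = np.asarray(y, float).ravel()
    yhat = np.asarray(yhat, float).ravel()
    if len(y) < 2:
        raise ValueError("a cycle needs >= 2 samples")
    ref = y if use_true_range else yhat
    rng_ = float(np.max(ref) - np.min(ref))
    if rng_ <= 0:
        logger.warning("zero range in NRMSE denominator; cycle excluded")
        return float("nan")
    return 100.0 * rmse(y, yhat) / rng_


def r2(y: np.ndarray, yhat: np.ndarray) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot."""
    y = np.asarray(y, float).ravel()
    yhat = np.asarray(yhat, float).ravel()
    if len(y) != len(yhat):
        raise ValueError("length mismatch")
    if len(y) < 2:
        raise ValueError("need >= 2 samples")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot <= 0:
        raise ValueError("R2 undefined for constant reference")
    ss_res = float(np.sum((y - yhat) ** 2))
    return 1.0 - ss_res / ss_tot


# ---------------------------------------------------------------------------
# split schemes
# ---------------------------------------------------------------------------

@dataclass
class SplitScheme:
    name: str
    k: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.name not in SCHEMES:
            raise ValueError(f"unknown scheme {self.name!r}")
        if self.k < 2:
            raise ValueError("k must be >= 2")


@dataclass
class SplitPlan:
    """Fold assignments. Units are cycle keys (subject_id, cycle_id) for
    the cycle-level schemes and subject ids for inter_subject. For
    within_one_subject there is one k-fold plan per subject."""

    scheme: SplitScheme
    folds: list[tuple[list, list]] = field(default_factory=list)
    per_subject: dict[int, list[tuple[list, list]]] = field(
        default_factory=dict)


def make_splits(cycles: list[Cycle], scheme: SplitScheme) -> SplitPlan:
    """Build the fold plan for one scheme, deterministic given the seed."""
    if not cycles:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(scheme.seed)
    plan = SplitPlan(scheme=scheme)
    subjects = sorted({c.subject_id for c in cycles})

    if scheme.name == "within_one_subject":
        for sid in subjects:
            keys = sorted(c.key for c in cycles if c.subject_id == sid)
            if len(keys) < scheme.k:
                raise ValueError(
                    f"subject {sid} has {len(keys)} cycles < k={scheme.k}")
            keys = [keys[i] for i in rng.permutation(len(keys))]
            chunks = np.array_split(np.arange(len(keys)), scheme.k)
            folds = []
            for ch in chunks:
                test = [keys[i] for i in ch]
                train_ = [k for k in keys if k not in set(test)]
                folds.append((sorted(train_), sorted(test)))
            plan.per_subject[sid] = folds
    elif scheme.name == "intra_subject":
        keys = sorted(c.key for c in cycles)
        keys = [keys[i] for i in rng.permutation(len(keys))]
        chunks = np.array_split(np.arange(len(keys)), scheme.k)
        for ch in chunks:
            test = set(keys[i] for i in ch)
            plan.folds.append((sorted(k for k in keys if k not in test),
                               sorted(test)))
    else:  # inter_subject
        if len(subjects) < scheme.k:
            raise ValueError("fewer subjects than folds")
        if len(subjects) % scheme.k != 0:
            raise ValueError(
                f"{len(subjects)} subjects not divisible into {scheme.k} "
                "equal groups")
        order = [subjects[i] for i in rng.permutation(len(subjects))]
        groups = np.array_split(np.arange(len(order)), scheme.k)
        for gr in groups:
            test = sorted(order[i] for i in gr)
            plan.folds.append((sorted(s for s in subjects if s not in set(test)),
                               test))
    return plan


# ---------------------------------------------------------------------------
# experiment driver
# ---------------------------------------------------------------------------

def _prepare_windows(cycles: list[Cycle], stats: NormStats,
                     feat_idx: np.ndarray, seq_len: int) -> WindowBatch:
    batches = [build_windows(c, seq_len=seq_len, feature_idx=feat_idx,
                             features=apply_minmax(c.features, stats))
               for c in cycles]
    return WindowBatch.concat(batches)


def _fold_metrics(model, test_cycles, stats, feat_idx, seq_len,
                  use_true_range=False) -> dict:
    """Per-joint pooled RMSE/R2 and cycle-averaged NRMSE on a test set."""
    ys, yhats, per_cycle_nrmse = [], [], {j: [] for j in JOINTS}
    per_cycle_rmse = {j: [] for j in JOINTS}
    for c in test_cycles:
        wb = _prepare_windows([c], stats, feat_idx, seq_len)
        yh = predict(model, wb)
        ys.append(c.labels)
        yhats.append(yh)
        for j, joint in enumerate(JOINTS):
            per_cycle_nrmse[joint].append(
                nrmse_cycle(c.labels[:, j], yh[:, j],
                            use_true_range=use_true_range))
            per_cycle_rmse[joint].append(rmse(c.labels[:, j], yh[:, j]))
    Y = np.vstack(ys)
    Yh = np.vstack(yhats)
    out = {}
    for j, joint in enumerate(JOINTS):
        vals = np.asarray(per_cycle_nrmse[joint], float)
        out[joint] = {
            "rmse": rmse(Y[:, j], Yh[:, j]),
            "r2": r2(Y[:, j], Yh[:, j]),
            "nrmse": float(np.nanmean(vals)) if np.any(np.isfinite(vals))
            else float("nan"),
            "rmse_cycle_mean": float(np.mean(per_cycle_rmse[joint])),
        }
    return out


def _train_and_score(train_cycles, test_cycles, hp: Hyperparams,
                     feature_set: str, threshold: float,
                     use_true_range: bool) -> tuple[dict, list[str]]:
    stats = fit_minmax(train_cycles)
    if feature_set == "selected":
        tables = [joint_importance(train_cycles, j) for j in JOINTS]
        names = select_features(tables, threshold=threshold)
    else:
        names = list(CHANNELS)
    feat_idx = feature_indices(names)
    wb = _prepare_windows(train_cycles, stats, feat_idx, hp.seq_len)
    model, _ = train(wb, hp, feature_names=tuple(names))
    return (_fold_metrics(model, test_cycles, stats, feat_idx, hp.seq_len,
                          use_true_range=use_true_range), names)


@dataclass
class MetricsReport:
    """Tidy per-fold metrics plus aggregation helpers."""

    rows: pd.DataFrame  # scheme, feature_set, fold, subject, joint, metric cols

    def summary(self) -> pd.DataFrame:
        """Cross-fold (and, for within, cross-subject) mean and SD."""
        g = (self.rows.groupby(["scheme", "feature_set", "joint"])
             [["rmse", "nrmse", "r2"]].agg(["mean", "std"]))
        return g

    def table(self, scheme: str, feature_set: str) -> pd.DataFrame:
        """One report table: rows R2/RMSE/NRMSE, columns ankle/knee/hip."""
        sub = self.rows[(self.rows.scheme == scheme)
                        & (self.rows.feature_set == feature_set)]
        means = sub.groupby("joint")[["r2", "rmse", "nrmse"]].mean()
        out = pd.DataFrame(
            {j: [means.loc[j, "r2"], means.loc[j, "rmse"],
                 means.loc[j, "nrmse"]] for j in ("ankle", "knee", "hip")},
            index=["R2", "RMSE (deg)", "NRMSE (%)"])
        return out


def run_experiment(cycles: list[Cycle], hp: Hyperparams,
                   schemes=SCHEMES, feature_sets=("all", "selected"),
                   k: int = 5, threshold: float = 0.30,
                   split_seed: int = 0, model_seed: int = 0,
                   use_true_range: bool = False) -> MetricsReport:
    """Run the scheme x feature-set grid with k-fold CV on aligned cycles.

    Normalization statistics and feature selection are refitted on each
    fold's training cycles only (no leakage). Every trained model gets a
    distinct deterministic seed derived from ``model_seed``.
    """
    by_key = {c.key: c for c in cycles}
    records = []
    model_counter = 0
    for scheme_name in schemes:
        scheme = SplitScheme(scheme_name, k=k, seed=split_seed)
        plan = make_splits(cycles, scheme)
        for feature_set in feature_sets:
            if scheme_name == "within_one_subject":
                for sid, folds in plan.per_subject.items():
                    for fold_i, (tr, te) in enumerate(folds):
                        hp_fold = Hyperparams(
                            **{**_hp_dict(hp),
                               "seed": model_seed + 9973 * model_counter})
                        model_counter += 1
                        metrics, names = _train_and_score(
                            [by_key[kk] for kk in tr],
                            [by_key[kk] for kk in te],
                            hp_fold, feature_set, threshold, use_true_range)
                        for joint, md in metrics.items():
                            records.append({
                                "scheme": scheme_name,
                                "feature_set": feature_set,
                                "fold": fold_i, "subject": sid,
                                "joint": joint,
                                "features": ",".join(names), **md})
            else:
                for fold_i, (tr, te) in enumerate(plan.folds):
                    if scheme_name == "inter_subject":
                        tr_c = [c for c in cycles if c.subject_id in set(tr)]
                        te_c = [c for c in cycles if c.subject_id in set(te)]
                    else:
                        tr_c = [by_key[kk] for kk in tr]
                        te_c = [by_key[kk] for kk in te]
                    hp_fold = Hyperparams(
                        **{**_hp_dict(hp),
                           "seed": model_seed + 9973 * model_counter})
                    model_counter += 1
                    metrics, names = _train_and_score(
                        tr_c, te_c, hp_fold, feature_set, threshold,
                        use_true_range)
                    for joint, md in metrics.items():
                        records.append({
                            "scheme": scheme_name, "feature_set": feature_set,
                            "fold": fold_i, "subject": -1, "joint": joint,
                            "features": ",".join(names), **md})
    return MetricsReport(rows=pd.DataFrame.from_records(records))


def _hp_dict(hp: Hyperparams) -> dict:
    from dataclasses import asdict
    d = asdict(hp)
    d["loss_weights"] = tuple(d["loss_weights"])
    return d
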