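"""Single-layer LSTM regressor mapping IMU windows to three joint angles.

Inputs are sliding windows of length 5 over normalized features within one
gait cycle; the target is the hip/knee/ankle angle at the window's last
sample. The loss is a weighted sum of per-joint mean squared errors
(weights 3 / 1 / 4 for hip / knee / ankle by default), optimized with Adam.

The cell and its backward pass are implemented directly in NumPy with
explicit backpropagation through time: gates i, f, o are sigmoid, the cell
candidate and cell-to-hidden activation are tanh, and the read-out is a
single linear layer from the last hidden state. Angles are regressed in
degrees; internally the read-out is parameterized through a fixed affine
target scaling (per-joint train-label mean and spread) so optimization is
well conditioned regardless of the joints' dynamic ranges — the loss itself
is always computed in degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .preprocess import Cycle

#: default per-joint loss weights (hip, knee, ankle)
DEFAULT_LOSS_WEIGHTS = (3.0, 1.0, 4.0)


@dataclass
class Hyperparams:
    """Training hyperparameters (defaults: 1-layer LSTM, hidden 50,
    batch 256, Adam at 1e-3, sequence length 5, 500 epochs, tanh cell
    activation, loss weights 3/1/4)."""

    n_layers: int = 1
    batch_size: int = 256
    hidden_size: int = 50
    learning_rate: float = 0.001
    seq_len: int = 5
    epochs: int = 500
    loss_weights: tuple[float, float, float] = DEFAULT_LOSS_WEIGHTS
    seed: int = 0
    optimizer: str = "adam"
    activation: str = "tanh"

    def __post_init__(self) -> None:
        if self.n_layers != 1:
            raise ValueError("only a single LSTM layer is supported")
        for name in ("batch_size", "hidden_size", "seq_len", "epochs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if len(self.loss_weights) != 3 or any(w < 0 for w in self.loss_weights):
            raise ValueError("loss_weights must be three non-negative values")
        if self.optimizer != "adam":
            raise ValueError("only adam is supported")
        if self.activation != "tanh":
            raise ValueError("only tanh cell activation is supported")


@dataclass
class WindowBatch:
    """Sliding windows with per-window provenance (subject, cycle, sample)."""

    X: np.ndarray      # (n, seq_len, n_features)
    y: np.ndarray      # (n, 3) degrees
    keys: np.ndarray   # (n, 3) int: subject_id, cycle_id, sample_idx

    def __post_init__(self) -> None:
        if self.X.shape[0] != self.y.shape[0] or self.X.shape[0] != self.keys.shape[0]:
            raise ValueError("inconsistent window counts")

    def __len__(self) -> int:
        return self.X.shape[0]

    @staticmethod
    def concat(batches: Sequence["WindowBatch"]) -> "WindowBatch":
        return WindowBatch(
            X=np.concatenate([b.X for b in batches]),
            y=np.concatenate([b.y for b in batches]),
            keys=np.concatenate([b.keys for b in batches]))


def build_windows(cycle: Cycle, seq_len: int = 5,
                  feature_idx: np.ndarray | None = None,
                  features: np.ndarray | None = None) -> WindowBatch:
    """One window per sample of a cycle; windows never cross cycles.

    Early samples are left-padded by replicating the first sample so every
    label gets a full-length window and hence a prediction. ``features``
    may supply a pre-normalized feature matrix for the same cycle.
    """
    if seq_len < 1:
        raise ValueError("seq_len must be >= 1")
    F = cycle.features if features is None else np.asarray(features, float)
    if F.shape[0] != cycle.n_samples:
        raise ValueError("feature override must match the cycle length")
    if feature_idx is not None:
        F = F[:, feature_idx]
    n = F.shape[0]
    padded = np.vstack([np.repeat(F[:1], seq_len - 1, axis=0), F])
    X = np.stack([padded[t:t + seq_len] for t in range(n)])
    keys = np.column_stack([
        np.full(n, cycle.subject_id), np.full(n, cycle.cycle_id),
        np.arange(n)]).astype(int)
    return WindowBatch(X=X, y=cycle.labels.copy(), keys=keys)


def weighted_mse(y: np.ndarray, yhat: np.ndarray,
                 weights: Sequence[float] = DEFAULT_LOSS_WEIGHTS) -> float:
    """A*MSE_hip + B*MSE_knee + C*MSE_ankle over samples, in deg^2."""
    y = np.asarray(y, float)
    yhat = np.asarray(yhat, float)
    if y.shape != yhat.shape or y.ndim != 2 or y.shape[1] != 3:
        raise ValueError("y and yhat must both be (n, 3)")
    if y.shape[0] < 1:
        raise ValueError("need at least one sample")
    mse = ((yhat - y) ** 2).mean(axis=0)
    return float(np.dot(weights, mse))


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class LstmModel:
    """Learned parameters plus the fixed read-out target scaling.

    Gate blocks in ``Wx``/``Wh``/``b`` are ordered [input, forget,
    candidate, output]. ``target_mean``/``target_scale`` are the per-joint
    affine constants fitted on the training labels; predictions are
    read_out * scale + mean, in degrees.
    """

    Wx: np.ndarray           # (F, 4H)
    Wh: np.ndarray           # (H, 4H)
    b: np.ndarray            # (4H,)
    Wy: np.ndarray           # (H, 3)
    by: np.ndarray           # (3,)
    target_mean: np.ndarray  # (3,)
    target_scale: np.ndarray  # (3,)
    feature_names: tuple[str, ...] = ()
    hp: Hyperparams | None = None

    @property
    def n_features(self) -> int:
        return self.Wx.shape[0]

    @property
    def hidden_size(self) -> int:
        return self.Wh.shape[0]

    def param_dict(self) -> dict[str, np.ndarray]:
        return {"Wx": self.Wx, "Wh": self.Wh, "b": self.b,
                "Wy": self.Wy, "by": self.by}

    def save(self, path) -> None:
        import json
        payload = {
            "feature_names": list(self.feature_names),
            "hyperparams": asdict(self.hp) if self.hp else None,
            "target_mean": self.target_mean.tolist(),
            "target_scale": self.target_scale.tolist(),
        }
        for k, v in self.param_dict().items():
            payload[k] = v.tolist()
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "LstmModel":
        import json
        with open(path, encoding="utf-8") as fh:
            d = json.load(fh)
        hp = Hyperparams(**{**d["hyperparams"],
                            "loss_weights": tuple(d["hyperparams"]["loss_weights"])}) \
            if d.get("hyperparams") else None
        return cls(Wx=np.array(d["Wx"]), Wh=np.array(d["Wh"]),
                   b=np.array(d["b"]), Wy=np.array(d["Wy"]),
                   by=np.array(d["by"]),
                   target_mean=np.array(d["target_mean"]),
                   target_scale=np.array(d["target_scale"]),
                   feature_names=tuple(d["feature_names"]), hp=hp)


def _init_model(n_features: int, hp: Hyperparams,
                target_mean: np.ndarray, target_scale: np.ndarray,
                rng: np.random.Generator,
                feature_names: tuple[str, ...]) -> LstmModel:
    H = hp.hidden_size

    def glorot(fan_in, fan_out, shape):
        lim = np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-lim, lim, size=shape)

    Wx = glorot(n_features, H, (n_features, 4 * H))
    Wh = glorot(H, H, (H, 4 * H))
    b = np.zeros(4 * H)
    b[H:2 * H] = 1.0  # forget-gate bias: remember by default
    Wy = glorot(H, 3, (H, 3))
    by = np.zeros(3)
    return LstmModel(Wx=Wx, Wh=Wh, b=b, Wy=Wy, by=by,
                     target_mean=target_mean, target_scale=target_scale,
                     feature_names=feature_names, hp=hp)


def _init_readout_least_squares(model: LstmModel, X: np.ndarray,
                                y: np.ndarray, max_rows: int = 4096,
                                ridge: float = 1e-5) -> None:
    """Initialize the linear read-out at its ridge least-squares optimum.

    The freshly initialized recurrent cell already provides a rich random
    feature map of each window; solving the (convex) read-out problem once
    before gradient descent starts removes the slow linear phase of Adam
    and leaves the remaining epochs to shape the recurrent weights. Purely
    an initialization: every parameter is trained afterwards.
    """
    rows = np.arange(min(len(X), max_rows))
    _, (_, h) = _forward(model, X[rows])
    y_raw = (y[rows] - model.target_mean) / model.target_scale
    A = np.column_stack([h, np.ones(len(rows))])
    reg = ridge * np.eye(A.shape[1])
    reg[-1, -1] = 0.0
    sol = np.linalg.solve(A.T @ A + len(rows) * reg, A.T @ y_raw)
    model.Wy[...] = sol[:-1]
    model.by[...] = sol[-1]


def _forward(model: LstmModel, X: np.ndarray):
    """Run the cell over time; returns predictions and the BPTT cache."""
    B, T, F = X.shape
    H = model.hidden_size
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    cache = []
    for t in range(T):
        z = X[:, t] @ model.Wx + h @ model.Wh + model.b
        i = _sigmoid(z[:, :H])
        f = _sigmoid(z[:, H:2 * H])
        g = np.tanh(z[:, 2 * H:3 * H])
        o = _sigmoid(z[:, 3 * H:])
        c_new = f * c + i * g
        tc = np.tanh(c_new)
        h_new = o * tc
        cache.append((h, c, i, f, g, o, tc))
        h, c = h_new, c_new
    raw = h @ model.Wy + model.by
    yhat = raw * model.target_scale + model.target_mean
    return yhat, (cache, h)


def _backward(model: LstmModel, X: np.ndarray, dyhat: np.ndarray, fwd_cache):
    """Gradients of the loss w.r.t. all parameters given d(loss)/d(yhat)."""
    cache, h_last = fwd_cache
    B, T, F = X.shape
    H = model.hidden_size
    draw = dyhat * model.target_scale
    grads = {
        "Wy": h_last.T @ draw,
        "by": draw.sum(axis=0),
        "Wx": np.zeros_like(model.Wx),
        "Wh": np.zeros_like(model.Wh),
        "b": np.zeros_like(model.b),
    }
    dh = draw @ model.Wy.T
    dc = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        h_prev, c_prev, i, f, g, o, tc = cache[t]
        do = dh * tc
        dc = dc + dh * o * (1.0 - tc ** 2)
        di = dc * g
        df = dc * c_prev
        dg = dc * i
        dz = np.concatenate([
            di * i * (1.0 - i),
            df * f * (1.0 - f),
            dg * (1.0 - g ** 2),
            do * o * (1.0 - o)], axis=1)
        grads["Wx"] += X[:, t].T @ dz
        grads["Wh"] += h_prev.T @ dz
        grads["b"] += dz.sum(axis=0)
        dh = dz @ model.Wh.T
        dc = dc * f
    return grads


def loss_and_grads(model: LstmModel, X: np.ndarray, y: np.ndarray,
                   weights: Sequence[float]):
    """Weighted MSE over the batch and its parameter gradients."""
    yhat, fwd = _forward(model, X)
    n = X.shape[0]
    resid = yhat - y
    loss = float(np.dot(weights, (resid ** 2).mean(axis=0)))
    dyhat = 2.0 * resid * np.asarray(weights) / n
    return loss, _backward(model, X, dyhat, fwd)


class TrainingDiverged(RuntimeError):
    pass


def train(train_windows: WindowBatch, hp: Hyperparams,
          feature_names: tuple[str, ...] = ()) -> tuple[LstmModel, np.ndarray]:
    """Train the LSTM with mini-batch Adam; returns (model, loss history).

    Data are shuffled each epoch with the run seed. The read-out's affine
    target scaling is fixed from the training labels before optimization,
    so the degree-scale loss is well conditioned from the first step. All
    randomness (initialization, shuffling) flows from ``hp.seed``, making
    training deterministic in single-threaded mode.
    """
    if len(train_windows) < 1:
        raise ValueError("need at least one training window")
    X, y = train_windows.X, train_windows.y
    rng = np.random.default_rng(hp.seed)

    target_mean = y.mean(axis=0)
    spread = y.std(axis=0)
    target_scale = np.where(spread > 1e-8, spread, 1.0)

    model = _init_model(X.shape[2], hp, target_mean, target_scale, rng,
                        tuple(feature_names))
    _init_readout_least_squares(model, X, y)

    params = model.param_dict()
    m = {k: np.zeros_like(v) for k, v in params.items()}
    v = {k: np.zeros_like(p) for k, p in params.items()}
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0
    n = len(train_windows)
    history = np.empty(hp.epochs)

    for epoch in range(hp.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, hp.batch_size):
            idx = order[start:start + hp.batch_size]
            loss, grads = loss_and_grads(model, X[idx], y[idx],
                                         hp.loss_weights)
            if not np.isfinite(loss):
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch}, step {step}: "
                    f"lr={hp.learning_rate}, batch_mean={X[idx].mean():.3g}, "
                    f"batch_std={X[idx].std():.3g}")
            step += 1
            for k, p in params.items():
                g = grads[k]
                m[k] = beta1 * m[k] + (1 - beta1) * g
                v[k] = beta2 * v[k] + (1 - beta2) * g * g
                mhat = m[k] / (1 - beta1 ** step)
                vhat = v[k] / (1 - beta2 ** step)
                p -= hp.learning_rate * mhat / (np.sqrt(vhat) + eps)
            epoch_loss += loss
            n_batches += 1
        history[epoch] = epoch_loss / n_batches
    return model, history


def predict(model: LstmModel, windows: WindowBatch) -> np.ndarray:
    """Per-window 3-joint predictions (deg), aligned with ``windows.keys``.

    A pure function of (model, inputs): windows are independent samples, so
    batch composition and ordering do not affect individual outputs.
    """
    if windows.X.shape[2] != model.n_features:
        raise ValueError(
            f"model expects {model.n_features} features, "
            f"got {windows.X.shape[2]}")
    yhat, _ = _forward(model, windows.X)
    return yhat
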