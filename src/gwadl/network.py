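"""Two-hidden-layer feed-forward regression networks for genomic prediction.

The trainer is a deterministic numpy implementation of mini-batch SGD with
momentum on the penalized loss

    MSE + l1 * sum|w| + l2 * sum w^2

with a single dropout rate shared by the input and both hidden layers
(inverted dropout, so evaluation needs no rescaling), tanh / relu / maxout
activations (maxout with 2 linear pieces per unit), per-feature input
standardization, and an early-stopping rule on the relative reduction of the
3-epoch moving average of the training MSE. Every random choice (weight
initialization, batch shuffling, dropout masks) comes from one seeded
generator, so identical seeds give bitwise-identical training runs.

Variable importance follows Gedeon's weight-magnitude measure: layer-wise
normalized absolute weights multiplied along all input->output paths.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from ._utils import derive_seed, kfold_indices, mse_r2, pearson_r2
from .gblup import PredictionResult

__all__ = [
    "NetConfig",
    "TrainedNetwork",
    "ImportanceScores",
    "train_network",
    "grid_search",
    "default_grid",
    "random_grid",
    "gedeon_importance",
    "crossval_gwadl",
    "should_stop",
]

ACTIVATIONS = ("tanh", "relu", "maxout")

# Grid levels reproducing the canonical 3 x 4 x 4 x 4 x 4 x 5 = 3,840 search
H_LEVELS = (40, 126, 213, 300)
L1_LEVELS = (2e-6, 1e-5, 5e-5, 1e-4)
L2_LEVELS = (2e-6, 1e-5, 5e-5, 1e-4)
DROPOUT_LEVELS = (0.04, 0.15, 0.275, 0.40, 0.50)


@dataclass(frozen=True)
class NetConfig:
    h1: int = 126
    h2: int = 126
    activation: str = "relu"
    l1: float = 2e-6
    l2: float = 2e-6
    dropout: float = 0.04
    max_epochs: int = 200
    stop_window: int = 3
    stop_tol: float = 0.01
    stop_mode: str = "relative"  # or "absolute"
    learning_rate: float = 0.005
    momentum: float = 0.9
    batch_size: int = 32
    clip_grad_norm: float = 10.0  # global-norm gradient clipping; 0 disables
    seed: int = 0

    def __post_init__(self):
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"activation must be one of {ACTIVATIONS}")
        if not (40 <= self.h1 <= 300 and 40 <= self.h2 <= 300):
            raise ValueError("hidden widths must lie in [40, 300]")
        if not (0.0 <= self.dropout <= 0.5):
            raise ValueError("dropout must lie in [0, 0.5]")
        if self.seed is None:
            raise ValueError("seed is mandatory")


def default_grid(seed: int = 0) -> list[NetConfig]:
    """The full 3,840-configuration hyperparameter grid."""
    grid = []
    for act, h1, h2, l1, l2, dr in itertools.product(
            ACTIVATIONS, H_LEVELS, H_LEVELS, L1_LEVELS, L2_LEVELS, DROPOUT_LEVELS):
        grid.append(NetConfig(h1=h1, h2=h2, activation=act, l1=l1, l2=l2,
                              dropout=dr, seed=seed))
    return grid


def random_grid(n: int, seed: int = 0) -> list[NetConfig]:
    """A seeded random subsample of the full grid, for desk-scale searches."""
    full = default_grid(seed)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(full), size=min(n, len(full)), replace=False)
    return [full[i] for i in sorted(idx)]


def should_stop(history: list[float], window: int, tol: float,
                mode: str = "relative") -> bool:
    """Early-stopping rule: the moving-average MSE over the last ``window``
    epochs improved on the previous window by less than ``tol`` (relatively,
    or absolutely in "absolute" mode)."""
    if len(history) < 2 * window:
        return False
    prev = float(np.mean(history[-2 * window:-window]))
    cur = float(np.mean(history[-window:]))
    if mode == "absolute":
        return (prev - cur) < tol
    if prev <= 0:
        return True
    return (prev - cur) / prev < tol


@dataclass
class TrainedNetwork:
    config: NetConfig
    weights: list[np.ndarray]   # [W1, W2, W3]; maxout layers are 2-piece stacks
    biases: list[np.ndarray]
    x_mean: np.ndarray
    x_sd: np.ndarray
    y_mean: float
    y_sd: float
    history: list[float]        # per-epoch full-data training MSE (scaled units)
    stopped_epoch: int

    def _hidden(self, A: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
        act = self.config.activation
        if act == "maxout":
            return np.maximum(A @ W[0] + b[0], A @ W[1] + b[1])
        z = A @ W + b
        return np.tanh(z) if act == "tanh" else np.maximum(z, 0.0)

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        A = (X - self.x_mean) / self.x_sd
        A = self._hidden(A, self.weights[0], self.biases[0])
        A = self._hidden(A, self.weights[1], self.biases[1])
        out = A @ self.weights[2] + self.biases[2]
        return out.ravel() * self.y_sd + self.y_mean

    def training_r2(self, X: np.ndarray, y: np.ndarray) -> float:
        return pearson_r2(y, self.predict(X))

    def save(self, path) -> None:
        """Serialize to a single self-describing .npz archive (weights,
        biases, config, standardization parameters, training history)."""
        import json
        from dataclasses import asdict

        arrays = {"x_mean": self.x_mean, "x_sd": self.x_sd,
                  "y_scale": np.array([self.y_mean, self.y_sd]),
                  "history": np.asarray(self.history, dtype=float),
                  "stopped_epoch": np.array([self.stopped_epoch]),
                  "config_json": np.frombuffer(
                      json.dumps(asdict(self.config)).encode(), dtype=np.uint8)}
        for i, (W, b) in enumerate(zip(self.weights, self.biases), 1):
            arrays[f"W{i}"] = W
            arrays[f"b{i}"] = b
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "TrainedNetwork":
        import json

        with np.load(path) as z:
            cfg = NetConfig(**json.loads(bytes(z["config_json"]).decode()))
            return cls(cfg,
                       [z["W1"], z["W2"], z["W3"]],
                       [z["b1"], z["b2"], z["b3"]],
                       z["x_mean"], z["x_sd"],
                       float(z["y_scale"][0]), float(z["y_scale"][1]),
                       z["history"].tolist(), int(z["stopped_epoch"][0]))


@dataclass
class ImportanceScores:
    scores: np.ndarray

    def __post_init__(self):
        s = np.asarray(self.scores, dtype=float)
        if np.any(s < 0):
            raise ValueError("importance scores must be non-negative")
        self.scores = s

    @property
    def ranks(self) -> np.ndarray:
        """1 = most important."""
        order = np.argsort(-self.scores, kind="stable")
        r = np.empty_like(order)
        r[order] = np.arange(1, order.size + 1)
        return r


def _init_layer(rng, fan_in, fan_out, pieces):
    scale = np.sqrt(2.0 / (fan_in + fan_out))
    if pieces == 1:
        return rng.normal(0.0, scale, (fan_in, fan_out)), np.zeros(fan_out)
    return (rng.normal(0.0, scale, (pieces, fan_in, fan_out)),
            np.zeros((pieces, fan_out)))


def _forward_hidden(A, W, b, act):
    """Returns (activation output, cache for backprop)."""
    if act == "maxout":
        z0 = A @ W[0] + b[0]
        z1 = A @ W[1] + b[1]
        which = (z1 > z0)
        return np.where(which, z1, z0), which
    z = A @ W + b
    if act == "tanh":
        out = np.tanh(z)
        return out, out
    out = np.maximum(z, 0.0)
    return out, (z > 0)


def _backward_hidden(dA, A_prev, W, cache, act):
    """Returns (dA_prev, dW, db) for one hidden layer."""
    if act == "maxout":
        which = cache
        d1 = dA * which
        d0 = dA * (~which)
        dW = np.stack([A_prev.T @ d0, A_prev.T @ d1])
        db = np.stack([d0.sum(axis=0), d1.sum(axis=0)])
        dA_prev = d0 @ W[0].T + d1 @ W[1].T
        return dA_prev, dW, db
    if act == "tanh":
        dz = dA * (1.0 - cache**2)
    else:
        dz = dA * cache
    return dz @ W.T, A_prev.T @ dz, dz.sum(axis=0)


def train_network(X: np.ndarray, y: np.ndarray, cfg: NetConfig) -> TrainedNetwork:
    """Fit the two-hidden-layer regressor; deterministic given cfg.seed."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = X.shape
    if y.size != n:
        raise ValueError("y length must match X rows")
    x_mean = X.mean(axis=0)
    x_sd = X.std(axis=0)
    x_sd = np.where(x_sd > 0, x_sd, 1.0)
    y_mean = float(y.mean())
    y_sd = float(y.std()) or 1.0
    Xs = (X - x_mean) / x_sd
    ys = (y - y_mean) / y_sd

    rng = np.random.default_rng(cfg.seed)
    act = cfg.activation
    pieces = 2 if act == "maxout" else 1
    W1, b1 = _init_layer(rng, m, cfg.h1, pieces)
    W2, b2 = _init_layer(rng, cfg.h1, cfg.h2, pieces)
    W3, b3 = _init_layer(rng, cfg.h2, 1, 1)
    params = [W1, b1, W2, b2, W3, b3]
    vel = [np.zeros_like(p) for p in params]

    keep = 1.0 - cfg.dropout
    history: list[float] = []
    net = TrainedNetwork(cfg, [W1, W2, W3], [b1, b2, b3], x_mean, x_sd,
                         y_mean, y_sd, history, 0)

    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            A0 = Xs[idx]
            yb = ys[idx]
            bs = idx.size
            if cfg.dropout > 0:
                m0 = (rng.random(A0.shape) < keep) / keep
                A0 = A0 * m0
            A1, c1 = _forward_hidden(A0, W1, b1, act)
            if cfg.dropout > 0:
                m1 = (rng.random(A1.shape) < keep) / keep
                A1d = A1 * m1
            else:
                m1 = None
                A1d = A1
            A2, c2 = _forward_hidden(A1d, W2, b2, act)
            if cfg.dropout > 0:
                m2 = (rng.random(A2.shape) < keep) / keep
                A2d = A2 * m2
            else:
                m2 = None
                A2d = A2
            pred = (A2d @ W3 + b3).ravel()
            err = pred - yb
            if not np.isfinite(err).all():
                raise FloatingPointError(
                    "non-finite training loss (exploding gradient); "
                    "reduce the learning rate")
            dpred = (2.0 / bs) * err[:, None]
            dW3 = A2d.T @ dpred
            db3 = dpred.sum(axis=0)
            dA2 = dpred @ W3.T
            if m2 is not None:
                dA2 = dA2 * m2
            dA1, dW2, db2 = _backward_hidden(dA2, A1d, W2, c2, act)
            if m1 is not None:
                dA1 = dA1 * m1
            dA0, dW1, db1 = _backward_hidden(dA1, A0, W1, c1, act)
            grads = [dW1, db1, dW2, db2, dW3, db3]
            # penalty gradients on weights only
            for gi, p in zip((0, 2, 4), (W1, W2, W3)):
                grads[gi] = grads[gi] + cfg.l1 * np.sign(p) + 2.0 * cfg.l2 * p
            if cfg.clip_grad_norm > 0:
                gnorm = np.sqrt(sum(float(np.sum(gr * gr)) for gr in grads))
                if gnorm > cfg.clip_grad_norm:
                    scale = cfg.clip_grad_norm / gnorm
                    grads = [gr * scale for gr in grads]
            for p, v, gr in zip(params, vel, grads):
                v *= cfg.momentum
                v -= cfg.learning_rate * gr
                p += v
        # full-data training MSE without dropout
        resid = net.predict(X) - y
        history.append(float(np.mean((resid / y_sd) ** 2)))
        if should_stop(history, cfg.stop_window, cfg.stop_tol, cfg.stop_mode):
            break
    net.stopped_epoch = len(history)
    return net


def gedeon_importance(net: TrainedNetwork) -> ImportanceScores:
    """Weight-magnitude variable importance over all input->output paths.

    Each layer's absolute weights are normalized over their inputs
    (column-wise); the per-input score is the sum over paths of the product of
    normalized magnitudes, renormalized to sum to 1. Maxout layers use the
    element-wise maximum of the two pieces' magnitudes.
    """
    def mag(W):
        return np.abs(W).max(axis=0) if W.ndim == 3 else np.abs(W)

    def col_norm(M):
        s = M.sum(axis=0)
        return np.divide(M, s, out=np.zeros_like(M), where=s > 0)

    P = col_norm(mag(net.weights[0]))
    Q = col_norm(mag(net.weights[1]))
    w3 = mag(net.weights[2]).ravel()
    R = w3 / w3.sum() if w3.sum() > 0 else np.zeros_like(w3)
    raw = P @ (Q @ R)
    total = raw.sum()
    scores = raw / total if total > 0 else raw
    return ImportanceScores(scores)


def grid_search(X: np.ndarray, y: np.ndarray, grid: list[NetConfig],
                folds: int = 5, seed: int = 0
                ) -> tuple[NetConfig, pd.DataFrame]:
    """Score each configuration by mean k-fold CV MSE; return the argmin.

    All configurations share the same seeded folds, so scores are paired.
    """
    if not grid:
        raise ValueError("empty grid")
    parts = kfold_indices(len(y), folds, seed)
    rows = []
    best = None
    for ci, cfg in enumerate(grid):
        mses, r2s = [], []
        for f, test in enumerate(parts):
            train = np.setdiff1d(np.arange(len(y)), test)
            fit_cfg = replace(cfg, seed=derive_seed(cfg.seed, ci, f))
            try:
                net = train_network(X[train], y[train], fit_cfg)
            except FloatingPointError:
                # divergent member of the grid: score it out of contention
                mses.append(np.inf)
                r2s.append(0.0)
                continue
            pred = net.predict(X[test])
            mses.append(float(np.mean((y[test] - pred) ** 2)))
            r2s.append(pearson_r2(y[test], pred))
        mean_mse = float(np.mean(mses))
        rows.append({"config": ci, "h1": cfg.h1, "h2": cfg.h2,
                     "activation": cfg.activation, "l1": cfg.l1, "l2": cfg.l2,
                     "dropout": cfg.dropout, "cv_mse": mean_mse,
                     "cv_r2": float(np.mean(r2s))})
        if best is None or mean_mse < best[0]:
            best = (mean_mse, cfg)
    return best[1], pd.DataFrame(rows)


def crossval_gwadl(X: np.ndarray, y: np.ndarray, cfg: NetConfig,
                   folds: int = 5, seed: int = 0,
                   r2_definition: str = "pearson") -> PredictionResult:
    """k-fold CV prediction with the shared fold protocol (same seed =>
    same partitions as :func:`gwadl.gblup.crossval_gblup`)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    parts = kfold_indices(n, folds, seed)
    pred_all = np.empty(n)
    fold_of = np.empty(n, dtype=int)
    r2s, r2s_alt = [], []
    degenerate = y.std() == 0
    for f, test in enumerate(parts):
        train = np.setdiff1d(np.arange(n), test)
        fold_of[test] = f
        if degenerate:
            pred_all[test] = y.mean()
            r2s.append(0.0)
            r2s_alt.append(0.0)
            continue
        net = train_network(X[train], y[train],
                            replace(cfg, seed=derive_seed(cfg.seed, 97, f)))
        pred = net.predict(X[test])
        pred_all[test] = pred
        r2s.append(pearson_r2(y[test], pred))
        r2s_alt.append(mse_r2(y[test], pred))
    primary = r2s if r2_definition == "pearson" else r2s_alt
    ids = [f"s{i}" for i in range(n)]
    return PredictionResult(ids, pred_all, y, fold_of, np.array(primary),
                            r2_definition=r2_definition, degenerate=degenerate,
                            fold_r2_alt=np.array(r2s_alt))
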