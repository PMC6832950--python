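"""Model training: Adam, validation split, early stopping, prediction.

Training minimises mean squared error on (optionally z-scored) yields.
One integer seed drives the validation split, weight initialisation,
batch shuffling and dropout masks, so a fixed seed reproduces a run
bit-for-bit on one platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .networks import ModelConfig, Network, build_model

__all__ = ["EarlyStopping", "Adam", "TrainedModel", "train", "predict", "validation_split"]


class EarlyStopping:
    """Stop when the monitored loss has not improved for `patience`
    consecutive epochs.  ``update`` returns True when training should stop."""

    def __init__(self, patience: int, min_delta: float = 0.0):
        if patience < 1:
            raise ValueError("patience must be >= 1")
        self.patience = patience
        self.min_delta = min_delta
        self.best = np.inf
        self.best_epoch = -1
        self.wait = 0

    def update(self, loss: float, epoch: int) -> bool:
        if loss < self.best - self.min_delta:
            self.best = loss
            self.best_epoch = epoch
            self.wait = 0
            return False
        self.wait += 1
        return self.wait >= self.patience


class Adam:
    """Adam with the customary defaults (lr 1e-3, betas 0.9/0.999)."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-7):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.v) for p in self.params]
        self.v = [np.zeros_like(p.v) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.g
            v *= self.b2
            v += (1 - self.b2) * p.g ** 2
            p.v -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


@dataclass
class TrainedModel:
    network: Network
    config: ModelConfig
    history: dict[str, list[float]]
    stopped_epoch: int  # 1-based last epoch actually run
    label_mean: float
    label_std: float
    val_indices: np.ndarray

    @property
    def input_shape(self) -> tuple[int, int, int]:
        return self.network.input_shape


def validation_split(n: int, val_fraction: float, rng: np.random.Generator):
    """Uniform random split into (train_idx, val_idx); at least one sample
    on each side."""
    perm = rng.permutation(n)
    n_val = min(max(1, int(round(val_fraction * n))), n - 1)
    return np.sort(perm[n_val:]), np.sort(perm[:n_val])


def _as_xy(dataset) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(dataset, tuple):
        X, y = dataset
    else:
        X, y = dataset.stack()
    return np.asarray(X), np.asarray(y, dtype=np.float64)


def train(dataset, config: ModelConfig, network: Network | None = None) -> TrainedModel:
    """Fit a model on a tensor dataset (or an (X, y) pair).

    Holds out ``val_fraction`` of the samples uniformly at random,
    minimises MSE with Adam, stops early when validation loss fails to
    improve for ``early_stop_patience`` consecutive epochs and (by
    default) restores the best-validation weights.
    """
    X, y = _as_xy(dataset)
    if len(X) < 2:
        raise ValueError("training requires at least 2 samples")
    rng = np.random.default_rng(config.seed)
    if network is None:
        network = build_model(config, X.shape[1:])
    tr_idx, va_idx = validation_split(len(X), config.val_fraction, rng)

    if config.standardize_labels:
        mu = float(y[tr_idx].mean())
        sd = float(y[tr_idx].std())
        sd = sd if sd > 0 else 1.0
    else:
        mu, sd = 0.0, 1.0
    ys = (y - mu) / sd

    Xtr, ytr = X[tr_idx], ys[tr_idx]
    Xva, yva = X[va_idx], ys[va_idx]
    opt = Adam(network.params(), lr=config.learning_rate)
    stopper = EarlyStopping(config.early_stop_patience)
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
    best_weights = network.get_weights()
    stopped = config.epochs
    B = config.batch_size

    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(len(Xtr))
        epoch_loss = 0.0
        for bi, start in enumerate(range(0, len(order), B)):
            idx = order[start:start + B]
            xb, yb = Xtr[idx], ytr[idx]
            pred = network.forward(xb, train=True, rng=rng)
            err = pred - yb
            loss = float(np.mean(err ** 2))
            if not np.isfinite(loss):
                raise RuntimeError(f"non-finite loss at epoch {epoch}, batch {bi}")
            epoch_loss += loss * len(idx)
            network.zero_grad()
            network.backward((2.0 * err / len(idx)).astype(err.dtype))
            if config.clip_norm is not None:
                _clip_global_norm(network.params(), config.clip_norm)
            opt.step()
        history["train_loss"].append(epoch_loss / len(Xtr))

        val_pred = _forward_eval(network, Xva)
        val_loss = float(np.mean((val_pred - yva) ** 2))
        if not np.isfinite(val_loss):
            raise RuntimeError(f"non-finite validation loss at epoch {epoch}")
        history["val_loss"].append(val_loss)
        if val_loss <= min(history["val_loss"]):
            best_weights = network.get_weights()
        if stopper.update(val_loss, epoch):
            stopped = epoch
            break

    if config.restore_best:
        network.set_weights(best_weights)
    return TrainedModel(network, config, history, stopped, mu, sd, va_idx)


def _clip_global_norm(params, max_norm: float) -> None:
    total = np.sqrt(sum(float(np.sum(p.g.astype(np.float64) ** 2)) for p in params))
    if total > max_norm:
        scale = max_norm / (total + 1e-12)
        for p in params:
            p.g *= scale


def _forward_eval(network: Network, X: np.ndarray, batch: int = 256) -> np.ndarray:
    rng = np.random.default_rng(0)  # unused at inference (no dropout)
    outs = [network.forward(X[i:i + batch], train=False, rng=rng)
            for i in range(0, len(X), batch)]
    return np.concatenate(outs) if outs else np.empty(0)


def predict(model: TrainedModel, dataset) -> np.ndarray:
    """Predicted yields in kg/ha, one per tensor; empty input -> empty."""
    if isinstance(dataset, np.ndarray):
        X = dataset
    elif isinstance(dataset, tuple):
        X = np.asarray(dataset[0])
    elif isinstance(dataset, list):
        if not dataset:
            return np.empty(0)
        X = np.stack([t.values for t in dataset])
    else:
        X, _ = dataset.stack()
    if X.size == 0:
        return np.empty(0)
    if X.shape[1:] != model.input_shape:
        raise ValueError(
            f"tensor shape {X.shape[1:]} does not match trained input "
            f"{model.input_shape} (expected t={model.input_shape[0]}, received t={X.shape[1]})")
    z = _forward_eval(model.network, X)
    return z * model.label_std + model.label_mean
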