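"""The three yield-model architectures.

All consume histogram tensors of shape (t, n_bins, n_bands) and emit a
single yield value:

* ``cnn_lstm`` — the full model: a time-distributed convolutional stack
  (two 1x2 convolutions of 32 and 64 filters, each followed by ReLU,
  batch normalization and a 1x2 max-pool, then flatten + batch norm)
  feeding a 256-unit LSTM that emits an output at every step, a shared
  per-step dense layer, a flatten over time, 0.5 dropout and a linear
  unit.  The 1x2 kernels act along the bin axis only: the band ordering
  is arbitrary, so mixing adjacent bands would be meaningless.
* ``cnn`` — the recurrence ablated: same convolutional stack, then all
  per-step features concatenated into one vector, dense, dropout, linear.
* ``lstm`` — the convolutions ablated: raw per-step slices flattened and
  fed straight to the LSTM, then dense / flatten / dropout / linear.

The two baselines are minimal reconstructions obtained by splitting the
full model into its components; the filter counts, unit counts, dropout
and kernel sizes are shared so comparisons isolate the architecture.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .layers import (AsImage, BatchNorm, Conv1x2, Dense, Dropout, Flatten,
                     FlattenTime, LSTM, MaxPool1x2, ReLU, Sequential,
                     TimeDistributed)

__all__ = ["ModelConfig", "Network", "build_cnn_lstm", "build_cnn_baseline",
           "build_lstm_baseline", "build_model", "FAST_PROFILE"]

ARCHITECTURES = ("cnn_lstm", "cnn", "lstm")


@dataclass(frozen=True)
class ModelConfig:
    """Architecture and optimisation hyper-parameters.

    Defaults follow the published configuration: 32/64 convolution
    filters with 1x2 kernels and 1x2 pools, a 256-unit LSTM, a 64-unit
    dense layer, 0.5 dropout, ReLU activations, mean-squared-error loss
    minimised by Adam for up to 100 epochs at batch size 16, with early
    stopping after 10 epochs without validation improvement on a random
    0.2 validation split.
    """

    architecture: str = "cnn_lstm"
    conv_filters: tuple[int, int] = (32, 64)
    lstm_units: int = 256
    dense_units: int = 64
    dropout: float = 0.5
    epochs: int = 100
    batch_size: int = 16
    early_stop_patience: int = 10
    val_fraction: float = 0.2
    learning_rate: float = 1e-3
    clip_norm: float | None = None  # global gradient-norm clipping
    standardize_labels: bool = True
    restore_best: bool = True
    dtype: str = "float32"  # "float64" for gradient checking
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in (0, 1)")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if not 1 <= self.early_stop_patience <= self.epochs:
            raise ValueError("early_stop_patience must be in [1, epochs]")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        if self.dtype not in ("float32", "float64"):
            raise ValueError("dtype must be 'float32' or 'float64'")


#: reduced widths for CPU-bound experiments; architecture topology unchanged
FAST_PROFILE = dict(conv_filters=(4, 8), lstm_units=24, dense_units=12,
                    learning_rate=3e-3)


class Network:
    """A built model: layer graph plus bookkeeping for training."""

    def __init__(self, layers: Sequential, config: ModelConfig,
                 input_shape: tuple[int, int, int]):
        self.layers = layers
        self.config = config
        self.input_shape = tuple(input_shape)  # (t, n_bins, n_bands)

    def params(self):
        return self.layers.params()

    @property
    def n_parameters(self) -> int:
        return int(sum(p.v.size for p in self.params()))

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator) -> np.ndarray:
        if x.shape[1:] != self.input_shape:
            raise ValueError(
                f"input shape {x.shape[1:]} does not match model input {self.input_shape} "
                f"(expected t={self.input_shape[0]}, received t={x.shape[1]})")
        x = np.asarray(x, dtype=np.dtype(self.config.dtype))
        return self.layers.forward(x, train, rng)[:, 0]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.layers.backward(dy[:, None])

    def zero_grad(self) -> None:
        for p in self.params():
            p.g[...] = 0.0

    def get_weights(self) -> list[np.ndarray]:
        """Trainable parameters plus inference state (batch-norm running
        statistics) — everything needed to restore a checkpoint."""
        return [p.v.copy() for p in self.params()] + [a.copy() for a in self.layers.state()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        params = self.params()
        for p, w in zip(params, weights[:len(params)], strict=False):
            p.v[...] = w
        self.layers.set_state([a.copy() for a in weights[len(params):]])


def _conv_stack(config: ModelConfig, n_bins: int, n_bands: int,
                rng: np.random.Generator) -> tuple[list, int]:
    """Time-distributed convolutional feature extractor; returns layers and
    the per-step flattened feature length (bins reduce n -> n/2 -> n/4)."""
    if n_bins < 4:
        raise ValueError(f"bin axis of length {n_bins} cannot be max-pooled twice")
    f1, f2 = config.conv_filters
    dt = np.dtype(config.dtype)
    layers = [
        AsImage(),
        Conv1x2(1, f1, rng, dt), ReLU(), BatchNorm(f1, dtype=dt), MaxPool1x2(),
        Conv1x2(f1, f2, rng, dt), ReLU(), BatchNorm(f2, dtype=dt), MaxPool1x2(),
        Flatten(),
    ]
    feat = n_bands * (n_bins // 4) * f2
    layers.append(BatchNorm(feat, dtype=dt))
    return layers, feat


def build_cnn_lstm(config: ModelConfig, input_shape: tuple[int, int, int]) -> Network:
    t, n_bins, n_bands = input_shape
    rng = np.random.default_rng(config.seed)
    dt = np.dtype(config.dtype)
    conv, feat = _conv_stack(config, n_bins, n_bands, rng)
    layers = Sequential([
        TimeDistributed(conv),
        LSTM(feat, config.lstm_units, rng, dt),
        Dense(config.lstm_units, config.dense_units, rng, dt), ReLU(),
        FlattenTime(),
        Dropout(config.dropout),
        Dense(t * config.dense_units, 1, rng, dt),
    ])
    return Network(layers, config, input_shape)


def build_cnn_baseline(config: ModelConfig, input_shape: tuple[int, int, int]) -> Network:
    t, n_bins, n_bands = input_shape
    rng = np.random.default_rng(config.seed)
    dt = np.dtype(config.dtype)
    conv, feat = _conv_stack(config, n_bins, n_bands, rng)
    layers = Sequential([
        TimeDistributed(conv),
        FlattenTime(),
        Dense(t * feat, config.dense_units, rng, dt), ReLU(),
        Dropout(config.dropout),
        Dense(config.dense_units, 1, rng, dt),
    ])
    return Network(layers, config, input_shape)


def build_lstm_baseline(config: ModelConfig, input_shape: tuple[int, int, int]) -> Network:
    t, n_bins, n_bands = input_shape
    rng = np.random.default_rng(config.seed)
    dt = np.dtype(config.dtype)
    feat = n_bins * n_bands
    layers = Sequential([
        TimeDistributed([Flatten()]),
        LSTM(feat, config.lstm_units, rng, dt),
        Dense(config.lstm_units, config.dense_units, rng, dt), ReLU(),
        FlattenTime(),
        Dropout(config.dropout),
        Dense(t * config.dense_units, 1, rng, dt),
    ])
    return Network(layers, config, input_shape)


_BUILDERS = {
    "cnn_lstm": build_cnn_lstm,
    "cnn": build_cnn_baseline,
    "lstm": build_lstm_baseline,
}


def build_model(config: ModelConfig, input_shape: tuple[int, int, int]) -> Network:
    return _BUILDERS[config.architecture](config, input_shape)
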