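"""Model stack: gradient correctness, shapes, early stopping, training."""

import numpy as np
import pytest

from histoyield.nn import (EarlyStopping, ModelConfig, build_cnn_baseline,
                           build_cnn_lstm, build_lstm_baseline, build_model,
                           predict, train)
from histoyield.nn.layers import MaxPool1x2
from histoyield.nn.training import validation_split


def _tiny_config(arch="cnn_lstm", **kw):
    defaults = dict(architecture=arch, conv_filters=(2, 3), lstm_units=4,
                    dense_units=3, epochs=5, batch_size=4, early_stop_patience=3,
                    dropout=0.0, dtype="float64", seed=0)
    defaults.update(kw)
    return ModelConfig(**defaults)


# ------------------------------------------------------------ gradient check

@pytest.mark.parametrize("arch", ["cnn_lstm", "cnn", "lstm"])
def test_gradients_match_finite_differences(arch):
    """Analytic gradients of the full loss agree with central differences
    for a subsample of every parameter tensor of every architecture."""
    rng = np.random.default_rng(3)
    X = rng.random((5, 3, 8, 4))
    y = rng.random(5)
    cfg = _tiny_config(arch)
    net = build_model(cfg, X.shape[1:])

    def loss_fn():
        fwd_rng = np.random.default_rng(0)
        pred = net.forward(X, train=True, rng=fwd_rng)
        return float(np.mean((pred - y) ** 2))

    # analytic gradients (batch-norm batch statistics depend only on X,
    # and dropout is off, so repeated forwards are identical)
    loss0 = loss_fn()
    pred = net.forward(X, train=True, rng=np.random.default_rng(0))
    net.zero_grad()
    net.backward((2.0 * (pred - y) / len(y)))

    eps = 1e-6
    checked = 0
    for p in net.params():
        flat_v = p.v.ravel()
        flat_g = p.g.ravel()
        idx = rng.choice(flat_v.size, size=min(4, flat_v.size), replace=False)
        for j in idx:
            orig = flat_v[j]
            flat_v[j] = orig + eps
            lp = loss_fn()
            flat_v[j] = orig - eps
            lm = loss_fn()
            flat_v[j] = orig
            num = (lp - lm) / (2 * eps)
            assert num == pytest.approx(flat_g[j], rel=2e-4, abs=1e-7), \
                f"param shape {p.v.shape} index {j}: numeric {num} vs analytic {flat_g[j]}"
            checked += 1
    assert checked >= 20


# ------------------------------------------------------------------- shapes

@pytest.mark.parametrize("t", [34, 8, 1])
@pytest.mark.parametrize("builder", [build_cnn_lstm, build_cnn_baseline,
                                     build_lstm_baseline])
def test_architectures_build_and_predict_at_all_lengths(builder, t):
    cfg = _tiny_config()
    net = builder(cfg, (t, 32, 11))
    x = np.random.default_rng(0).random((2, t, 32, 11))
    out = net.forward(x, train=False, rng=np.random.default_rng(0))
    assert out.shape == (2,)


def test_conv_stack_reduces_bins_32_16_8():
    """Two 1x2 pools halve the bin axis twice: 32 -> 16 -> 8, so the
    per-step feature length is bands * 8 * filters."""
    cfg = _tiny_config()
    net = build_cnn_lstm(cfg, (4, 32, 11))
    lstm = net.layers.layers[1]
    assert lstm.Wx.v.shape[0] == 11 * 8 * cfg.conv_filters[1]


def test_narrow_bin_axis_rejected():
    with pytest.raises(ValueError, match="pool"):
        build_cnn_lstm(_tiny_config(), (4, 3, 11))
    # the pure-LSTM baseline has no pooling and accepts any bin count
    build_lstm_baseline(_tiny_config(), (4, 3, 11))


def test_baseline_parameter_counts():
    """The LSTM baseline drops the convolutional stack and is strictly
    smaller than the full model.  The CNN baseline removes the recurrence
    but concatenates every per-step feature vector into one dense layer,
    which at the published widths makes it the *largest* of the three —
    ablating a component does not always shrink the network."""
    full = build_cnn_lstm(ModelConfig(architecture="cnn_lstm"), (34, 32, 11))
    cnn = build_cnn_baseline(ModelConfig(architecture="cnn"), (34, 32, 11))
    lstm = build_lstm_baseline(ModelConfig(architecture="lstm"), (34, 32, 11))
    assert lstm.n_parameters < full.n_parameters
    assert cnn.n_parameters > full.n_parameters
    # per-step convolutional extractors are identical in size
    conv_params = sum(p.v.size for p in full.layers.layers[0].params())
    assert conv_params == sum(p.v.size for p in cnn.layers.layers[0].params())


def test_maxpool_requires_even_columns():
    with pytest.raises(ValueError):
        MaxPool1x2().forward(np.zeros((2, 3, 5, 1)), False, None)


# ------------------------------------------------------------ early stopping

def test_early_stopping_scripted_sequence():
    """Stops exactly when the loss has failed to improve for `patience`
    consecutive epochs, not one epoch sooner."""
    stopper = EarlyStopping(patience=3)
    losses = [1.0, 0.8, 0.9, 0.85, 0.81]  # best at epoch 2, then 3 bad epochs
    stops = [stopper.update(l, e) for e, l in enumerate(losses, 1)]
    assert stops == [False, False, False, False, True]
    assert stopper.best == 0.8 and stopper.best_epoch == 2


def test_early_stopping_improvement_resets_wait():
    stopper = EarlyStopping(patience=2)
    assert not stopper.update(1.0, 1)
    assert not stopper.update(1.1, 2)
    assert not stopper.update(0.9, 3)  # reset
    assert not stopper.update(0.95, 4)
    assert stopper.update(0.96, 5)


def test_patience_zero_rejected():
    with pytest.raises(ValueError):
        EarlyStopping(patience=0)
    with pytest.raises(ValueError):
        ModelConfig(early_stop_patience=0)


def test_config_validation():
    with pytest.raises(ValueError):
        ModelConfig(val_fraction=0.0)
    with pytest.raises(ValueError):
        ModelConfig(dropout=1.0)
    with pytest.raises(ValueError):
        ModelConfig(architecture="transformer")


# ----------------------------------------------------------------- training

def test_validation_split_is_deterministic_and_disjoint():
    rng1 = np.random.default_rng(5)
    rng2 = np.random.default_rng(5)
    tr1, va1 = validation_split(50, 0.2, rng1)
    tr2, va2 = validation_split(50, 0.2, rng2)
    assert np.array_equal(tr1, tr2) and np.array_equal(va1, va2)
    assert len(va1) == 10
    assert set(tr1).isdisjoint(va1)
    assert set(tr1) | set(va1) == set(range(50))


def test_training_fits_constant_target():
    """A dataset whose label is constant must be fit almost exactly."""
    rng = np.random.default_rng(0)
    X = rng.random((30, 4, 8, 4))
    c = 2500.0
    y = np.full(30, c)
    cfg = _tiny_config(epochs=60, early_stop_patience=60, learning_rate=1e-2)
    model = train((X, y), cfg)
    preds = predict(model, X)
    assert np.sqrt(np.mean((preds - c) ** 2)) < 0.05 * c


def test_training_learns_linear_signal():
    """Yields driven by the mean histogram position must be learnable to
    well below the label standard deviation."""
    rng = np.random.default_rng(1)
    X = np.zeros((80, 4, 8, 4))
    pos = rng.integers(0, 8, size=80)
    for i, p in enumerate(pos):
        X[i, :, p, :] = 1.0
    y = 2000.0 + 150.0 * pos
    cfg = _tiny_config(conv_filters=(4, 8), lstm_units=8, dense_units=4,
                       epochs=80, early_stop_patience=80, learning_rate=5e-3)
    model = train((X, y), cfg)
    preds = predict(model, X)
    rmse = np.sqrt(np.mean((preds - y) ** 2))
    assert rmse < 0.3 * y.std()


def test_training_is_deterministic_for_fixed_seed():
    rng = np.random.default_rng(2)
    X = rng.random((20, 2, 8, 4))
    y = rng.random(20) * 100
    cfg = _tiny_config(epochs=3)
    m1 = train((X, y), cfg)
    m2 = train((X, y), cfg)
    assert np.array_equal(m1.val_indices, m2.val_indices)
    assert m1.history == m2.history
    assert np.array_equal(predict(m1, X), predict(m2, X))


def test_stopped_epoch_respects_patience():
    rng = np.random.default_rng(4)
    X = rng.random((20, 2, 8, 4))
    y = rng.random(20)
    cfg = _tiny_config(epochs=40, early_stop_patience=3, learning_rate=0.0)
    model = train((X, y), cfg)  # zero learning rate: no improvement possible
    assert model.stopped_epoch <= 4  # first epoch sets best, then 3 stale


def test_predict_contracts():
    rng = np.random.default_rng(0)
    X = rng.random((10, 4, 8, 4))
    y = rng.random(10)
    model = train((X, y), _tiny_config(epochs=2, early_stop_patience=2))
    assert predict(model, []).size == 0
    two = np.repeat(X[:1], 2, axis=0)
    p = predict(model, two)
    assert p[0] == p[1]
    with pytest.raises(ValueError, match="t="):
        predict(model, rng.random((3, 7, 8, 4)))
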