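"""Network construction arithmetic, training contracts, and linear-limit oracles."""

import numpy as np
import pytest
from sklearn.linear_model import Ridge

import gblupnet.deep as deep
from gblupnet import _nn


def test_mlp_parameter_count_arithmetic():
    cfg = deep.NetworkConfig(arch="mlp", hidden_sizes=(2,), learning_rate=1e-3)
    model = deep.build_model(cfg, n_markers=3)
    assert model.n_params == 3 * 2 + 2 + 2 * 1 + 1  # 11


def test_cnn_convolution_arithmetic():
    cfg = deep.NetworkConfig(
        arch="cnn", hidden_sizes=(4,), conv_filters=1, kernel_size=5, pool_size=3
    )
    model = deep.build_model(cfg, n_markers=10)
    conv = model.net.layers[0]
    out = conv.forward(np.zeros((2, 10)))
    assert out.shape == (2, 6, 1)  # valid padding: 10 - 5 + 1
    pooled = model.net.layers[2].forward(out)
    assert pooled.shape == (2, 2, 1)  # two non-overlapping windows of 3


def test_config_validation():
    with pytest.raises(ValueError, match="convolution"):
        deep.NetworkConfig(arch="mlp", conv_filters=4)
    with pytest.raises(ValueError):
        deep.NetworkConfig(arch="qrnn")
    with pytest.raises(ValueError):
        deep.NetworkConfig(arch="mlp", learning_rate=-1.0)
    with pytest.raises(ValueError, match="kernel"):
        deep.build_model(deep.NetworkConfig(arch="cnn", kernel_size=50), n_markers=10)


def test_presets_cover_both_lines():
    sire_cnn = deep.preset("sire", "cnn")
    dam_cnn = deep.preset("dam", "cnn")
    assert sire_cnn.conv_filters == 16 and dam_cnn.conv_filters == 8
    assert deep.preset("sire", "mlp").hidden_sizes == (96, 64, 32, 16)
    assert deep.preset("dam", "mlp").l1 == 0.007
    with pytest.raises(ValueError):
        deep.preset("terminal", "mlp")


def test_same_seed_identical_initial_weights():
    cfg = deep.NetworkConfig(arch="mlp", hidden_sizes=(8, 4), seed=9)
    w1 = deep.build_model(cfg, 20).net.get_weights()
    w2 = deep.build_model(cfg, 20).net.get_weights()
    for a, b in zip(w1, w2):
        assert np.array_equal(a, b)
    w3 = deep.build_model(deep.NetworkConfig(arch="mlp", hidden_sizes=(8, 4), seed=10), 20)
    assert not np.array_equal(w1[0], w3.net.get_weights()[0])


@pytest.fixture(scope="module")
def additive_task():
    rng = np.random.default_rng(0)
    n, m = 1200, 150
    X = rng.integers(0, 3, size=(n, m)).astype(float)
    w = rng.normal(size=m)
    y = X @ w
    y = (y - y.mean()) / y.std()
    return X, y


def test_mlp_learns_noiseless_additive_target(additive_task):
    X, y = additive_task
    cfg = deep.NetworkConfig(
        arch="mlp", hidden_sizes=(64, 32), l1=0.0, l2=0.0, learning_rate=2e-3,
        max_epochs=300, early_stop_patience=30, seed=1,
    )
    model = deep.build_model(cfg, X.shape[1])
    _, hist = deep.train(model, X[:800], y[:800], X[800:1000], y[800:1000])
    assert hist["best_val_loss"] < 0.05 * y.var()


def test_zero_epoch_budget_keeps_initialization(additive_task):
    X, y = additive_task
    cfg = deep.NetworkConfig(arch="mlp", hidden_sizes=(8,), max_epochs=0, seed=2)
    model = deep.build_model(cfg, X.shape[1])
    before = model.net.get_weights()
    deep.train(model, X[:100], y[:100], X[100:150], y[100:150])
    for a, b in zip(before, model.net.get_weights()):
        assert np.array_equal(a, b)


def test_early_stopping_restores_best_validation_weights(additive_task):
    X, y = additive_task
    cfg = deep.NetworkConfig(
        arch="mlp", hidden_sizes=(16,), learning_rate=5e-3, max_epochs=150,
        early_stop_patience=5, seed=3,
    )
    model = deep.build_model(cfg, X.shape[1])
    _, hist = deep.train(model, X[:300], y[:300], X[300:400], y[300:400])
    val = np.array(hist["val_loss"])
    best_epoch = int(val.argmin())
    # halts within patience of the best epoch, and holds the best weights
    assert len(val) <= best_epoch + cfg.early_stop_patience + 1
    restored = float(np.mean((model.predict(X[300:400]) - y[300:400]) ** 2))
    assert restored == pytest.approx(val.min(), rel=1e-10)


def test_duplicate_rows_and_order_invariance(additive_task):
    X, y = additive_task
    cfg = deep.NetworkConfig(arch="mlp", hidden_sizes=(8,), seed=4, max_epochs=0)
    model = deep.build_model(cfg, X.shape[1])
    deep.train(model, X[:50], y[:50], X[50:80], y[50:80])
    dup = np.vstack([X[:5], X[:5]])
    pred = model.predict(dup)
    assert np.allclose(pred[:5], pred[5:])
    perm = np.random.default_rng(0).permutation(30)
    assert np.allclose(model.predict(X[:30][perm]), model.predict(X[:30])[perm])


def test_known_linear_weights_predict_exactly():
    rng = np.random.default_rng(5)
    w = rng.normal(size=7)
    layer = _nn.Dense(7, 1, rng)
    layer.W[:, 0] = w
    layer.b[0] = 2.5
    net = _nn.Sequential([layer])
    X = rng.normal(size=(11, 7))
    assert np.allclose(net.predict(X), X @ w + 2.5, atol=1e-12)


def test_nan_loss_aborts_with_diagnostics(additive_task):
    X, y = additive_task
    cfg = deep.NetworkConfig(
        arch="mlp", hidden_sizes=(32,), learning_rate=1e-3, max_epochs=20, seed=6
    )
    model = deep.build_model(cfg, X.shape[1])
    model.net.params()[0][0, 0] = np.nan  # poisoned weight: loss must not pass silently
    with pytest.raises(FloatingPointError, match="epoch"):
        deep.train(model, X[:200], y[:200], X[200:260], y[200:260])


def test_shape_mismatch_rejected(additive_task):
    X, y = additive_task
    model = deep.build_model(deep.NetworkConfig(arch="mlp", hidden_sizes=(4,)), X.shape[1])
    with pytest.raises(ValueError, match="expected"):
        model.predict(X[:, :10])


def test_linear_activation_mlp_matches_ridge_regression():
    # leaky slope 1.0 makes every activation the identity: the trained MLP is
    # a product of linear maps and should track a ridge fit closely
    rng = np.random.default_rng(7)
    n, m = 2000, 500
    X = rng.integers(0, 3, size=(n, m)).astype(float)
    y = X @ (rng.normal(size=m) * 0.1) + rng.normal(scale=0.5, size=n)
    y = (y - y.mean()) / y.std()
    cfg = deep.NetworkConfig(
        arch="mlp", hidden_sizes=(32,), leaky_alpha=1.0, l1=0.0, l2=0.0,
        learning_rate=1e-3, max_epochs=150, early_stop_patience=20, seed=2,
    )
    model = deep.build_model(cfg, m)
    deep.train(model, X[:1400], y[:1400], X[1400:1700], y[1400:1700])
    ridge = Ridge(alpha=1.0).fit(X[:1400], y[:1400]).predict(X[1700:])
    assert np.corrcoef(model.predict(X[1700:]), ridge)[0, 1] > 0.98


def test_cnn_trains_and_predicts(additive_task):
    X, y = additive_task
    cfg = deep.NetworkConfig(
        arch="cnn", hidden_sizes=(16,), conv_filters=4, kernel_size=5, pool_size=3,
        learning_rate=1e-3, max_epochs=15, early_stop_patience=5, seed=8,
    )
    model = deep.build_model(cfg, X.shape[1])
    _, hist = deep.train(model, X[:400], y[:400], X[400:500], y[400:500])
    assert len(hist["val_loss"]) >= 1
    assert np.all(np.isfinite(model.predict(X[500:520])))


def test_average_pooling_option(additive_task):
    X, y = additive_task
    cfg = deep.NetworkConfig(
        arch="cnn", hidden_sizes=(8,), conv_filters=2, kernel_size=5, pool_size=3,
        pool_type="average", max_epochs=2, learning_rate=1e-3, seed=9,
    )
    model = deep.build_model(cfg, X.shape[1])
    deep.train(model, X[:200], y[:200], X[200:260], y[200:260])
    assert np.all(np.isfinite(model.predict(X[:10])))


def test_save_load_roundtrip(tmp_path, additive_task):
    X, y = additive_task
    cfg = deep.NetworkConfig(arch="mlp", hidden_sizes=(8, 4), max_epochs=3,
                             learning_rate=1e-3, seed=10)
    model = deep.build_model(cfg, X.shape[1])
    deep.train(model, X[:200], y[:200], X[200:260], y[200:260])
    path = str(tmp_path / "ckpt.npz")
    deep.save_model(model, path)
    loaded = deep.load_model(path)
    assert np.allclose(loaded.predict(X[:20]), model.predict(X[:20]), atol=1e-12)
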