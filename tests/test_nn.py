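"""Network mechanics: exact gradients, determinism, checkpoints, training."""

import numpy as np
import pytest

from epiguide.nn import Adam, CasCNN, ModelConfig, build_model, loss_and_grad


def _tiny_net(task="regression", seed=3, dropout=0.0):
    cfg = ModelConfig(kernel_sizes=(1, 2, 3), filters_per_size=4, fc_units=(6, 5),
                      dropout=dropout, task=task, seed=seed)
    return CasCNN(5, 12, cfg), cfg


def _num_grad(f, arr, idx, eps=1e-6):
    arr[idx] += eps
    lp = f()
    arr[idx] -= 2 * eps
    lm = f()
    arr[idx] += eps
    return (lp - lm) / (2 * eps)


@pytest.mark.parametrize("task", ["regression", "classification"])
def test_backprop_matches_finite_differences(task):
    net, _ = _tiny_net(task=task)
    rng = np.random.default_rng(0)
    X = rng.normal(size=(7, 5, 12))
    y = rng.normal(size=7) if task == "regression" else (rng.random(7) > 0.5).astype(float)

    def loss_of():
        raw, _ = net.forward(X, training=False)
        return loss_and_grad(raw, y, task)[0]

    raw, cache = net.forward(X, training=False)
    _, draw = loss_and_grad(raw, y, task)
    grads, dX = net.backward(draw, cache, want_input_grad=True)
    for name in ("convW2", "convb3", "W0", "b1", "bn_gamma", "bn_beta", "W2"):
        p = net.params[name]
        idx = tuple(0 for _ in p.shape)
        num = _num_grad(loss_of, p, idx)
        assert grads[name][idx] == pytest.approx(num, rel=1e-5, abs=1e-8)
    idx = (2, 1, 5)
    assert dX[idx] == pytest.approx(_num_grad(loss_of, X, idx), rel=1e-5, abs=1e-8)


def test_backprop_through_training_mode_batchnorm():
    net, _ = _tiny_net(task="classification", seed=5)
    rng = np.random.default_rng(1)
    X = rng.normal(size=(9, 5, 12))
    y = (rng.random(9) > 0.5).astype(float)

    def loss_of():
        rm, rv = net.running_mean.copy(), net.running_var.copy()
        raw, _ = net.forward(X, training=True, dropout_rng=np.random.default_rng(0))
        net.running_mean, net.running_var = rm, rv
        return loss_and_grad(raw, y, "classification")[0]

    rm, rv = net.running_mean.copy(), net.running_var.copy()
    raw, cache = net.forward(X, training=True, dropout_rng=np.random.default_rng(0))
    net.running_mean, net.running_var = rm, rv
    _, draw = loss_and_grad(raw, y, "classification")
    grads, _ = net.backward(draw, cache)
    for name in ("convW1", "bn_gamma", "bn_beta", "W0", "W1"):
        p = net.params[name]
        idx = tuple(0 for _ in p.shape)
        assert grads[name][idx] == pytest.approx(_num_grad(loss_of, p, idx), rel=1e-4, abs=1e-8)


def test_default_architecture_summary():
    net, summary = build_model((11, 40), ModelConfig())
    assert summary["n_branches"] == 5
    assert summary["total_filters"] == 150
    assert summary["fc_units"] == [80, 60, 40]
    assert summary["dropout"] == 0.4
    conv_layers = [l for l in summary["layers"] if l["layer"].startswith("conv1d")]
    assert [l["output_shape"][1] for l in conv_layers] == [40, 39, 38, 37, 36]


def test_minimal_config_builds_and_trains():
    cfg = ModelConfig(kernel_sizes=(1,), filters_per_size=1, fc_units=(2,),
                      dropout=0.0, seed=0, batch_size=5)
    net = CasCNN(4, 23, cfg)
    rng = np.random.default_rng(0)
    X, y = rng.normal(size=(10, 4, 23)), rng.normal(size=10)
    opt = Adam(net.params, lr=1e-3)
    raw, cache = net.forward(X, training=True, dropout_rng=rng)
    _, draw = loss_and_grad(raw, y, "regression")
    grads, _ = net.backward(draw, cache)
    opt.step(net.params, grads)  # one full update without error


def test_too_small_input_errors():
    with pytest.raises(ValueError, match="kernel"):
        CasCNN(4, 3, ModelConfig(kernel_sizes=(1, 5)))


def test_same_seed_same_init_and_first_epoch_loss():
    losses = []
    for _ in range(2):
        net, cfg = _tiny_net(seed=11, dropout=0.4)
        rng = np.random.default_rng(99)
        X, y = rng.normal(size=(20, 5, 12)), rng.normal(size=20)
        drop_rng = np.random.default_rng(cfg.seed)
        opt = Adam(net.params, lr=1e-3)
        raw, cache = net.forward(X, training=True, dropout_rng=drop_rng)
        loss, draw = loss_and_grad(raw, y, "regression")
        grads, _ = net.backward(draw, cache)
        opt.step(net.params, grads)
        losses.append((loss, net.params["W0"].copy()))
    assert losses[0][0] == losses[1][0]
    assert np.array_equal(losses[0][1], losses[1][1])


def test_checkpoint_reload_bit_identical(tmp_path):
    net, _ = _tiny_net(seed=2)
    rng = np.random.default_rng(3)
    X = rng.normal(size=(8, 5, 12))
    net.running_mean[:] = rng.normal(size=net.n_features)
    net.running_var[:] = np.abs(rng.normal(size=net.n_features)) + 0.5
    before = net.predict(X)
    net.save(tmp_path / "ckpt")
    reloaded = CasCNN.load(tmp_path / "ckpt")
    assert np.array_equal(reloaded.predict(X), before)


def test_training_loss_decreases_on_learnable_data():
    from epiguide.model import fit_network

    cfg = ModelConfig(kernel_sizes=(1, 2), filters_per_size=8, fc_units=(16,),
                      dropout=0.0, task="regression", seed=0, max_epochs=5,
                      patience=5, batch_size=32, learning_rate=3e-3)
    net = CasCNN(4, 23, cfg)
    rng = np.random.default_rng(0)
    X = np.stack([np.eye(4)[rng.integers(0, 4, size=23)].T for _ in range(300)])
    y = 2.0 * X[:, 2, 10] - 1.0 * X[:, 0, 5]    # depends on G@11 and A@6
    hist = fit_network(net, X[:250], y[:250], X[250:], y[250:], cfg)
    losses = [h["train_loss"] for h in hist]
    assert losses[-1] < losses[0]
    assert losses[0] - losses[-1] > 0.1 * losses[0]
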