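import numpy as np
import pytest
from scipy import ndimage

from hrfprobe.nn import (Hyperparams, NetworkSpec, ResNet3d,
                         TrainingDivergence, bce_with_logits, load_network,
                         save_network, sgd_momentum_step, train_network)
from hrfprobe.nn.layers import Conv3d, Dense, MaxPool3d, ReLU
from hrfprobe.nn.network import ResidualBlock

SMALL = NetworkSpec(input_shape=(16, 16, 16, 2), channels=(2, 2, 2, 2, 4),
                    dropout_rate=0.0)


# ----------------------------------------------------------- conv layer
def test_conv3d_matches_scipy_correlate_oracle(rng):
    x = rng.normal(size=(2, 3, 5, 5, 5))
    conv = Conv3d(3, 4, rng=rng)
    out = conv.forward(x)
    w, b = conv.params["w"], conv.params["b"]
    for n in range(2):
        for co in range(4):
            oracle = sum(
                ndimage.correlate(x[n, ci], w[co, ci], mode="constant")
                for ci in range(3)) + b[co]
            assert np.max(np.abs(out[n, co] - oracle)) < 1e-10


def test_conv3d_gradients_match_finite_differences(rng):
    x = rng.normal(size=(1, 2, 4, 4, 4))
    conv = Conv3d(2, 2, rng=rng)
    out = conv.forward(x, training=True)
    g = rng.normal(size=out.shape)
    dx = conv.backward(g)

    def loss(xx):
        return float((conv.forward(xx) * g).sum())

    eps = 1e-6
    for idx in [(0, 0, 0, 0, 0), (0, 1, 2, 3, 1), (0, 0, 3, 3, 3)]:
        xp = x.copy(); xp[idx] += eps
        xm = x.copy(); xm[idx] -= eps
        num = (loss(xp) - loss(xm)) / (2 * eps)
        assert num == pytest.approx(dx[idx], rel=1e-4, abs=1e-7)
    # weight gradient at a couple of entries
    widx = (1, 0, 0, 1, 2)
    base_w = conv.params["w"].copy()
    conv.params["w"] = base_w.copy(); conv.params["w"][widx] += eps
    lp = loss(x)
    conv.params["w"] = base_w.copy(); conv.params["w"][widx] -= eps
    lm = loss(x)
    conv.params["w"] = base_w
    conv.forward(x, training=True)
    conv.backward(g)
    assert (lp - lm) / (2 * eps) == pytest.approx(
        conv.grads["w"][widx], rel=1e-4)


def test_maxpool_routes_gradient_to_winner(rng):
    pool = MaxPool3d()
    x = rng.normal(size=(1, 1, 4, 4, 4))
    out = pool.forward(x)
    g = np.ones_like(out)
    back = pool.backward(g)
    assert back.sum() == out.size              # one winner per block
    assert np.all((back > 0) <= (x == np.repeat(np.repeat(np.repeat(
        out, 2, 2), 2, 3), 2, 4)))


# ------------------------------------------------------------- network
def test_zero_weight_network_outputs_one_half():
    net = ResNet3d(SMALL, rng_seed=0)
    for layer, name, value in net.parameters():
        value[...] = 0.0
    x = np.zeros((2, 16, 16, 16, 2))
    assert np.allclose(net.predict_proba(x), 0.5)


def test_parameter_count_matches_arithmetic_oracle():
    """Layer-by-layer hand sum for the small spec."""
    net = ResNet3d(SMALL, rng_seed=0)

    def conv_params(cin, cout, k=3):
        return cout * cin * k ** 3 + cout

    def bn_params(c):
        return 2 * c

    expected = conv_params(2, 2) + bn_params(2)          # stem
    prev = 2
    for c in (2, 2, 2, 4):
        expected += conv_params(prev, c) + bn_params(c)    # conv1 + bn1
        expected += conv_params(c, c) + bn_params(c)       # conv2 + bn2
        if prev != c:
            expected += conv_params(prev, c, k=1) + bn_params(c)
        prev = c
    expected += 4 * 1 * 1 + 1                            # dense head
    assert net.n_parameters() == expected


def test_four_blocks_each_halve_spatial_extent(rng):
    net = ResNet3d(SMALL, rng_seed=0)
    assert len(net.blocks) == 4
    x = rng.normal(size=(1, 2, 16, 16, 16))
    x = net.stem_relu.forward(net.stem_bn.forward(net.stem.forward(x)))
    for i, block in enumerate(net.blocks):
        x = block.forward(x)
        assert x.shape[2:] == (16 // 2 ** (i + 1),) * 3


def test_residual_block_with_zero_convs_is_pooled_identity(rng):
    block = ResidualBlock(3, 3, rng=np.random.default_rng(0))
    for sub in block.sublayers():
        for name in sub.params:
            if name in ("w", "b"):
                sub.params[name][...] = 0.0
    x = np.abs(rng.normal(size=(1, 3, 8, 8, 8)))  # nonneg input pathway
    out = block.forward(x)
    pool = MaxPool3d()
    assert np.allclose(out, pool.forward(x))


def test_small_input_rejected():
    with pytest.raises(ValueError):
        NetworkSpec(input_shape=(8, 8, 8, 2), channels=(2, 2, 2, 2, 4))


def test_inference_is_deterministic_and_bounded(rng):
    net = ResNet3d(SMALL, rng_seed=1)
    x = rng.normal(size=(3, 16, 16, 16, 2))
    p1 = net.predict_proba(x)
    p2 = net.predict_proba(x)
    assert np.array_equal(p1, p2)
    assert np.all((p1 >= 0) & (p1 <= 1))


def test_checkpoint_round_trip(tmp_path, rng):
    net = ResNet3d(SMALL, rng_seed=2)
    x = rng.normal(size=(2, 16, 16, 16, 2))
    path = tmp_path / "model.npz"
    save_network(net, path)
    back = load_network(path)
    assert np.allclose(net.predict_proba(x), back.predict_proba(x))


# ------------------------------------------------------------ training
def test_bce_matches_manual_formula(rng):
    z = rng.normal(size=6)
    y = (rng.random(6) > 0.5).astype(float)
    loss, _ = bce_with_logits(z, y)
    p = 1 / (1 + np.exp(-z))
    manual = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
    assert loss == pytest.approx(manual, rel=1e-10)


def test_zero_learning_rate_leaves_weights_unchanged(rng):
    net = ResNet3d(SMALL, rng_seed=3)
    before = [v.copy() for _, _, v in net.parameters()]
    x = rng.normal(size=(4, 16, 16, 16, 2))
    y = np.array([0, 1, 0, 1.0])
    train_network(net, x, y, Hyperparams(learning_rate=0.0,
                                         training_steps=3, batch_size=4,
                                         dropout_rate=0.0))
    after = [v for _, _, v in net.parameters()]
    assert all(np.array_equal(a, b) for a, b in zip(before, after))


def test_sgd_momentum_equals_two_step_recurrence():
    """One-parameter quadratic: v_{t+1} = m v_t - lr g_t, w += v."""
    dense = Dense(1, 1)
    dense.params["w"][...] = 2.0
    dense.params["b"][...] = 0.0

    class Net:
        def parameters(self):
            yield dense, "w", dense.params["w"]

    lr, mom = 0.1, 0.9
    vel = {}
    w_hand, v_hand = 2.0, 0.0
    for _ in range(5):
        g = 2.0 * dense.params["w"][0, 0]  # d/dw of w^2
        dense.grads["w"] = np.array([[g]])
        sgd_momentum_step(Net(), vel, lr, mom)
        v_hand = mom * v_hand - lr * (2.0 * w_hand)
        w_hand = w_hand + v_hand
        assert dense.params["w"][0, 0] == pytest.approx(w_hand, rel=1e-12)


def test_loss_decreases_over_first_steps(rng):
    net = ResNet3d(SMALL, rng_seed=4)
    x = rng.normal(size=(6, 16, 16, 16, 2))
    x[:3, 4:8, 4:8, 4:8, :] += 2.0  # separable signal
    y = np.array([1, 1, 1, 0, 0, 0.0])
    losses = []
    train_network(net, x, y,
                  Hyperparams(learning_rate=0.05, momentum=0.9,
                              training_steps=10, batch_size=6,
                              dropout_rate=0.0),
                  rng_seed=0, loss_callback=lambda s, l: losses.append(l))
    assert losses[-1] < losses[0]


def test_single_sample_per_class_overfits_to_perfect_accuracy(rng):
    net = ResNet3d(SMALL, rng_seed=5)
    x = rng.normal(size=(2, 16, 16, 16, 2))
    y = np.array([0, 1.0])
    train_network(net, x, y,
                  Hyperparams(learning_rate=0.05, momentum=0.9,
                              training_steps=40, batch_size=2,
                              dropout_rate=0.0), rng_seed=0)
    pred = (net.predict_proba(x) >= 0.5).astype(int)
    assert np.array_equal(pred, [0, 1])


def test_divergent_learning_rate_raises_naming_hyperparams(rng):
    net = ResNet3d(SMALL, rng_seed=6)
    x = rng.normal(size=(4, 16, 16, 16, 2)) * 10
    y = np.array([0, 1, 0, 1.0])
    with pytest.raises((TrainingDivergence, FloatingPointError),
                       match="learning_rate|overflow"):
        with np.errstate(over="raise"):
            train_network(net, x, y,
                          Hyperparams(learning_rate=1e6, momentum=0.99,
                                      training_steps=30, batch_size=4,
                                      dropout_rate=0.0))


def test_single_class_training_rejected(rng):
    net = ResNet3d(SMALL, rng_seed=7)
    x = rng.normal(size=(3, 16, 16, 16, 2))
    with pytest.raises(ValueError):
        train_network(net, x, np.ones(3), Hyperparams(training_steps=1))


def test_training_deterministic_under_seed(rng):
    x = rng.normal(size=(4, 16, 16, 16, 2))
    y = np.array([0, 1, 0, 1.0])
    hp = Hyperparams(learning_rate=0.02, training_steps=5, batch_size=4,
                     dropout_rate=0.3)
    p = []
    for _ in range(2):
        net = ResNet3d(SMALL, rng_seed=8)
        train_network(net, x, y, hp, rng_seed=9)
        p.append(net.predict_proba(x))
    assert np.array_equal(p[0], p[1])
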