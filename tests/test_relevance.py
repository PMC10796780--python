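import numpy as np
import pytest

from hrfprobe.nn import NetworkSpec, ResNet3d
from hrfprobe.relevance import (RelevanceMap, aggregate_heatmaps,
                                dtd_heatmap, fold_conv_bn,
                                group_average_comparison,
                                _zplus_dense)

SMALL = NetworkSpec(input_shape=(16, 16, 16, 2), channels=(2, 2, 2, 2, 4),
                    dropout_rate=0.0)


# ------------------------------------------------- closed-form z+ rule
def test_single_dense_layer_zplus_closed_form(rng):
    """R_i = w_i x_i / sum_j w_j x_j * output for positive weights/input."""
    x = np.abs(rng.normal(size=(1, 5))) + 0.1
    w = np.abs(rng.normal(size=(5, 1))) + 0.1
    out = float((x @ w)[0, 0])
    rel = _zplus_dense(x, w, np.array([[out]]))
    expected = (w[:, 0] * x[0]) / out * out
    assert np.max(np.abs(rel[0] - expected)) < 1e-9
    assert rel.sum() == pytest.approx(out, rel=1e-9)


def _mlp_forward(x, weights):
    a = x
    acts = [a]
    for i, w in enumerate(weights):
        z = a @ w
        a = np.maximum(z, 0.0) if i < len(weights) - 1 else z
        acts.append(a)
    return acts


def _taylor_oracle(x, weights):
    """Brute-force deep Taylor relevance for a positive-weight, bias-free
    MLP: per neuron, bisection root search along the segment toward the
    origin, finite-difference gradient at the root, recursively applied
    layer by layer."""
    acts = _mlp_forward(x, weights)
    rel = acts[-1].copy()  # output relevance = network output
    for layer in range(len(weights) - 1, -1, -1):
        a_in = acts[layer]
        w = weights[layer]
        new_rel = np.zeros_like(a_in)
        for j in range(w.shape[1]):
            if rel[j] <= 0:
                continue
            zj = float(a_in @ w[:, j])
            cj = rel[j] / zj

            def pre_act(t):  # activation along segment x(1-t)
                return float((a_in * (1 - t)) @ w[:, j])

            lo, hi = 0.0, 1.0  # bisection root search for pre_act == 0
            for _ in range(80):
                mid = 0.5 * (lo + hi)
                if pre_act(mid) > 1e-300:
                    lo = mid
                else:
                    hi = mid
            root = a_in * (1 - hi)
            eps = 1e-6
            for i in range(len(a_in)):
                xp = root.copy(); xp[i] += eps
                xm = root.copy(); xm[i] -= eps
                grad = (float(xp @ w[:, j]) - float(xm @ w[:, j])) / (2 * eps)
                new_rel[i] += grad * (a_in[i] - root[i]) * cj
        rel = new_rel
    return rel


def test_zplus_chain_matches_bruteforce_taylor_oracle(rng):
    """Two-layer, all-positive-weight network on <= 8 units."""
    x = np.abs(rng.normal(size=6)) + 0.1
    w1 = np.abs(rng.normal(size=(6, 4))) + 0.05
    w2 = np.abs(rng.normal(size=(4, 1))) + 0.05
    acts = _mlp_forward(x, [w1, w2])
    out = acts[-1]
    rel_hidden = _zplus_dense(acts[1][None, :], w2, out[None, :])[0]
    rel_input = _zplus_dense(x[None, :], w1, rel_hidden[None, :])[0]
    oracle = _taylor_oracle(x, [w1, w2])
    assert np.max(np.abs(rel_input - oracle) / np.abs(oracle)) < 1e-6
    assert rel_input.sum() == pytest.approx(float(out[0]), rel=1e-9)


# ------------------------------------------------- full-network checks
def _positive_score_net_and_input(rng, tries=10):
    for seed in range(tries):
        net = ResNet3d(SMALL, rng_seed=seed)
        x = rng.normal(size=(16, 16, 16, 2))
        rmap = dtd_heatmap(net, x)
        if rmap.source_decision > 0.1:
            return net, x
    raise AssertionError("no positive-logit configuration found")


def test_layerwise_conservation_on_random_network(rng):
    net, x = _positive_score_net_and_input(rng)
    sums = []
    rmap = dtd_heatmap(net, x, layer_sums=sums)
    totals = [s for _, s in sums]
    assert totals[0] == pytest.approx(rmap.source_decision)
    for prev, cur in zip(totals[:-1], totals[1:]):
        assert abs(cur - prev) / totals[0] < 1e-4
    assert rmap.total == pytest.approx(totals[-1], rel=1e-6)


def test_relevance_is_nonnegative_everywhere(rng):
    net, x = _positive_score_net_and_input(rng)
    rmap = dtd_heatmap(net, x)
    assert np.all(rmap.volume >= 0)
    assert rmap.volume.shape == (16, 16, 16)


def test_zero_input_on_bias_free_network_gives_zero_relevance():
    net = ResNet3d(SMALL, rng_seed=0)
    rmap = dtd_heatmap(net, np.zeros((16, 16, 16, 2)),
                       input_bounds=(-1.0, 1.0))
    assert rmap.source_decision == 0.0
    assert np.all(rmap.volume == 0.0)


def test_scaling_head_weights_scales_relevance(rng):
    net, x = _positive_score_net_and_input(rng)
    base = dtd_heatmap(net, x)
    net.head.params["w"] *= 3.0
    scaled = dtd_heatmap(net, x)
    assert scaled.source_decision == pytest.approx(3 * base.source_decision,
                                                  rel=1e-9)
    assert np.allclose(scaled.volume, 3 * base.volume, rtol=1e-6,
                       atol=1e-12)


def test_bn_folding_preserves_inference(rng):
    """Folded conv+BN weights reproduce the two-layer inference output."""
    from hrfprobe.nn.layers import BatchNorm3d, Conv3d, _conv3d
    conv = Conv3d(2, 3, rng=rng)
    bn = BatchNorm3d(3)
    bn.running_mean[:] = rng.normal(size=3)
    bn.running_var[:] = np.abs(rng.normal(size=3)) + 0.5
    bn.params["gamma"][:] = rng.normal(size=3)
    bn.params["beta"][:] = rng.normal(size=3)
    x = rng.normal(size=(1, 2, 6, 6, 6))
    direct = bn.forward(conv.forward(x), training=False)
    w, b = fold_conv_bn(conv, bn)
    folded, _ = _conv3d(x, w)
    folded = folded + b[None, :, None, None, None]
    assert np.max(np.abs(direct - folded)) < 1e-10


# ---------------------------------------------------------- aggregation
def _map(vol, **kw):
    return RelevanceMap(volume=vol, source_decision=float(vol.sum()), **kw)


def test_aggregate_identical_maps_is_identity(rng):
    vol = np.abs(rng.normal(size=(4, 4, 4)))
    avg = aggregate_heatmaps([_map(vol.copy()) for _ in range(5)],
                             normalize_each=False)
    assert np.allclose(avg, vol)


def test_aggregate_disjoint_unit_maps_splits_mass():
    a = np.zeros((3, 3, 3)); a[0, 0, 0] = 4.0
    b = np.zeros((3, 3, 3)); b[2, 2, 2] = 9.0
    avg = aggregate_heatmaps([_map(a), _map(b)], normalize_each=True)
    assert avg[0, 0, 0] == pytest.approx(0.5)
    assert avg[2, 2, 2] == pytest.approx(0.5)
    assert avg.sum() == pytest.approx(1.0)


def test_aggregate_matches_mean_oracle(rng):
    vols = [np.abs(rng.normal(size=(4, 4, 4))) for _ in range(7)]
    avg = aggregate_heatmaps([_map(v) for v in vols], normalize_each=False)
    assert np.max(np.abs(avg - np.mean(vols, axis=0))) < 1e-12


def test_aggregate_rejects_empty_and_mismatched():
    with pytest.raises(ValueError):
        aggregate_heatmaps([])
    with pytest.raises(ValueError):
        aggregate_heatmaps([_map(np.ones((2, 2, 2))),
                            _map(np.ones((3, 3, 3)))])


def test_group_comparison_identity_and_inversion(rng):
    vol = np.abs(rng.normal(size=(4, 4, 4)))
    _, corr = group_average_comparison(
        {"control": [_map(vol.copy())], "patient": [_map(vol.copy())]},
        normalize_each=False)
    assert corr == pytest.approx(1.0)
    inverted = 2 * vol.mean() - vol
    _, corr = group_average_comparison(
        {"control": [_map(vol.copy())], "patient": [_map(inverted)]},
        normalize_each=False)
    assert corr == pytest.approx(-1.0)


def test_independent_random_maps_are_uncorrelated(rng):
    hits = 0
    for _ in range(10):
        a = np.abs(rng.normal(size=(16, 16, 16)))
        b = np.abs(rng.normal(size=(16, 16, 16)))
        _, corr = group_average_comparison(
            {"control": [_map(a)], "patient": [_map(b)]},
            normalize_each=False)
        hits += abs(corr) < 0.1
    assert hits >= 9


def test_constant_group_map_rejected():
    with pytest.raises(ValueError, match="constant"):
        group_average_comparison(
            {"control": [_map(np.ones((3, 3, 3)))],
             "patient": [_map(np.ones((3, 3, 3)))]})
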