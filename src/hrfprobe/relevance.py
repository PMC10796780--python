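"""Deep Taylor decomposition (DTD) relevance heatmaps.

The classifier's decision is decomposed into nonnegative per-voxel
contributions by propagating relevance backward through the network:

* relevance is seeded at the positive part of the pre-sigmoid logit
  (DTD is defined for positive network outputs);
* batch-normalization layers are folded into the adjacent convolution
  weights/biases first, so every learned layer is linear + ReLU;
* hidden convolution/dense layers use the z+ rule (redistribution
  proportional to positive pre-activation contributions, biases excluded
  from the redistribution);
* max-pooling routes relevance winner-take-all to the pooled maximum;
* additive residual shortcuts split relevance between the two incoming
  branches in proportion to their positive parts;
* the first (stem) convolution uses the bounded-input z^B rule, because
  z-normalized epochs are signed.

Lag-channel relevances are summed into a single 3D map per decision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn.layers import BatchNorm3d, Conv3d, Dense, _conv3d
from .nn.network import ResNet3d

__all__ = ["RelevanceMap", "UnsupportedArchitectureError", "dtd_heatmap",
           "aggregate_heatmaps", "group_average_comparison",
           "fold_conv_bn"]

_EPS = 1e-12


class UnsupportedArchitectureError(TypeError):
    """A layer type with no DTD propagation rule was encountered."""


@dataclass
class RelevanceMap:
    """Nonnegative per-voxel relevance for one classification decision."""

    volume: np.ndarray           # 3D, lag channels summed
    source_decision: float       # propagated (positive part of) logit
    subject_id: str = ""
    model_id: str = ""

    @property
    def total(self) -> float:
        return float(self.volume.sum())


# ---------------------------------------------------------------------
# batch-norm folding
# ---------------------------------------------------------------------
def fold_conv_bn(conv: Conv3d, bn: BatchNorm3d | None):
    """Return (w, b) of the conv with inference-mode BN absorbed."""
    if not isinstance(conv, Conv3d):
        raise UnsupportedArchitectureError(
            f"cannot fold layer of type {type(conv).__name__}")
    w = conv.params["w"].copy()
    b = conv.params["b"].copy()
    if bn is None:
        return w, b
    scale = bn.params["gamma"] / np.sqrt(bn.running_var + bn.eps)
    w *= scale[:, None, None, None, None]
    b = (b - bn.running_mean) * scale + bn.params["beta"]
    return w, b


# ---------------------------------------------------------------------
# propagation rules
# ---------------------------------------------------------------------
def _convT(s: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Transposed convolution: backpropagate s through conv weights w."""
    w_flip = w[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
    out, _ = _conv3d(s, w_flip)
    return out


def _zplus_conv(a: np.ndarray, w: np.ndarray, rel: np.ndarray) -> np.ndarray:
    """z+ rule through a convolution with nonnegative input a."""
    wp = np.maximum(w, 0.0)
    z, _ = _conv3d(a, wp)
    s = rel / (z + _EPS)
    return a * _convT(s, wp)


def _zb_conv(x: np.ndarray, w: np.ndarray, rel: np.ndarray,
             low: float, high: float) -> np.ndarray:
    """Bounded-input z^B rule for the first convolution (signed input)."""
    wp = np.maximum(w, 0.0)
    wm = np.minimum(w, 0.0)
    z, _ = _conv3d(x, w)
    zl, _ = _conv3d(np.full_like(x, low), wp)
    zh, _ = _conv3d(np.full_like(x, high), wm)
    denom = z - zl - zh
    s = rel / (denom + _EPS)
    return (x * _convT(s, w) - low * _convT(s, wp) - high * _convT(s, wm))


def _zplus_dense(a: np.ndarray, w: np.ndarray, rel: np.ndarray) -> np.ndarray:
    wp = np.maximum(w, 0.0)
    z = a @ wp
    s = rel / (z + _EPS)
    return a * (s @ wp.T)


def _split_add(main: np.ndarray, short: np.ndarray, rel: np.ndarray):
    """Split relevance at a residual addition by positive parts."""
    mp = np.maximum(main, 0.0)
    sp = np.maximum(short, 0.0)
    denom = mp + sp + _EPS
    return rel * mp / denom, rel * sp / denom


# ---------------------------------------------------------------------
# full-network heatmap
# ---------------------------------------------------------------------
def dtd_heatmap(
    net: ResNet3d,
    epoch_data: np.ndarray,
    input_bounds: tuple[float, float] | None = None,
    subject_id: str = "",
    model_id: str = "",
    layer_sums: list | None = None,
) -> RelevanceMap:
    """Relevance heatmap for one averaged epoch (x, y, z, lag).

    `input_bounds` are the (low, high) bounds of the z^B rule at the stem
    convolution; by default the observed min/max of the epoch itself.
    If `layer_sums` is a list, (stage name, total relevance) pairs are
    appended after every propagation step so layer-wise conservation can
    be audited.
    """
    x = net._to_batch(epoch_data)  # (1, lag, X, Y, Z)
    if x.shape[0] != 1:
        raise ValueError("dtd_heatmap explains one decision at a time")
    low, high = (input_bounds if input_bounds is not None
                 else (float(x.min()), float(x.max())))

    # -- inference forward pass with folded weights, caching activations
    w_stem, b_stem = fold_conv_bn(net.stem, net.stem_bn)
    z, _ = _conv3d(x, w_stem)
    a = np.maximum(z + b_stem[None, :, None, None, None], 0.0)

    cache = []
    for block in net.blocks:
        w1, b1 = fold_conv_bn(block.conv1, block.bn1)
        w2, b2 = fold_conv_bn(block.conv2, block.bn2)
        z1, _ = _conv3d(a, w1)
        a1 = np.maximum(z1 + b1[None, :, None, None, None], 0.0)
        z2, _ = _conv3d(a1, w2)
        main = z2 + b2[None, :, None, None, None]
        if block.projection is not None:
            wp_, bp_ = fold_conv_bn(block.projection, block.bn_proj)
            zs, _ = _conv3d(a, wp_)
            short = zs + bp_[None, :, None, None, None]
        else:
            wp_, bp_ = None, None
            short = a
        out = np.maximum(main + short, 0.0)
        pooled = block.pool.forward(out)
        cache.append({"a_in": a, "a1": a1, "w1": w1, "w2": w2,
                      "w_proj": wp_, "main": main, "short": short,
                      "pool": block.pool})
        a = pooled

    if not isinstance(net.head, Dense):
        raise UnsupportedArchitectureError(
            f"unsupported head layer {type(net.head).__name__}")
    features = a.reshape(1, -1)
    logit = float((features @ net.head.params["w"]
                   + net.head.params["b"])[0, 0])
    score = max(logit, 0.0)

    # -- relevance backward pass
    def note(stage: str, r: np.ndarray) -> None:
        if layer_sums is not None:
            layer_sums.append((stage, float(r.sum())))

    note("output", np.array([score]))
    rel = _zplus_dense(features, net.head.params["w"],
                       np.array([[score]]))
    note("head", rel)
    rel = rel.reshape(a.shape)
    for bi, entry in zip(reversed(range(len(cache))), reversed(cache)):
        rel = entry["pool"].route(rel)  # winner-take-all un-pooling
        note(f"block{bi}.pool", rel)
        r_main, r_short = _split_add(entry["main"], entry["short"], rel)
        note(f"block{bi}.split", r_main + r_short)
        r = _zplus_conv(entry["a1"], entry["w2"], r_main)
        note(f"block{bi}.conv2", r + r_short)
        r = _zplus_conv(entry["a_in"], entry["w1"], r)
        if entry["w_proj"] is not None:
            r += _zplus_conv(entry["a_in"], entry["w_proj"], r_short)
        else:
            r += r_short
        rel = r
        note(f"block{bi}.conv1", rel)

    rel = _zb_conv(x, w_stem, rel, low, high)
    note("stem", rel)
    volume = np.maximum(rel[0], 0.0).sum(axis=0)  # sum lag channels -> 3D
    return RelevanceMap(volume=volume, source_decision=score,
                        subject_id=subject_id, model_id=model_id)


# ---------------------------------------------------------------------
# aggregation across subjects / groups
# ---------------------------------------------------------------------
def aggregate_heatmaps(maps: list[RelevanceMap],
                       normalize_each: bool = True) -> np.ndarray:
    """Voxelwise mean map; optionally scale each map to unit sum first so
    every decision contributes equal total relevance."""
    if not maps:
        raise ValueError("no heatmaps to aggregate")
    shapes = {m.volume.shape for m in maps}
    if len(shapes) != 1:
        raise ValueError(f"heatmap shapes differ: {shapes}")
    vols = []
    for m in maps:
        v = m.volume
        if normalize_each:
            total = v.sum()
            v = v / total if total > 0 else v
        vols.append(v)
    return np.mean(vols, axis=0)


def group_average_comparison(maps_by_group: dict[str, list[RelevanceMap]],
                             normalize_each: bool = True):
    """Per-group average maps plus their spatial (Pearson) correlation."""
    if any(not v for v in maps_by_group.values()) or len(maps_by_group) < 2:
        raise ValueError("need non-empty heatmap lists for both groups")
    averages = {g: aggregate_heatmaps(v, normalize_each)
                for g, v in maps_by_group.items()}
    flat = [a.ravel() for a in averages.values()]
    if any(np.std(f) < 1e-15 for f in flat):
        raise ValueError("similarity undefined for a constant average map")
    corr = float(np.corrcoef(flat[0], flat[1])[0, 1])
    return averages, corr
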