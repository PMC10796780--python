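"""Slim 3D residual network for group classification of averaged epochs.

Architecture: one 3D convolution stem (BN + ReLU), four residual blocks
(each: conv-BN-ReLU-conv-BN, additive shortcut with a 1x1x1 projection
when channel counts change, ReLU, then 2x2x2 max pooling halving every
spatial axis), a flatten, dropout, and a single-logit dense head read out
through a sigmoid.  All convolutions are stride 1 with 3x3x3 kernels;
spatial downsampling happens only in the pooling layers.  The epoch's lag
axis enters as the input channel axis, preserving 3D spatial convolution
semantics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .layers import (BatchNorm3d, Conv3d, Dense, Dropout, Flatten, Layer,
                     MaxPool3d, ReLU)

__all__ = ["NetworkSpec", "ResidualBlock", "ResNet3d",
           "save_network", "load_network"]


@dataclass(frozen=True)
class NetworkSpec:
    """Hyper-structure of the classifier.

    ``channels`` lists the stem width followed by the four residual-block
    widths; "slim" defaults keep the parameter count in the tens of
    thousands.
    """

    input_shape: tuple[int, int, int, int] = (16, 16, 16, 8)  # x, y, z, lags
    channels: tuple[int, ...] = (8, 8, 16, 16, 32)
    dropout_rate: float = 0.2
    kernel_size: int = 3

    def __post_init__(self) -> None:
        if len(self.channels) != 5:
            raise ValueError("channels must list stem + 4 block widths")
        n_pools = len(self.channels) - 1
        for d in self.input_shape[:3]:
            if d % (2 ** n_pools) != 0 or d < 2 ** n_pools:
                raise ValueError(
                    f"spatial dim {d} cannot be halved {n_pools} times")


class ResidualBlock(Layer):
    """conv-BN-ReLU-conv-BN + shortcut, ReLU, then 2x2x2 max pooling."""

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.conv1 = Conv3d(in_channels, out_channels, rng=rng)
        self.bn1 = BatchNorm3d(out_channels)
        self.relu1 = ReLU()
        self.conv2 = Conv3d(out_channels, out_channels, rng=rng)
        self.bn2 = BatchNorm3d(out_channels)
        self.projection: Conv3d | None = None
        self.bn_proj: BatchNorm3d | None = None
        if in_channels != out_channels:
            self.projection = Conv3d(in_channels, out_channels,
                                     kernel_size=1, rng=rng)
            self.bn_proj = BatchNorm3d(out_channels)
        self.relu_out = ReLU()
        self.pool = MaxPool3d()

    def sublayers(self) -> list[Layer]:
        subs = [self.conv1, self.bn1, self.relu1, self.conv2, self.bn2]
        if self.projection is not None:
            subs += [self.projection, self.bn_proj]
        return subs + [self.relu_out, self.pool]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        main = self.bn1.forward(self.conv1.forward(x, training), training)
        main = self.relu1.forward(main, training)
        main = self.bn2.forward(self.conv2.forward(main, training), training)
        if self.projection is not None:
            short = self.bn_proj.forward(
                self.projection.forward(x, training), training)
        else:
            short = x
        self._main, self._short = main, short
        out = self.relu_out.forward(main + short, training)
        return self.pool.forward(out, training)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = self.relu_out.backward(self.pool.backward(grad))
        g_main = self.bn2.backward(grad)
        g_main = self.conv2.backward(g_main)
        g_main = self.relu1.backward(g_main)
        g_main = self.conv1.backward(self.bn1.backward(g_main))
        if self.projection is not None:
            g_short = self.projection.backward(self.bn_proj.backward(grad))
        else:
            g_short = grad
        return g_main + g_short


class ResNet3d:
    """The full classifier: epoch (x, y, z, lag) -> probability."""

    def __init__(self, spec: NetworkSpec,
                 rng_seed: int | np.random.Generator = 0) -> None:
        rng = np.random.default_rng(rng_seed)
        self.spec = spec
        lags = spec.input_shape[3]
        stem_c, *block_c = spec.channels
        self.stem = Conv3d(lags, stem_c, kernel_size=spec.kernel_size,
                           rng=rng)
        self.stem_bn = BatchNorm3d(stem_c)
        self.stem_relu = ReLU()
        self.blocks = []
        prev = stem_c
        for c in block_c:
            self.blocks.append(ResidualBlock(prev, c, rng))
            prev = c
        self.flatten = Flatten()
        self.dropout = Dropout(spec.dropout_rate, rng=rng)
        final_spatial = [d // 2 ** len(block_c) for d in spec.input_shape[:3]]
        n_features = prev * int(np.prod(final_spatial))
        self.head = Dense(n_features, 1, rng=rng)

    # -- plumbing -----------------------------------------------------
    def layers(self) -> list[Layer]:
        out = [self.stem, self.stem_bn, self.stem_relu]
        for b in self.blocks:
            out.extend(b.sublayers())
        return out + [self.flatten, self.dropout, self.head]

    def parameters(self):
        for layer in self.layers():
            for name, val in layer.params.items():
                yield layer, name, val

    def n_parameters(self) -> int:
        return sum(v.size for _, _, v in self.parameters())

    # -- forward/backward ---------------------------------------------
    @staticmethod
    def _to_batch(epochs: np.ndarray) -> np.ndarray:
        """(N, x, y, z, lag) or (x, y, z, lag) -> (N, lag, x, y, z)."""
        arr = np.asarray(epochs, dtype=float)
        if arr.ndim == 4:
            arr = arr[None]
        return arr.transpose(0, 4, 1, 2, 3)

    def logits(self, epochs: np.ndarray, training: bool = False) -> np.ndarray:
        x = self._to_batch(epochs)
        x = self.stem_relu.forward(
            self.stem_bn.forward(self.stem.forward(x, training), training),
            training)
        for block in self.blocks:
            x = block.forward(x, training)
        x = self.dropout.forward(self.flatten.forward(x, training), training)
        return self.head.forward(x, training)[:, 0]

    def predict_proba(self, epochs: np.ndarray) -> np.ndarray:
        """Inference-mode probabilities in [0, 1]; deterministic."""
        z = self.logits(epochs, training=False)
        return 1.0 / (1.0 + np.exp(-z))

    def backward(self, grad_logits: np.ndarray) -> np.ndarray:
        g = self.head.backward(grad_logits[:, None])
        g = self.flatten.backward(self.dropout.backward(g))
        for block in reversed(self.blocks):
            g = block.backward(g)
        g = self.stem.backward(
            self.stem_bn.backward(self.stem_relu.backward(g)))
        return g


def _state_arrays(net: ResNet3d) -> dict[str, np.ndarray]:
    state = {}
    for i, layer in enumerate(net.layers()):
        for name, val in layer.params.items():
            state[f"layer{i}.{name}"] = val
        if isinstance(layer, BatchNorm3d):
            state[f"layer{i}.running_mean"] = layer.running_mean
            state[f"layer{i}.running_var"] = layer.running_var
    return state


def save_network(net: ResNet3d, path) -> None:
    """Portable checkpoint: spec JSON + flat weight arrays (.npz)."""
    spec_json = json.dumps({
        "input_shape": list(net.spec.input_shape),
        "channels": list(net.spec.channels),
        "dropout_rate": net.spec.dropout_rate,
        "kernel_size": net.spec.kernel_size,
    })
    np.savez(path, __spec__=np.frombuffer(spec_json.encode(), dtype=np.uint8),
             **_state_arrays(net))


def load_network(path) -> ResNet3d:
    archive = np.load(path)
    spec_dict = json.loads(bytes(archive["__spec__"]).decode())
    spec = NetworkSpec(
        input_shape=tuple(spec_dict["input_shape"]),
        channels=tuple(spec_dict["channels"]),
        dropout_rate=spec_dict["dropout_rate"],
        kernel_size=spec_dict["kernel_size"])
    net = ResNet3d(spec)
    for i, layer in enumerate(net.layers()):
        for name in layer.params:
            layer.params[name][...] = archive[f"layer{i}.{name}"]
        if isinstance(layer, BatchNorm3d):
            layer.running_mean[...] = archive[f"layer{i}.running_mean"]
            layer.running_var[...] = archive[f"layer{i}.running_var"]
    return net
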