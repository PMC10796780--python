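"""Minimal 3D neural-network layers in numpy.

Tensors are laid out as (N, C, X, Y, Z).  Every layer implements
``forward(x, training)`` and ``backward(grad)``; parameters and their
gradients live in ``params`` / ``grads`` dicts so the optimizer can
update them generically.  Convolutions use an im2col formulation via
``sliding_window_view`` (stride 1, 'same' padding); the input gradient is
computed as a convolution with the spatially flipped, channel-transposed
kernel, which avoids an explicit col2im scatter.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Layer", "Conv3d", "BatchNorm3d", "ReLU", "MaxPool3d",
           "Flatten", "Dense", "Dropout", "glorot_uniform"]


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int,
                   fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _conv3d(x: np.ndarray, w: np.ndarray) -> np.ndarray:
    """'Same' 3D cross-correlation, stride 1.

    x: (N, Cin, X, Y, Z); w: (Cout, Cin, k, k, k) with odd k.
    """
    k = w.shape[2]
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k),
                                                   axis=(2, 3, 4))
    n, cin, X, Y, Z = x.shape
    col = win.transpose(0, 2, 3, 4, 1, 5, 6, 7).reshape(
        n * X * Y * Z, cin * k ** 3)
    out = col @ w.reshape(w.shape[0], -1).T
    return out.reshape(n, X, Y, Z, w.shape[0]).transpose(0, 4, 1, 2, 3), col


class Conv3d(Layer):
    """3D convolution, stride 1, odd kernel, 'same' zero padding."""

    def __init__(self, in_channels: int, out_channels: int,
                 kernel_size: int = 3,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd")
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * kernel_size ** 3
        fan_out = out_channels * kernel_size ** 3
        self.params["w"] = glorot_uniform(
            rng, (out_channels, in_channels) + (kernel_size,) * 3,
            fan_in, fan_out)
        self.params["b"] = np.zeros(out_channels)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x_shape = x.shape
        out, col = _conv3d(x, self.params["w"])
        self._col = col if training else None
        return out + self.params["b"][None, :, None, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        n, cout, X, Y, Z = grad.shape
        gmat = grad.transpose(0, 2, 3, 4, 1).reshape(-1, cout)
        self.grads["w"] = (gmat.T @ self._col).reshape(self.params["w"].shape)
        self.grads["b"] = gmat.sum(axis=0)
        # dL/dx = grad * flipped, channel-transposed kernel
        w_flip = self.params["w"][:, :, ::-1, ::-1, ::-1].transpose(
            1, 0, 2, 3, 4)
        dx, _ = _conv3d(grad, w_flip)
        return dx


class BatchNorm3d(Layer):
    """Per-channel batch normalization over (N, X, Y, Z)."""

    def __init__(self, channels: int, momentum: float = 0.9,
                 eps: float = 1e-5) -> None:
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.params["gamma"] = np.ones(channels)
        self.params["beta"] = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        axes = (0, 2, 3, 4)
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var)
        else:
            mean, var = self.running_mean, self.running_var
        shp = (1, -1, 1, 1, 1)
        self._xhat = (x - mean.reshape(shp)) / np.sqrt(
            var.reshape(shp) + self.eps)
        self._var = var
        return (self.params["gamma"].reshape(shp) * self._xhat
                + self.params["beta"].reshape(shp))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        axes = (0, 2, 3, 4)
        m = grad.shape[0] * grad.shape[2] * grad.shape[3] * grad.shape[4]
        shp = (1, -1, 1, 1, 1)
        self.grads["gamma"] = (grad * self._xhat).sum(axis=axes)
        self.grads["beta"] = grad.sum(axis=axes)
        g = grad * self.params["gamma"].reshape(shp)
        inv_sd = 1.0 / np.sqrt(self._var.reshape(shp) + self.eps)
        return inv_sd / m * (
            m * g - g.sum(axis=axes).reshape(shp)
            - self._xhat * (g * self._xhat).sum(axis=axes).reshape(shp))


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._mask


class MaxPool3d(Layer):
    """2x2x2 max pooling, stride 2; records winner positions for backward
    and for winner-take-all relevance routing."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        n, c, X, Y, Z = x.shape
        if X % 2 or Y % 2 or Z % 2:
            raise ValueError(f"spatial dims must be even to pool, got "
                             f"{(X, Y, Z)}")
        blocks = x.reshape(n, c, X // 2, 2, Y // 2, 2, Z // 2, 2)
        out = blocks.max(axis=(3, 5, 7))
        up = np.repeat(np.repeat(np.repeat(
            out, 2, axis=2), 2, axis=3), 2, axis=4)
        winners = (x == up)
        # break ties: keep only the first winner per 2x2x2 block
        wb = winners.reshape(n, c, X // 2, 2, Y // 2, 2, Z // 2, 2)
        flat = wb.transpose(0, 1, 2, 4, 6, 3, 5, 7).reshape(
            n, c, X // 2, Y // 2, Z // 2, 8)
        first = np.zeros_like(flat)
        np.put_along_axis(first, flat.argmax(axis=-1)[..., None], True,
                          axis=-1)
        self._winners = first.reshape(
            n, c, X // 2, Y // 2, Z // 2, 2, 2, 2).transpose(
            0, 1, 2, 5, 3, 6, 4, 7).reshape(x.shape)
        return out

    def backward(self, grad: np.ndarray) -> np.ndarray:
        up = np.repeat(np.repeat(np.repeat(
            grad, 2, axis=2), 2, axis=3), 2, axis=4)
        return up * self._winners

    def route(self, values: np.ndarray) -> np.ndarray:
        """Scatter pooled-grid values to the winning input positions."""
        return self.backward(values)


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.params["w"] = glorot_uniform(
            rng, (in_features, out_features), in_features, out_features)
        self.params["b"] = np.zeros(out_features)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.params["w"] + self.params["b"]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.grads["w"] = self._x.T @ grad
        self.grads["b"] = grad.sum(axis=0)
        return grad @ self.params["w"].T


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1 - self.rate)
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad if self._mask is None else grad * self._mask
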