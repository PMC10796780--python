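"""SGD-with-momentum training on binary cross-entropy.

The loss is computed on the logit (sigmoid folded into the loss for
numerical stability); its gradient with respect to the logit is simply
``sigmoid(z) - y``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import ResNet3d

__all__ = ["Hyperparams", "bce_with_logits", "sgd_momentum_step",
           "train_network", "TrainingDivergence"]


@dataclass(frozen=True)
class Hyperparams:
    dropout_rate: float = 0.2
    learning_rate: float = 0.02
    momentum: float = 0.9
    training_steps: int = 150
    batch_size: int = 8

    def __post_init__(self) -> None:
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must be in [0, 1)")
        for name in ("learning_rate", "momentum", "training_steps"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


class TrainingDivergence(RuntimeError):
    pass


def bce_with_logits(logits: np.ndarray, labels: np.ndarray):
    """Mean binary cross-entropy and its gradient w.r.t. the logits."""
    z = np.asarray(logits, float)
    y = np.asarray(labels, float)
    # log(1 + e^z) computed stably
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    p = 1.0 / (1.0 + np.exp(-z))
    return loss, (p - y) / len(y)


def sgd_momentum_step(net: ResNet3d, velocity: dict,
                      learning_rate: float, momentum: float) -> None:
    """v <- momentum * v - lr * g;  w <- w + v."""
    for layer, name, value in net.parameters():
        if name not in layer.grads:
            continue
        key = (id(layer), name)
        v = velocity.get(key, 0.0)
        v = momentum * v - learning_rate * layer.grads[name]
        velocity[key] = v
        value += v


def train_network(
    net: ResNet3d,
    inputs,
    labels: np.ndarray,
    hp: Hyperparams,
    rng_seed: int | np.random.Generator = 0,
    batch_fn=None,
    loss_callback=None,
) -> ResNet3d:
    """Train in place and return the network.

    `inputs` is either an array (N, x, y, z, lag) or, when training-time
    augmentation is wanted, `batch_fn(indices, rng)` supplies the
    (re-augmented) batch arrays for the sampled subject indices each step.
    Divergence (non-finite loss) raises :class:`TrainingDivergence` naming
    the offending hyperparameters.
    """
    labels = np.asarray(labels, float)
    if len(set(labels.tolist())) < 2:
        raise ValueError("training data must contain both classes")
    rng = np.random.default_rng(rng_seed)
    n = len(labels)
    velocity: dict = {}
    for step in range(hp.training_steps):
        idx = rng.choice(n, size=min(hp.batch_size, n), replace=False)
        if batch_fn is not None:
            batch = batch_fn(idx, rng)
        else:
            batch = np.asarray(inputs)[idx]
        logits = net.logits(batch, training=True)
        loss, dlogits = bce_with_logits(logits, labels[idx])
        if not np.isfinite(loss):
            raise TrainingDivergence(
                f"loss diverged at step {step} with learning_rate="
                f"{hp.learning_rate}, momentum={hp.momentum}")
        if loss_callback is not None:
            loss_callback(step, loss)
        net.backward(dlogits)
        sgd_momentum_step(net, velocity, hp.learning_rate, hp.momentum)
    return net
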