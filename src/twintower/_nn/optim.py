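"""SGD with momentum and Adam, with per-step multiplicative learning-rate decay.

The decay rate ``d`` shrinks the learning rate as ``lr <- lr * (1 - d)`` after
every optimizer step, so after t steps the rate is ``lr0 * (1 - d)**t``. With
the tiny decay values used here (2e-7) this is indistinguishable from constant
rate over short runs but matches the stated schedule exactly.

SGD follows the classic heavy-ball recursion
    v <- momentum * v + g
    w <- w - lr * v
so with momentum 0 it reduces to plain gradient descent.
"""

from __future__ import annotations

import numpy as np

from ..errors import ConfigError
from .layers import Param


class Optimizer:
    def __init__(self, params: list[Param], lr: float, decay: float, weight_decay: float = 0.0):
        if lr <= 0:
            raise ConfigError(f"learning rate must be positive, got {lr}")
        if not 0 <= decay < 1:
            raise ConfigError(f"decay must lie in [0, 1), got {decay}")
        if weight_decay < 0:
            raise ConfigError(f"weight decay must be non-negative, got {weight_decay}")
        self.params = params
        self.lr = float(lr)
        self.decay = float(decay)
        self.weight_decay = float(weight_decay)
        self.t = 0

    def _apply_weight_decay(self) -> None:
        if self.weight_decay:
            for p in self.params:
                p.grad += self.weight_decay * p.value

    def step(self) -> None:  # pragma: no cover
        raise NotImplementedError

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0


class SGD(Optimizer):
    def __init__(
        self,
        params: list[Param],
        lr: float,
        momentum: float = 0.9,
        decay: float = 0.0,
        weight_decay: float = 0.0,
    ):
        super().__init__(params, lr, decay, weight_decay)
        self.momentum = float(momentum)
        self._v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self._apply_weight_decay()
        for p, v in zip(self.params, self._v):
            v *= self.momentum
            v += p.grad
            p.value -= self.lr * v
        self.t += 1
        self.lr *= 1.0 - self.decay


class Adam(Optimizer):
    def __init__(
        self,
        params: list[Param],
        lr: float,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
        decay: float = 0.0,
        weight_decay: float = 0.0,
    ):
        super().__init__(params, lr, decay, weight_decay)
        self.beta1, self.beta2, self.eps = float(beta1), float(beta2), float(eps)
        self._m = [np.zeros_like(p.value) for p in params]
        self._v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self._apply_weight_decay()
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            m *= self.beta1
            m += (1.0 - self.beta1) * p.grad
            v *= self.beta2
            v += (1.0 - self.beta2) * p.grad**2
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
        self.lr *= 1.0 - self.decay


def make_optimizer(
    name: str,
    params: list[Param],
    lr: float,
    momentum: float = 0.9,
    decay: float = 0.0,
    weight_decay: float = 0.0,
) -> Optimizer:
    """Build an optimizer by name; ``momentum`` maps to Adam's beta1."""
    key = name.strip().lower()
    if key == "sgd":
        return SGD(params, lr=lr, momentum=momentum, decay=decay, weight_decay=weight_decay)
    if key == "adam":
        return Adam(params, lr=lr, beta1=momentum, decay=decay, weight_decay=weight_decay)
    raise ConfigError(f"unknown optimizer {name!r}; expected 'SGD' or 'Adam'")
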