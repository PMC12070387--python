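"""Layers with explicit forward/backward passes.

Convolutions use im2col with 'same' zero padding and stride 1; max pooling is
2x2/stride 2 with gradient routed to the first maximum (deterministic under
ties, which matter because binarized segmentation channels are piecewise
constant). Weight init is Glorot uniform from a caller-supplied Generator.
"""

from __future__ import annotations

import numpy as np

from ..errors import ShapeMismatchError


class Param:
    """A learnable array plus its gradient accumulator."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = Param(_glorot(rng, (n_in, n_out), n_in, n_out))
        self.b = Param(np.zeros(n_out))
        self._x: np.ndarray | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] != self.W.value.shape[0]:
            raise ShapeMismatchError(
                f"dense layer expects width {self.W.value.shape[0]}, got {x.shape[1]}"
            )
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(B, C, H, W) zero-padded 'same' -> (B, H*W, C*k*k) patch matrix."""
    p = k // 2
    b, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    windows = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    # windows: (B, C, H, W, k, k) -> (B, H, W, C, k, k) -> (B, H*W, C*k*k)
    return np.ascontiguousarray(windows.transpose(0, 2, 3, 1, 4, 5)).reshape(b, h * w, c * k * k)


class Conv2d(Layer):
    """Stride-1 'same' 2D convolution (cross-correlation, as is conventional)."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        fan_in = c_in * k * k
        fan_out = c_out * k * k
        self.W = Param(_glorot(rng, (c_out, c_in, k, k), fan_in, fan_out))
        self.b = Param(np.zeros(c_out))
        self.k = k
        self._cols: np.ndarray | None = None
        self._xshape: tuple[int, ...] | None = None

    def params(self) -> list[Param]:
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        if c != self.W.value.shape[1]:
            raise ShapeMismatchError(
                f"conv expects {self.W.value.shape[1]} input channels, got {c}"
            )
        self._xshape = x.shape
        cols = _im2col(x, self.k)
        self._cols = cols
        c_out = self.W.value.shape[0]
        out = cols @ self.W.value.reshape(c_out, -1).T + self.b.value
        return out.transpose(0, 2, 1).reshape(b, c_out, h, w)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        b, c_out, h, w = grad.shape
        g = grad.reshape(b, c_out, h * w).transpose(0, 2, 1)  # (B, HW, c_out)
        dW = np.einsum("bpo,bpi->oi", g, self._cols)
        self.W.grad += dW.reshape(self.W.value.shape)
        self.b.grad += g.sum(axis=(0, 1))
        # dx = 'same' correlation of grad with channel-swapped, spatially flipped W
        W_flip = self.W.value[:, :, ::-1, ::-1].transpose(1, 0, 2, 3)  # (c_in, c_out, k, k)
        cols_g = _im2col(grad, self.k)
        c_in = W_flip.shape[0]
        dx = cols_g @ W_flip.reshape(c_in, -1).T
        return dx.transpose(0, 2, 1).reshape(self._xshape)


class MaxPool2d(Layer):
    """2x2 max pooling, stride 2; odd trailing rows/cols are cropped."""

    def __init__(self):
        self._mask: np.ndarray | None = None
        self._inshape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, c, h, w = x.shape
        self._inshape = x.shape
        h2, w2 = h // 2, w // 2
        xc = x[:, :, : h2 * 2, : w2 * 2]
        patches = xc.reshape(b, c, h2, 2, w2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h2, w2, 4)
        idx = patches.argmax(axis=-1)
        self._mask = np.eye(4, dtype=np.float64)[idx]  # one-hot of first maximum
        return np.take_along_axis(patches, idx[..., None], axis=-1)[..., 0]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        b, c, h, w = self._inshape
        h2, w2 = h // 2, w // 2
        g = self._mask * grad[..., None]  # (b, c, h2, w2, 4)
        g = g.reshape(b, c, h2, w2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h2 * 2, w2 * 2)
        out = np.zeros(self._inshape)
        out[:, :, : h2 * 2, : w2 * 2] = g
        return out


class ReLU(Layer):
    def __init__(self):
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, 0.0)


class Flatten(Layer):
    def __init__(self):
        self._shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def param_values(self) -> list[np.ndarray]:
        return [p.value for p in self.params()]
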