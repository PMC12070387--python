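"""The low-complexity CNN image encoder.

Three convolutional blocks (conv -> 2x2 max pool -> ReLU) followed by a
flatten and two dense layers of 32 and 16 nodes produce a 16-dimensional
image-feature vector per sample. A detachable single-sigmoid head on top of
the 16 features serves stage-1 training and the image-only ablation model;
at fusion time only the 16 features are consumed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import _nn
from .cohort_io import SliceStack
from .errors import ConfigError, ShapeMismatchError

__all__ = [
    "ImageTowerConfig",
    "ImageTowerState",
    "init_image_tower",
    "encode_image",
    "image_classify",
    "save_image_tower",
    "load_image_tower",
]


@dataclass(frozen=True)
class ImageTowerConfig:
    input_channels: int = 5
    input_size: int = 240
    conv_filters: tuple[int, int, int] = (8, 16, 32)
    kernel_size: int = 3
    pool_size: int = 2
    dense_nodes: tuple[int, int] = (32, 16)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.conv_filters) != 3:
            raise ConfigError(f"exactly 3 conv blocks required, got {len(self.conv_filters)}")
        if self.dense_nodes[-1] != 16:
            raise ConfigError("final dense width must be 16 (the image-feature dimension)")
        if min(self.conv_filters) <= 0 or self.input_size <= 0 or self.input_channels <= 0:
            raise ConfigError("all dimensions must be positive")
        if self.pool_size != 2:
            raise ConfigError("only 2x2 pooling is supported")

    @property
    def flat_dim(self) -> int:
        side = self.input_size
        for _ in self.conv_filters:
            side //= 2
        if side < 1:
            raise ConfigError(f"input size {self.input_size} too small for 3 pooling stages")
        return side * side * self.conv_filters[-1]


class ImageTowerState:
    """Trunk + classification head with a freeze flag.

    When ``frozen`` is true the trainer never hands the trunk's parameters to
    an optimizer, so an entire training epoch leaves them bitwise unchanged.
    """

    def __init__(self, config: ImageTowerConfig):
        self.config = config
        self.frozen = False
        self.history: dict[str, list[float]] = {}
        rng = np.random.default_rng(config.seed)
        blocks: list[_nn.layers.Layer] = []
        c_in = config.input_channels
        for c_out in config.conv_filters:
            blocks += [_nn.Conv2d(c_in, c_out, config.kernel_size, rng), _nn.MaxPool2d(), _nn.ReLU()]
            c_in = c_out
        blocks.append(_nn.Flatten())
        blocks += [_nn.Dense(config.flat_dim, config.dense_nodes[0], rng), _nn.ReLU()]
        blocks.append(_nn.Dense(config.dense_nodes[0], config.dense_nodes[1], rng))
        self.trunk = _nn.Sequential(blocks)
        self.head = _nn.Sequential([_nn.Dense(config.dense_nodes[1], 1, rng)])

    # -- parameter access -------------------------------------------------
    def parameters(self) -> list[_nn.Param]:
        return self.trunk.params() + self.head.params()

    def trainable_parameters(self) -> list[_nn.Param]:
        return [] if self.frozen else self.parameters()

    def param_checksum(self) -> float:
        return float(sum(np.abs(p.value).sum() for p in self.parameters()))


def init_image_tower(config: ImageTowerConfig) -> ImageTowerState:
    """Deterministically initialize a tower from ``config.seed``; unfrozen."""
    return ImageTowerState(config)


def _as_batch(state: ImageTowerState, batch) -> np.ndarray:
    if isinstance(batch, np.ndarray):
        x = batch
    else:
        x = np.stack([s.pixels if isinstance(s, SliceStack) else np.asarray(s) for s in batch])
    if x.ndim == 3:
        x = x[None]
    cfg = state.config
    if x.shape[1:] != (cfg.input_channels, cfg.input_size, cfg.input_size):
        raise ShapeMismatchError(
            f"expected (*, {cfg.input_channels}, {cfg.input_size}, {cfg.input_size}), got {x.shape}"
        )
    return x.astype(np.float64)


def encode_image(state: ImageTowerState, batch) -> np.ndarray:
    """Forward pass to the 16-dimensional feature layer; (n_samples, 16)."""
    return state.trunk.forward(_as_batch(state, batch))


def image_classify(state: ImageTowerState, batch) -> np.ndarray:
    """Per-sample probability of a positive therapy response, in (0, 1)."""
    return _nn.sigmoid(state.head.forward(encode_image(state, batch)).ravel())


# ---------------------------------------------------------------------------
# checkpointing


def save_image_tower(state: ImageTowerState, path: str | Path) -> None:
    arrays = {f"p{i}": p.value for i, p in enumerate(state.parameters())}
    np.savez(
        path,
        __config__=json.dumps(asdict(state.config)),
        __frozen__=np.array(state.frozen),
        **arrays,
    )


def load_image_tower(path: str | Path) -> ImageTowerState:
    with np.load(path, allow_pickle=False) as data:
        raw = json.loads(str(data["__config__"]))
        raw["conv_filters"] = tuple(raw["conv_filters"])
        raw["dense_nodes"] = tuple(raw["dense_nodes"])
        state = ImageTowerState(ImageTowerConfig(**raw))
        state.frozen = bool(data["__frozen__"])
        for i, p in enumerate(state.parameters()):
            p.value[...] = data[f"p{i}"]
    return state
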