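"""Autoencoder gene-expression encoder.

The encoder compresses a gene-expression vector through dense layers of 64
and 32 nodes; the 32-node bottleneck activation is the gene feature vector
handed to the fusion head. The decoder mirrors the encoder (32 -> 64 ->
input) with a linear output layer, trained under mean squared error. A
classifier head (64 -> 16 -> sigmoid) attaches to the bottleneck after AE
training and serves the gene-only ablation model.

Raw RNA-seq magnitudes span orders of magnitude, which makes MSE training
degenerate, so vectors pass through log(1+x) and a per-gene standardization
fitted on training data before entering the network. The fitted
preprocessing travels with the tower state so downstream consumers see a
consistent feature space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import _nn
from .errors import ConfigError, ShapeMismatchError

__all__ = [
    "GeneTowerConfig",
    "GenePreprocessor",
    "GeneTowerState",
    "init_gene_tower",
    "reconstruct",
    "encode_gene",
    "gene_classify",
    "save_gene_tower",
    "load_gene_tower",
]


@dataclass(frozen=True)
class GeneTowerConfig:
    input_dim: int = 19196
    encoder_nodes: tuple[int, int] = (64, 32)
    decoder_nodes: tuple[int, int] = (32, 64)
    classifier_nodes: tuple[int, int] = (64, 16)
    seed: int = 0
    strict_bottleneck: bool = True

    def __post_init__(self) -> None:
        if self.input_dim < 1:
            raise ConfigError(f"input_dim must be >= 1, got {self.input_dim}")
        if self.decoder_nodes != tuple(reversed(self.encoder_nodes)):
            raise ConfigError("decoder must mirror the encoder")
        if self.strict_bottleneck and self.encoder_nodes[-1] != 32:
            raise ConfigError("bottleneck width must be 32 (set strict_bottleneck=False to override)")

    @property
    def bottleneck(self) -> int:
        return self.encoder_nodes[-1]


@dataclass
class GenePreprocessor:
    """log(1+x) then per-gene standardization with training-set statistics."""

    log1p: bool = True
    mean: np.ndarray | None = None
    std: np.ndarray | None = None

    def fit(self, raw: np.ndarray) -> "GenePreprocessor":
        x = np.log1p(raw) if self.log1p else np.asarray(raw, dtype=np.float64)
        self.mean = x.mean(axis=0)
        self.std = np.maximum(x.std(axis=0), 1e-8)
        return self

    def transform(self, raw: np.ndarray) -> np.ndarray:
        x = np.log1p(raw) if self.log1p else np.asarray(raw, dtype=np.float64)
        if self.mean is None:
            return x
        return (x - self.mean) / self.std


class GeneTowerState:
    def __init__(self, config: GeneTowerConfig):
        self.config = config
        self.frozen = False
        self.history: dict[str, list[float]] = {}
        self.preproc = GenePreprocessor()
        rng = np.random.default_rng(config.seed)
        n_in = config.input_dim
        enc: list[_nn.layers.Layer] = []
        prev = n_in
        for width in config.encoder_nodes:
            enc += [_nn.Dense(prev, width, rng), _nn.ReLU()]
            prev = width
        self.encoder = _nn.Sequential(enc)
        dec: list[_nn.layers.Layer] = []
        for width in config.encoder_nodes[:-1][::-1]:
            dec += [_nn.Dense(prev, width, rng), _nn.ReLU()]
            prev = width
        dec.append(_nn.Dense(prev, n_in, rng))  # linear reconstruction output
        self.decoder = _nn.Sequential(dec)
        clf: list[_nn.layers.Layer] = []
        prev = config.bottleneck
        for width in config.classifier_nodes:
            clf += [_nn.Dense(prev, width, rng), _nn.ReLU()]
            prev = width
        clf.append(_nn.Dense(prev, 1, rng))
        self.classifier = _nn.Sequential(clf)

    def parameters(self) -> list[_nn.Param]:
        return self.encoder.params() + self.decoder.params() + self.classifier.params()

    def encoder_parameters(self) -> list[_nn.Param]:
        return self.encoder.params()

    def trainable_parameters(self) -> list[_nn.Param]:
        return [] if self.frozen else self.parameters()

    def param_checksum(self) -> float:
        return float(sum(np.abs(p.value).sum() for p in self.parameters()))


def init_gene_tower(config: GeneTowerConfig) -> GeneTowerState:
    """Deterministically initialize from ``config.seed``; unfrozen."""
    return GeneTowerState(config)


def _as_batch(state: GeneTowerState, batch: np.ndarray, preprocessed: bool) -> np.ndarray:
    x = np.asarray(batch, dtype=np.float64)
    if x.ndim == 1:
        x = x[None]
    if x.shape[1] != state.config.input_dim:
        raise ShapeMismatchError(
            f"expected gene vectors of length {state.config.input_dim}, got {x.shape[1]}"
        )
    return x if preprocessed else state.preproc.transform(x)


def reconstruct(
    state: GeneTowerState, batch: np.ndarray, preprocessed: bool = False
) -> tuple[np.ndarray, float]:
    """Autoencoder round trip; returns (reconstructions, mean squared error).

    The MSE is taken in the preprocessed space the AE is trained in.
    """
    x = _as_batch(state, batch, preprocessed)
    recon = state.decoder.forward(state.encoder.forward(x))
    return recon, float(np.mean((x - recon) ** 2))


def encode_gene(state: GeneTowerState, batch: np.ndarray, preprocessed: bool = False) -> np.ndarray:
    """Bottleneck activations, shape (n_samples, 32)."""
    return state.encoder.forward(_as_batch(state, batch, preprocessed))


def gene_classify(state: GeneTowerState, batch: np.ndarray, preprocessed: bool = False) -> np.ndarray:
    """Per-sample probability of a positive response from the bottleneck head."""
    logits = state.classifier.forward(encode_gene(state, batch, preprocessed))
    return _nn.sigmoid(logits.ravel())


# ---------------------------------------------------------------------------
# checkpointing


def save_gene_tower(state: GeneTowerState, path: str | Path) -> None:
    arrays = {f"p{i}": p.value for i, p in enumerate(state.parameters())}
    extras = {}
    if state.preproc.mean is not None:
        extras["__pre_mean__"] = state.preproc.mean
        extras["__pre_std__"] = state.preproc.std
    np.savez(
        path,
        __config__=json.dumps(asdict(state.config)),
        __frozen__=np.array(state.frozen),
        __log1p__=np.array(state.preproc.log1p),
        **extras,
        **arrays,
    )


def load_gene_tower(path: str | Path) -> GeneTowerState:
    with np.load(path, allow_pickle=False) as data:
        raw = json.loads(str(data["__config__"]))
        for key in ("encoder_nodes", "decoder_nodes", "classifier_nodes"):
            raw[key] = tuple(raw[key])
        state = GeneTowerState(GeneTowerConfig(**raw))
        state.frozen = bool(data["__frozen__"])
        state.preproc.log1p = bool(data["__log1p__"])
        if "__pre_mean__" in data:
            state.preproc.mean = data["__pre_mean__"]
            state.preproc.std = data["__pre_std__"]
        for i, p in enumerate(state.parameters()):
            p.value[...] = data[f"p{i}"]
    return state
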