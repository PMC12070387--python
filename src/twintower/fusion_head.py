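"""Feature scaling, modality fusion and the final classifier.

Image (16-dim) and gene (32-dim) encoder features are scaled separately to
zero mean / unit variance with statistics fitted on the multimodal training
set, then fused either by concatenation (default, 48-dim) or by a small
mixture of experts. The classification head is an MLP with dense layers of
64, 128 and 16 nodes followed by a single sigmoid output.

The mixture-of-experts variant runs ``n_experts`` copies of that head and
combines their sigmoid outputs with weights from a softmax gating network
over the 48-dim scaled concatenation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import _nn
from .errors import ConfigError, ScalerError, ShapeMismatchError

__all__ = [
    "FeatureScaler",
    "FusionConfig",
    "FusionHeadState",
    "fit_scaler",
    "fuse_features",
    "classify_fused",
    "moe_gate_weights",
    "predict_labels",
    "save_fusion_head",
    "load_fusion_head",
]

IMAGE_DIM = 16
GENE_DIM = 32
FUSED_DIM = IMAGE_DIM + GENE_DIM


@dataclass
class FeatureScaler:
    """Per-dimension affine standardization (Gaussian normalization)."""

    mean: np.ndarray
    std: np.ndarray

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=np.float64) - self.mean) / self.std

    def inverse(self, z: np.ndarray) -> np.ndarray:
        return np.asarray(z, dtype=np.float64) * self.std + self.mean


def fit_scaler(features: np.ndarray, eps: float = 1e-8) -> FeatureScaler:
    """Fit per-column sample mean and standard deviation (ddof=1).

    Standard deviations are floored at ``eps`` so constant columns map to 0
    instead of dividing by zero.
    """
    x = np.asarray(features, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ScalerError(f"scaler needs a 2D matrix with >= 2 rows, got shape {x.shape}")
    return FeatureScaler(mean=x.mean(axis=0), std=np.maximum(x.std(axis=0, ddof=1), eps))


@dataclass(frozen=True)
class FusionConfig:
    mode: str = "concat"  # or "moe"
    head_nodes: tuple[int, int, int] = (64, 128, 16)
    n_experts: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("concat", "moe"):
            raise ConfigError(f"fusion mode must be 'concat' or 'moe', got {self.mode!r}")
        if self.mode == "moe" and self.n_experts < 1:
            raise ConfigError("n_experts must be >= 1")


def _build_head(rng: np.random.Generator, nodes: tuple[int, ...]) -> _nn.Sequential:
    layers: list[_nn.layers.Layer] = []
    prev = FUSED_DIM
    for width in nodes:
        layers += [_nn.Dense(prev, width, rng), _nn.ReLU()]
        prev = width
    layers.append(_nn.Dense(prev, 1, rng))
    return _nn.Sequential(layers)


class FusionHeadState:
    def __init__(self, config: FusionConfig):
        self.config = config
        self.image_scaler: FeatureScaler | None = None
        self.gene_scaler: FeatureScaler | None = None
        self.history: dict[str, list[float]] = {}
        rng = np.random.default_rng(config.seed)
        if config.mode == "concat":
            self.experts = [_build_head(rng, config.head_nodes)]
            self.gate: _nn.Sequential | None = None
        else:
            self.experts = [_build_head(rng, config.head_nodes) for _ in range(config.n_experts)]
            self.gate = _nn.Sequential([_nn.Dense(FUSED_DIM, config.n_experts, rng)])

    @property
    def fitted(self) -> bool:
        return self.image_scaler is not None and self.gene_scaler is not None

    def fit_scalers(self, image_features: np.ndarray, gene_features: np.ndarray, eps: float = 1e-8) -> None:
        self.image_scaler = fit_scaler(image_features, eps)
        self.gene_scaler = fit_scaler(gene_features, eps)

    def parameters(self) -> list[_nn.Param]:
        params = [p for e in self.experts for p in e.params()]
        if self.gate is not None:
            params += self.gate.params()
        return params

    def param_checksum(self) -> float:
        return float(sum(np.abs(p.value).sum() for p in self.parameters()))


def init_fusion_head(config: FusionConfig) -> FusionHeadState:
    return FusionHeadState(config)


def fuse_features(
    image_f: np.ndarray, gene_f: np.ndarray, state: FusionHeadState
) -> np.ndarray:
    """Scale each modality and concatenate, image features first (width 48)."""
    if not state.fitted:
        raise ScalerError("scalers must be fitted before fusing features")
    img = np.atleast_2d(np.asarray(image_f, dtype=np.float64))
    gen = np.atleast_2d(np.asarray(gene_f, dtype=np.float64))
    if img.shape[1] != IMAGE_DIM or gen.shape[1] != GENE_DIM:
        raise ShapeMismatchError(
            f"expected image {IMAGE_DIM} and gene {GENE_DIM} widths, got {img.shape[1]} and {gen.shape[1]}"
        )
    if img.shape[0] != gen.shape[0]:
        raise ShapeMismatchError("image and gene batches differ in length")
    return np.concatenate(
        [state.image_scaler.transform(img), state.gene_scaler.transform(gen)], axis=1
    )


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def moe_gate_weights(state: FusionHeadState, fused: np.ndarray) -> np.ndarray:
    """Softmax gate weights over experts; rows are non-negative and sum to 1."""
    if state.gate is None:
        raise ConfigError("gate weights only exist in moe mode")
    return _softmax(state.gate.forward(np.atleast_2d(fused)))


def classify_fused(state: FusionHeadState, fused: np.ndarray) -> np.ndarray:
    """Per-sample probability from the fused 48-dim representation."""
    x = np.atleast_2d(np.asarray(fused, dtype=np.float64))
    if x.shape[1] != FUSED_DIM:
        raise ShapeMismatchError(f"fused width must be {FUSED_DIM}, got {x.shape[1]}")
    if state.config.mode == "concat":
        return _nn.sigmoid(state.experts[0].forward(x).ravel())
    probs = np.stack([_nn.sigmoid(e.forward(x).ravel()) for e in state.experts], axis=1)
    weights = moe_gate_weights(state, x)
    return (weights * probs).sum(axis=1)


def predict_labels(probabilities: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Hard 0/1 labels; positive iff probability >= threshold."""
    return (np.asarray(probabilities, dtype=np.float64) >= threshold).astype(int)


# ---------------------------------------------------------------------------
# checkpointing


def save_fusion_head(state: FusionHeadState, path: str | Path) -> None:
    if not state.fitted:
        raise ScalerError("refusing to checkpoint an unfitted fusion head")
    arrays = {f"p{i}": p.value for i, p in enumerate(state.parameters())}
    np.savez(
        path,
        __config__=json.dumps(asdict(state.config)),
        __img_mean__=state.image_scaler.mean,
        __img_std__=state.image_scaler.std,
        __gen_mean__=state.gene_scaler.mean,
        __gen_std__=state.gene_scaler.std,
        **arrays,
    )


def load_fusion_head(path: str | Path) -> FusionHeadState:
    with np.load(path, allow_pickle=False) as data:
        raw = json.loads(str(data["__config__"]))
        raw["head_nodes"] = tuple(raw["head_nodes"])
        state = FusionHeadState(FusionConfig(**raw))
        state.image_scaler = FeatureScaler(mean=data["__img_mean__"], std=data["__img_std__"])
        state.gene_scaler = FeatureScaler(mean=data["__gen_mean__"], std=data["__gen_std__"])
        for i, p in enumerate(state.parameters()):
            p.value[...] = data[f"p{i}"]
    return state
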