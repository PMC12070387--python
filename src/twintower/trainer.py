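"""Two-stage training: unimodal towers first, then frozen-encoder transfer.

Stage 1 trains the image tower (SGD with momentum, binary cross-entropy) on
image-only samples and the gene autoencoder (Adam, MSE) followed by its
bottleneck classifier on gene-only samples. Stage 2 freezes both towers,
fits the per-modality feature scalers on the multimodal training subset,
and trains only the fusion head (SGD, binary cross-entropy).

"Cross entropy" with a single sigmoid output is realized as binary
cross-entropy throughout. The decay rate is a per-step multiplicative
learning-rate decay. Mini-batch order is reshuffled every epoch from the
master seed, so an entire run is a pure function of (seed, cohort, configs).
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from . import _nn
from .cohort_io import Cohort, CohortSample
from .errors import (
    EmptyTrainingSetError,
    FoldError,
    ModalityError,
)
from .fusion_head import (
    FusionConfig,
    FusionHeadState,
    classify_fused,
    fuse_features,
    moe_gate_weights,
    save_fusion_head,
    load_fusion_head,
)
from .gene_tower import (
    GeneTowerConfig,
    GeneTowerState,
    encode_gene,
    gene_classify,
    init_gene_tower,
    save_gene_tower,
    load_gene_tower,
)
from .image_tower import (
    ImageTowerConfig,
    ImageTowerState,
    encode_image,
    image_classify,
    init_image_tower,
    save_image_tower,
    load_image_tower,
)
from .metrics import MetricReport, evaluate_predictions, mean_report

__all__ = [
    "PhaseConfig",
    "TrainConfig",
    "TrainedModel",
    "desk_scale_config",
    "train_stage1_image",
    "train_stage1_gene",
    "train_stage2_transfer",
    "run_two_stage",
    "cross_validate",
    "predict_fused",
    "evaluate_fused",
    "evaluate_image_only",
    "evaluate_gene_only",
    "save_trained_model",
    "load_trained_model",
]


@dataclass(frozen=True)
class PhaseConfig:
    optimizer: str
    momentum: float
    learning_rate: float
    decay: float
    loss: str
    epochs: int
    batch_size: int
    weight_decay: float = 0.0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("learning rate, epochs and batch size must be positive")


@dataclass(frozen=True)
class TrainConfig:
    """Per-phase hyperparameters. Defaults follow the reference setup:

    ============== ========= ========= =========
    phase           image     gene AE   transfer
    ============== ========= ========= =========
    optimizer       SGD       Adam      SGD
    momentum/beta1  0.9       0.9       0.9
    loss            BCE       MSE       BCE
    learning rate   2e-5      1e-4      1e-4
    decay           2e-7      2e-7      2e-7
    epochs          20        20        10
    batch size      16        16        16
    ============== ========= ========= =========

    The gene classifier phase (bottleneck head) reuses the gene-encoder
    optimizer settings with a BCE loss.
    """

    image: PhaseConfig = PhaseConfig("SGD", 0.9, 2e-5, 2e-7, "cross_entropy", 20, 16)
    gene_ae: PhaseConfig = PhaseConfig("Adam", 0.9, 1e-4, 2e-7, "mse", 20, 16)
    gene_classifier: PhaseConfig = PhaseConfig("Adam", 0.9, 1e-4, 2e-7, "cross_entropy", 20, 16)
    transfer: PhaseConfig = PhaseConfig("SGD", 0.9, 1e-4, 2e-7, "cross_entropy", 10, 16)
    seed: int = 0
    k_folds: int = 3
    freeze_encoder_for_classifier: bool = True


def desk_scale_config(seed: int = 0) -> TrainConfig:
    """Hyperparameters suited to the small synthetic regime (64x64, 500 genes).

    The reference learning rates target full-resolution MRI and ~19k genes;
    at desk scale they are too small to move the loss within the fixed epoch
    budgets, so the synthetic experiments raise them and add mild L2 weight
    decay against small-sample overfitting, while keeping every other
    setting (optimizers, losses, epochs, batch size) unchanged.
    """
    return TrainConfig(
        image=PhaseConfig("SGD", 0.9, 1e-2, 2e-7, "cross_entropy", 20, 16, 1e-3),
        gene_ae=PhaseConfig("Adam", 0.9, 1e-3, 2e-7, "mse", 20, 16),
        gene_classifier=PhaseConfig("Adam", 0.9, 1e-3, 2e-7, "cross_entropy", 20, 16, 1e-3),
        transfer=PhaseConfig("SGD", 0.9, 5e-2, 2e-7, "cross_entropy", 10, 16, 3e-2),
        seed=seed,
    )


@dataclass
class TrainedModel:
    image_tower: ImageTowerState
    gene_tower: GeneTowerState
    fusion: FusionHeadState
    history: dict[str, list[float]]
    config: TrainConfig


# ---------------------------------------------------------------------------
# internals


def _epoch_rng(seed: int, phase: str, epoch: int) -> np.random.Generator:
    tag = zlib.crc32(phase.encode()) & 0x7FFFFFFF
    return np.random.default_rng([seed & 0x7FFFFFFF, tag, epoch])


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start : start + batch_size]


def _make_optimizer(phase: PhaseConfig, params: list[_nn.Param]):
    return _nn.make_optimizer(
        phase.optimizer,
        params,
        lr=phase.learning_rate,
        momentum=phase.momentum,
        decay=phase.decay,
        weight_decay=phase.weight_decay,
    )


# ---------------------------------------------------------------------------
# stage 1


def train_stage1_image(
    cohort: Cohort, cfg: TrainConfig, tower_config: ImageTowerConfig | None = None
) -> ImageTowerState:
    """Train the image tower's classifier on image-only training samples."""
    samples = cohort.subset("stage1_image_train")
    if not samples:
        raise EmptyTrainingSetError("cohort has no stage1_image_train samples")
    X = Cohort.stack_images(samples)
    y = Cohort.labels(samples)
    if tower_config is None:
        tower_config = ImageTowerConfig(
            input_channels=X.shape[1], input_size=X.shape[2], seed=cfg.seed
        )
    state = init_image_tower(tower_config)
    opt = _make_optimizer(cfg.image, state.trainable_parameters())
    losses = []
    for epoch in range(cfg.image.epochs):
        rng = _epoch_rng(cfg.seed, "stage1_image", epoch)
        epoch_loss = 0.0
        for idx in _batches(len(y), cfg.image.batch_size, rng):
            opt.zero_grad()
            feats = state.trunk.forward(X[idx])
            logits = state.head.forward(feats)
            loss, grad = _nn.bce_with_logits(logits, y[idx])
            state.trunk.backward(state.head.backward(grad.reshape(logits.shape)))
            opt.step()
            epoch_loss += loss * len(idx)
        losses.append(epoch_loss / len(y))
    state.history["loss"] = losses
    return state


def train_stage1_gene(
    cohort: Cohort, cfg: TrainConfig, tower_config: GeneTowerConfig | None = None
) -> GeneTowerState:
    """Train the gene autoencoder, then its bottleneck classifier.

    The preprocessing (log1p + per-gene standardization) is fitted on the
    gene-only training samples. During the classifier phase the encoder is
    frozen by default so the bottleneck feature space learned by the AE is
    preserved.
    """
    samples = cohort.subset("stage1_gene_train")
    if not samples:
        raise EmptyTrainingSetError("cohort has no stage1_gene_train samples")
    raw = Cohort.stack_genes(samples)
    y = Cohort.labels(samples)
    if tower_config is None:
        tower_config = GeneTowerConfig(input_dim=raw.shape[1], seed=cfg.seed)
    state = init_gene_tower(tower_config)
    state.preproc.fit(raw)
    X = state.preproc.transform(raw)

    # --- autoencoder phase
    recon0 = state.decoder.forward(state.encoder.forward(X))
    state.history["ae_initial_mse"] = [float(np.mean((X - recon0) ** 2))]
    opt = _make_optimizer(cfg.gene_ae, state.encoder.params() + state.decoder.params())
    ae_losses = []
    for epoch in range(cfg.gene_ae.epochs):
        rng = _epoch_rng(cfg.seed, "stage1_gene_ae", epoch)
        epoch_loss = 0.0
        for idx in _batches(len(y), cfg.gene_ae.batch_size, rng):
            opt.zero_grad()
            xb = X[idx]
            recon = state.decoder.forward(state.encoder.forward(xb))
            loss, grad = _nn.mse_loss(recon, xb)
            state.encoder.backward(state.decoder.backward(grad))
            opt.step()
            epoch_loss += loss * len(idx)
        ae_losses.append(epoch_loss / len(y))
    state.history["ae_loss"] = ae_losses

    # --- classifier phase
    params = list(state.classifier.params())
    if not cfg.freeze_encoder_for_classifier:
        params += state.encoder.params()
    opt = _make_optimizer(cfg.gene_classifier, params)
    clf_losses = []
    for epoch in range(cfg.gene_classifier.epochs):
        rng = _epoch_rng(cfg.seed, "stage1_gene_clf", epoch)
        epoch_loss = 0.0
        for idx in _batches(len(y), cfg.gene_classifier.batch_size, rng):
            opt.zero_grad()
            bottleneck = state.encoder.forward(X[idx])
            logits = state.classifier.forward(bottleneck)
            loss, grad = _nn.bce_with_logits(logits, y[idx])
            grad_bottleneck = state.classifier.backward(grad.reshape(logits.shape))
            if not cfg.freeze_encoder_for_classifier:
                state.encoder.backward(grad_bottleneck)
            opt.step()
            epoch_loss += loss * len(idx)
        clf_losses.append(epoch_loss / len(y))
    state.history["clf_loss"] = clf_losses
    return state


# ---------------------------------------------------------------------------
# stage 2


def _check_dual(samples: list[CohortSample], context: str) -> None:
    for s in samples:
        if not (s.has_image and s.has_gene):
            raise ModalityError(f"{context}: sample {s.sample_id} is missing a modality")


def train_stage2_transfer(
    cohort: Cohort,
    image: ImageTowerState,
    gene: GeneTowerState,
    cfg: TrainConfig,
    fusion_cfg: FusionConfig,
) -> TrainedModel:
    """Freeze both towers and train the fusion head on multimodal samples.

    Scalers are fitted on the stage-2 *training* features only; tower
    parameters are bitwise untouched by construction (they are never handed
    to the optimizer).
    """
    samples = cohort.subset("stage2_train")
    if not samples:
        raise EmptyTrainingSetError("cohort has no stage2_train samples")
    _check_dual(samples, "stage2_train")
    image.frozen = True
    gene.frozen = True

    img_feats = encode_image(image, Cohort.stack_images(samples))
    gen_feats = encode_gene(gene, Cohort.stack_genes(samples))
    y = Cohort.labels(samples)

    fusion = FusionHeadState(fusion_cfg)
    fusion.fit_scalers(img_feats, gen_feats)
    fused = fuse_features(img_feats, gen_feats, fusion)

    opt = _make_optimizer(cfg.transfer, fusion.parameters())
    losses = []
    for epoch in range(cfg.transfer.epochs):
        rng = _epoch_rng(cfg.seed, "stage2_transfer", epoch)
        epoch_loss = 0.0
        for idx in _batches(len(y), cfg.transfer.batch_size, rng):
            opt.zero_grad()
            xb, yb = fused[idx], y[idx]
            if fusion_cfg.mode == "concat":
                logits = fusion.experts[0].forward(xb)
                loss, grad = _nn.bce_with_logits(logits, yb)
                fusion.experts[0].backward(grad.reshape(logits.shape))
            else:
                loss = _moe_backward(fusion, xb, yb)
            opt.step()
            epoch_loss += loss * len(idx)
        losses.append(epoch_loss / len(y))
    fusion.history["loss"] = losses

    history = {
        "image_loss": image.history.get("loss", []),
        "gene_ae_loss": gene.history.get("ae_loss", []),
        "gene_clf_loss": gene.history.get("clf_loss", []),
        "transfer_loss": losses,
    }
    return TrainedModel(image_tower=image, gene_tower=gene, fusion=fusion, history=history, config=cfg)


def _moe_backward(fusion: FusionHeadState, xb: np.ndarray, yb: np.ndarray) -> float:
    """BCE loss and backward pass through the gated mixture of experts."""
    n = len(yb)
    z = np.stack([e.forward(xb).ravel() for e in fusion.experts], axis=1)  # (n, E)
    p_e = _nn.sigmoid(z)
    g = moe_gate_weights(fusion, xb)  # (n, E)
    p = np.clip((g * p_e).sum(axis=1), 1e-12, 1 - 1e-12)
    yf = yb.astype(np.float64)
    loss = float(np.mean(-(yf * np.log(p) + (1 - yf) * np.log(1 - p))))
    dp = (p - yf) / (p * (1 - p)) / n
    # experts: dL/dz_e = dp * g_e * sigmoid'(z_e)
    dz = dp[:, None] * g * p_e * (1 - p_e)
    for e_idx, expert in enumerate(fusion.experts):
        expert.backward(dz[:, e_idx][:, None])
    # gate: softmax jacobian
    dg = dp[:, None] * p_e
    dh = g * (dg - (g * dg).sum(axis=1, keepdims=True))
    fusion.gate.backward(dh)
    return loss


def run_two_stage(
    cohort: Cohort,
    cfg: TrainConfig,
    fusion_cfg: FusionConfig | None = None,
    image_config: ImageTowerConfig | None = None,
    gene_config: GeneTowerConfig | None = None,
) -> TrainedModel:
    """Convenience wrapper: stage-1 towers then stage-2 transfer."""
    image = train_stage1_image(cohort, cfg, image_config)
    gene = train_stage1_gene(cohort, cfg, gene_config)
    return train_stage2_transfer(
        cohort, image, gene, cfg, fusion_cfg or FusionConfig(seed=cfg.seed)
    )


# ---------------------------------------------------------------------------
# prediction / evaluation


def predict_fused(model: TrainedModel, samples: list[CohortSample]) -> np.ndarray:
    _check_dual(samples, "prediction")
    img_f = encode_image(model.image_tower, Cohort.stack_images(samples))
    gen_f = encode_gene(model.gene_tower, Cohort.stack_genes(samples))
    return classify_fused(model.fusion, fuse_features(img_f, gen_f, model.fusion))


def evaluate_fused(model: TrainedModel, samples: list[CohortSample]) -> MetricReport:
    return evaluate_predictions(Cohort.labels(samples), predict_fused(model, samples))


def evaluate_image_only(state: ImageTowerState, samples: list[CohortSample]) -> MetricReport:
    probs = image_classify(state, Cohort.stack_images(samples))
    return evaluate_predictions(Cohort.labels(samples), probs)


def evaluate_gene_only(state: GeneTowerState, samples: list[CohortSample]) -> MetricReport:
    probs = gene_classify(state, Cohort.stack_genes(samples))
    return evaluate_predictions(Cohort.labels(samples), probs)


# ---------------------------------------------------------------------------
# cross-validation


def _stratified_folds(labels: np.ndarray, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Deal each class round-robin into k folds after a seeded shuffle."""
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise FoldError("cross-validation needs both classes present")
    for cls, count in zip(classes, counts):
        if count < k:
            raise FoldError(f"class {cls} has {count} samples; cannot fill {k} folds")
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in classes:
        members = rng.permutation(np.flatnonzero(labels == cls))
        for i, m in enumerate(members):
            folds[i % k].append(int(m))
    return [np.array(sorted(f)) for f in folds]


def cross_validate(
    cohort: Cohort,
    cfg: TrainConfig,
    fusion_cfg: FusionConfig | None = None,
    k: int | None = None,
    image: ImageTowerState | None = None,
    gene: GeneTowerState | None = None,
    image_config: ImageTowerConfig | None = None,
    gene_config: GeneTowerConfig | None = None,
) -> tuple[list[MetricReport], MetricReport]:
    """Stratified k-fold cross-validation of the stage-2 transfer.

    Stage-1 towers are trained once on the unimodal splits and shared across
    folds; each fold retrains only the fusion head on the remaining folds of
    the dual-modality subset and is evaluated on the held-out fold. Returns
    the per-fold reports and their unweighted mean.
    """
    k = k or cfg.k_folds
    if k < 2:
        raise FoldError(f"k must be >= 2, got {k}")
    fusion_cfg = fusion_cfg or FusionConfig(seed=cfg.seed)
    dual = sorted(cohort.group("dual"), key=lambda s: s.sample_id)
    labels = np.array([s.label for s in dual], dtype=int)
    rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, zlib.crc32(b"cv_folds") & 0x7FFFFFFF])
    folds = _stratified_folds(labels, k, rng)

    if image is None:
        image = train_stage1_image(cohort, cfg, image_config)
    if gene is None:
        gene = train_stage1_gene(cohort, cfg, gene_config)

    reports = []
    for fold_idx, test_idx in enumerate(folds):
        test_set = set(test_idx.tolist())
        fold_samples = [
            dataclasses.replace(s, split="stage2_test" if i in test_set else "stage2_train")
            for i, s in enumerate(dual)
        ]
        fold_cohort = Cohort(samples=fold_samples, gene_ids=cohort.gene_ids)
        fold_fusion_cfg = replace(fusion_cfg, seed=fusion_cfg.seed + 101 * (fold_idx + 1))
        model = train_stage2_transfer(fold_cohort, image, gene, cfg, fold_fusion_cfg)
        reports.append(evaluate_fused(model, fold_cohort.subset("stage2_test")))
    return reports, mean_report(reports)


# ---------------------------------------------------------------------------
# persistence


def save_trained_model(model: TrainedModel, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_image_tower(model.image_tower, out / "image_tower.npz")
    save_gene_tower(model.gene_tower, out / "gene_tower.npz")
    save_fusion_head(model.fusion, out / "fusion_head.npz")
    with open(out / "history.json", "w") as fh:
        json.dump(model.history, fh, indent=2)
    with open(out / "train_config.json", "w") as fh:
        json.dump(dataclasses.asdict(model.config), fh, indent=2)


def load_trained_model(in_dir: str | Path) -> TrainedModel:
    root = Path(in_dir)
    with open(root / "history.json") as fh:
        history = json.load(fh)
    with open(root / "train_config.json") as fh:
        raw = json.load(fh)
    phases = {name: PhaseConfig(**raw[name]) for name in ("image", "gene_ae", "gene_classifier", "transfer")}
    cfg = TrainConfig(
        **phases,
        seed=raw["seed"],
        k_folds=raw["k_folds"],
        freeze_encoder_for_classifier=raw["freeze_encoder_for_classifier"],
    )
    return TrainedModel(
        image_tower=load_image_tower(root / "image_tower.npz"),
        gene_tower=load_gene_tower(root / "gene_tower.npz"),
        fusion=load_fusion_head(root / "fusion_head.npz"),
        history=history,
        config=cfg,
    )
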