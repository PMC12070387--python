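"""Synthetic radiogenomic cohorts with a controllable cross-modal signal.

The generator emulates the structure of a mixed-modality glioma cohort:
many image-only samples, many gene-only samples and a small dual-modality
subset. Each sample carries two latent signals — a scalar image latent that
drives the size and contrast of an ellipsoidal "tumor" blob in a 4-sequence
volume, and a low-rank gene latent vector whose first component is the
gene-visible label signal. The binary therapy-response label follows a
logistic model on the latents,

    P(y = 1) = sigmoid(beta * (image_effect * z_img + gene_effect * z_gene[0])),

so the ground-truth signal strength of each modality is controlled exactly:
either modality alone sees only part of the label-relevant signal, and a
model fusing both can beat the best unimodal model. Setting both effects to
0 yields a null cohort whose labels are pure coin flips.

The generator targets the pipeline's statistical assumptions, not biological
realism: there is no MRI physics, no batch effect, and gene expression is a
softplus-linear factor model rather than negative-binomial counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .cohort_io import (
    CHANNELS,
    Cohort,
    CohortSample,
    SplitSpec,
    VolumeSet,
    extract_max_tumor_slice,
    partition_cohort,
)
from .errors import ConfigError

__all__ = [
    "SynthConfig",
    "generate_volume",
    "generate_gene_profile",
    "gene_loadings",
    "generate_cohort",
    "write_raw_dataset",
]


@dataclass(frozen=True)
class SynthConfig:
    n_image_only: int = 95
    n_gene_only: int = 452
    n_multimodal: int = 50
    image_size: int = 64  # 240 supported but slow; resolution-parametric throughout
    n_genes: int = 500
    latent_dim: int = 4
    image_effect: float = 0.5
    gene_effect: float = 0.5
    noise_sd: float = 0.5
    label_scale: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_image_only, self.n_gene_only, self.n_multimodal) < 0:
            raise ConfigError("sample counts must be non-negative")
        if self.n_image_only + self.n_gene_only + self.n_multimodal == 0:
            raise ConfigError("cohort must contain at least one sample")
        for e in (self.image_effect, self.gene_effect):
            if not 0.0 <= e <= 1.0:
                raise ConfigError(f"effects must lie in [0, 1], got {e}")
        if self.image_size < 8:
            raise ConfigError(f"image_size must be >= 8, got {self.image_size}")
        if self.n_genes < self.latent_dim:
            raise ConfigError("n_genes must be >= latent_dim")

    @property
    def depth(self) -> int:
        return max(8, self.image_size // 4)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=np.float64)))


def generate_volume(latent: float, cfg: SynthConfig, rng: np.random.Generator) -> VolumeSet:
    """A 4-sequence volume plus segmentation with a latent-driven tumor blob.

    Blob radius and contrast are strictly monotone increasing in ``latent``;
    the segmentation marks the blob and is guaranteed non-empty.
    """
    s, nz = cfg.image_size, cfg.depth
    drive = _sigmoid(latent)
    r_xy = s * (0.10 + 0.08 * drive)
    r_z = nz * (0.18 + 0.12 * drive)
    amplitude = 0.6 + 0.4 * drive

    center = np.array([s / 2, s / 2, nz / 2]) + rng.uniform(-0.04, 0.04, size=3) * [s, s, nz]
    xx, yy, zz = np.meshgrid(np.arange(s), np.arange(s), np.arange(nz), indexing="ij")
    dist2 = (
        ((xx - center[0]) / r_xy) ** 2
        + ((yy - center[1]) / r_xy) ** 2
        + ((zz - center[2]) / r_z) ** 2
    )
    mask = dist2 <= 1.0
    if not mask.any():
        mask[tuple(np.round(center).astype(int).clip(0, [s - 1, s - 1, nz - 1]))] = True
    bump = np.exp(-dist2)

    channels: dict[str, np.ndarray] = {}
    # per-sequence contrast of the lesion relative to background
    contrast = {"T1": 0.6, "T2": 1.0, "T1ce": 1.3, "FLAIR": 0.9}
    for name in CHANNELS[:-1]:
        texture = ndimage.gaussian_filter(rng.normal(size=(s, s, nz)), sigma=2.0)
        base = 0.5 + 0.15 * texture
        channels[name] = np.clip(base + amplitude * contrast[name] * bump, 0.0, None)
    channels["SEG"] = mask.astype(np.float64)
    return VolumeSet(sample_id="", channels=channels, voxel_shape=(s, s, nz))


def gene_loadings(cfg: SynthConfig) -> np.ndarray:
    """Fixed (n_genes, latent_dim) factor loadings, a function of cfg.seed only."""
    rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, 977])
    return rng.normal(size=(cfg.n_genes, cfg.latent_dim))


def generate_gene_profile(
    latent: np.ndarray, cfg: SynthConfig, rng: np.random.Generator
) -> np.ndarray:
    """Non-negative expression vector: softplus of a linear factor model.

    The softplus argument is shifted into its near-linear region so the
    population covariance keeps rank ~latent_dim.
    """
    z = np.asarray(latent, dtype=np.float64)
    if z.shape != (cfg.latent_dim,):
        raise ConfigError(f"latent must have length {cfg.latent_dim}, got shape {z.shape}")
    arg = 3.0 + gene_loadings(cfg) @ z + cfg.noise_sd * rng.normal(size=cfg.n_genes)
    return np.logaddexp(0.0, arg)  # softplus


@dataclass(frozen=True)
class _PlannedSample:
    sample_id: str
    group: str  # image_only | gene_only | dual
    z_img: float
    z_gene: np.ndarray
    label: int
    index: int


def _plan(cfg: SynthConfig) -> list[_PlannedSample]:
    rng = np.random.default_rng([cfg.seed & 0x7FFFFFFF, 7])
    groups = (
        ["image_only"] * cfg.n_image_only
        + ["gene_only"] * cfg.n_gene_only
        + ["dual"] * cfg.n_multimodal
    )
    prefix = {"image_only": "img", "gene_only": "gen", "dual": "dual"}
    counters = {g: 0 for g in prefix}
    planned = []
    for i, group in enumerate(groups):
        z_img = float(rng.normal())
        z_gene = rng.normal(size=cfg.latent_dim)
        score = cfg.label_scale * (cfg.image_effect * z_img + cfg.gene_effect * z_gene[0])
        label = int(rng.random() < _sigmoid(score))
        counters[group] += 1
        planned.append(
            _PlannedSample(
                sample_id=f"{prefix[group]}-{counters[group]:04d}",
                group=group,
                z_img=z_img,
                z_gene=z_gene,
                label=label,
                index=i,
            )
        )
    return planned


def _sample_rng(cfg: SynthConfig, index: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed & 0x7FFFFFFF, 1009, index])


def generate_cohort(cfg: SynthConfig, split_spec: SplitSpec | None = None) -> Cohort:
    """Full cohort with modality masks, labels and default split assignments."""
    samples: list[CohortSample] = []
    for plan in _plan(cfg):
        rng = _sample_rng(cfg, plan.index)
        image = None
        genes = None
        if plan.group in ("image_only", "dual"):
            vol = generate_volume(plan.z_img, cfg, rng)
            vol.sample_id = plan.sample_id
            image = extract_max_tumor_slice(vol)
        if plan.group in ("gene_only", "dual"):
            genes = generate_gene_profile(plan.z_gene, cfg, rng)
        samples.append(
            CohortSample(sample_id=plan.sample_id, image=image, genes=genes, label=plan.label)
        )
    gene_ids = [f"G{i:05d}" for i in range(cfg.n_genes)]
    cohort = Cohort(samples=samples, gene_ids=gene_ids)
    spec = split_spec or SplitSpec(seed=cfg.seed)
    return partition_cohort(cohort, spec)


def write_raw_dataset(cfg: SynthConfig, out_dir: str | Path) -> Cohort:
    """Write a raw-ingestion-layout dataset and return the matching cohort.

    Layout matches :func:`twintower.cohort_io.ingest_dataset`: per-sample
    NIfTI channel files, two-column transcript quantification tables, a GTF
    with an identity transcript->gene mapping, a labels CSV and a manifest.
    """
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(cfg)
    transcripts = [f"T{i:05d}" for i in range(cfg.n_genes)]

    with open(out / "annotation.gtf", "w") as fh:
        for tid, gid in zip(transcripts, cohort.gene_ids):
            attrs = f'gene_id "{gid}"; transcript_id "{tid}";'
            fh.write(f"chr1\tsynthetic\ttranscript\t1\t1000\t.\t+\t.\t{attrs}\n")

    label_rows = []
    manifest_rows = []
    for plan, sample in zip(_plan(cfg), cohort.samples):
        if sample.has_image:
            vol = generate_volume(plan.z_img, cfg, _sample_rng(cfg, plan.index))
            vdir = out / "volumes" / sample.sample_id
            vdir.mkdir(parents=True, exist_ok=True)
            for ch in CHANNELS:
                img = nib.Nifti1Image(vol.channels[ch], affine=np.eye(4))
                nib.save(img, vdir / f"{ch.lower()}.nii.gz")
        if sample.has_gene:
            qdir = out / "gene_quant"
            qdir.mkdir(parents=True, exist_ok=True)
            pd.DataFrame({"transcript_id": transcripts, "value": sample.genes}).to_csv(
                qdir / f"{sample.sample_id}.tsv", sep="\t", header=False, index=False
            )
        label_rows.append(
            {"sample_id": sample.sample_id, "response": "positive" if sample.label else "negative"}
        )
        manifest_rows.append(
            {
                "sample_id": sample.sample_id,
                "has_image": int(sample.has_image),
                "has_gene": int(sample.has_gene),
                "label": sample.label,
                "split": sample.split,
            }
        )
    pd.DataFrame(label_rows).to_csv(out / "labels.csv", index=False)
    pd.DataFrame(manifest_rows).to_csv(out / "manifest.csv", index=False)
    return cohort
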