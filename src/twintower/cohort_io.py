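"""Reading, validating and structuring cohort inputs.

A cohort mixes three kinds of samples: image-only (multi-sequence brain MRI
plus a tumor segmentation), gene-only (RNA-seq gene expression), and
dual-modality. This module turns raw files — NIfTI volumes, two-column
transcript quantification tables, a GTF annotation and a clinical label
table — into a :class:`Cohort` with per-sample modality masks, binary
therapy-response labels and deterministic train/test split assignments.

Preprocessing conventions:

* **Slice extraction** picks the transverse slice with the most nonzero
  segmentation voxels ("maximum voxel layer sampling"); ties break toward
  the lowest slice index. Intensity channels are min-max scaled to [0, 1]
  per slice; the segmentation channel is binarized.
* **Transcript collapsing** maps transcript IDs to stable gene IDs via the
  annotation, keeps the first occurrence of each gene and drops the rest,
  then intersects gene sets across samples; columns are sorted by gene ID.
* **Splits** are stratified by label within each modality group and are a
  deterministic function of (seed, sorted sample IDs).
"""

from __future__ import annotations

import csv
import re
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import (
    EmptyMatrixError,
    LabelError,
    ModalityFileError,
    NoTumorError,
    ShapeMismatchError,
    SplitError,
)

CHANNELS = ("T1", "T2", "T1ce", "FLAIR", "SEG")

SPLITS = (
    "stage1_image_train",
    "stage1_image_test",
    "stage1_gene_train",
    "stage1_gene_test",
    "stage2_train",
    "stage2_test",
)

__all__ = [
    "CHANNELS",
    "SPLITS",
    "VolumeSet",
    "SliceStack",
    "GeneMatrix",
    "ClinicalRecord",
    "CohortSample",
    "Cohort",
    "SplitSpec",
    "load_volume_set",
    "extract_max_tumor_slice",
    "parse_gtf_transcript_map",
    "read_quant_table",
    "build_gene_matrix",
    "binarize_response",
    "partition_cohort",
    "write_cohort",
    "read_cohort",
    "ingest_dataset",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass
class VolumeSet:
    """All five co-registered 3D channels for one sample."""

    sample_id: str
    channels: dict[str, np.ndarray]
    voxel_shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        missing = [c for c in CHANNELS if c not in self.channels]
        if missing:
            raise ModalityFileError(f"{self.sample_id}: missing channels {missing}")
        shapes = {c: self.channels[c].shape for c in CHANNELS}
        if len(set(shapes.values())) != 1:
            raise ShapeMismatchError(f"{self.sample_id}: channel shapes differ: {shapes}")
        seg = self.channels["SEG"]
        if np.any(seg < 0) or not np.allclose(seg, np.round(seg)):
            raise ShapeMismatchError(f"{self.sample_id}: SEG must hold non-negative integer labels")


@dataclass
class SliceStack:
    """One transverse slice of all five channels, channel order T1,T2,T1ce,FLAIR,SEG."""

    sample_id: str
    pixels: np.ndarray  # (5, H, W)
    slice_index: int


@dataclass
class GeneMatrix:
    sample_ids: list[str]
    gene_ids: list[str]
    values: np.ndarray  # (n_samples, n_genes)

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise EmptyMatrixError("duplicate gene IDs in matrix")
        if self.values.shape != (len(self.sample_ids), len(self.gene_ids)):
            raise ShapeMismatchError(
                f"matrix shape {self.values.shape} vs "
                f"{len(self.sample_ids)} samples x {len(self.gene_ids)} genes"
            )


@dataclass(frozen=True)
class ClinicalRecord:
    sample_id: str
    response_label: int  # 1 = positive response to therapy

    def __post_init__(self) -> None:
        if self.response_label not in (0, 1):
            raise LabelError(f"{self.sample_id}: label must be 0 or 1")


@dataclass
class CohortSample:
    sample_id: str
    image: SliceStack | None
    genes: np.ndarray | None
    label: int
    split: str | None = None

    @property
    def has_image(self) -> bool:
        return self.image is not None

    @property
    def has_gene(self) -> bool:
        return self.genes is not None


@dataclass
class Cohort:
    """Samples with modality masks, labels and split assignments."""

    samples: list[CohortSample]
    gene_ids: list[str] | None = None

    def __post_init__(self) -> None:
        for s in self.samples:
            if not (s.has_image or s.has_gene):
                raise ShapeMismatchError(f"{s.sample_id}: sample has no modality at all")

    def __len__(self) -> int:
        return len(self.samples)

    def subset(self, split: str) -> list[CohortSample]:
        return [s for s in self.samples if s.split == split]

    def group(self, which: str) -> list[CohortSample]:
        """Samples by modality group: 'image_only', 'gene_only' or 'dual'."""
        if which == "image_only":
            return [s for s in self.samples if s.has_image and not s.has_gene]
        if which == "gene_only":
            return [s for s in self.samples if s.has_gene and not s.has_image]
        if which == "dual":
            return [s for s in self.samples if s.has_image and s.has_gene]
        raise ValueError(f"unknown group {which!r}")

    @staticmethod
    def stack_images(samples: Iterable[CohortSample]) -> np.ndarray:
        return np.stack([s.image.pixels for s in samples])

    @staticmethod
    def stack_genes(samples: Iterable[CohortSample]) -> np.ndarray:
        return np.stack([s.genes for s in samples])

    @staticmethod
    def labels(samples: Iterable[CohortSample]) -> np.ndarray:
        return np.array([s.label for s in samples], dtype=int)


@dataclass(frozen=True)
class SplitSpec:
    unimodal_train_fraction: float = 0.8
    multimodal_train_fraction: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (self.unimodal_train_fraction, self.multimodal_train_fraction):
            if not 0.0 < f < 1.0:
                raise SplitError(f"train fraction must lie in (0, 1), got {f}")


# ---------------------------------------------------------------------------
# volumes


def load_volume_set(paths_by_channel: Mapping[str, str | Path], sample_id: str = "") -> VolumeSet:
    """Load the five NIfTI channels of one sample and validate their shapes."""
    arrays: dict[str, np.ndarray] = {}
    for channel in CHANNELS:
        if channel not in paths_by_channel:
            raise ModalityFileError(f"missing channel {channel!r}")
        path = Path(paths_by_channel[channel])
        if not path.exists():
            raise ModalityFileError(f"{channel}: file not found: {path}")
        data = np.asanyarray(nib.load(path).dataobj).astype(np.float64)
        if data.ndim != 3:
            raise ShapeMismatchError(f"{channel}: expected a 3D volume, got ndim={data.ndim}")
        arrays[channel] = data
    sid = sample_id or Path(paths_by_channel["T1"]).parent.name
    return VolumeSet(sample_id=sid, channels=arrays, voxel_shape=arrays["T1"].shape)


def extract_max_tumor_slice(vol: VolumeSet, normalize: bool = True) -> SliceStack:
    """Cut all channels at the transverse slice with the largest tumor area.

    The transverse axis is the third array axis; among slices with the maximal
    nonzero segmentation-voxel count the lowest index wins. With ``normalize``
    each intensity channel is min-max scaled to [0, 1] on the extracted slice
    (constant slices map to 0) and SEG is binarized.
    """
    seg = vol.channels["SEG"]
    counts = np.count_nonzero(seg, axis=(0, 1))
    if counts.sum() == 0:
        raise NoTumorError(f"{vol.sample_id}: segmentation contains no tumor voxels")
    z = int(np.argmax(counts))  # argmax returns the first (lowest) maximal index
    planes = []
    for channel in CHANNELS:
        plane = vol.channels[channel][:, :, z].astype(np.float64)
        if normalize:
            if channel == "SEG":
                plane = (plane != 0).astype(np.float64)
            else:
                lo, hi = plane.min(), plane.max()
                plane = (plane - lo) / (hi - lo) if hi > lo else np.zeros_like(plane)
        planes.append(plane)
    return SliceStack(sample_id=vol.sample_id, pixels=np.stack(planes), slice_index=z)


# ---------------------------------------------------------------------------
# gene expression

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def parse_gtf_transcript_map(gtf_path: str | Path) -> dict[str, str]:
    """Extract a transcript_id -> gene_id map from a (possibly gzipped) GTF.

    Every feature line carrying both attributes contributes; the first mapping
    seen for a transcript wins.
    """
    import gzip

    path = Path(gtf_path)
    opener = gzip.open if path.suffix == ".gz" else open
    mapping: dict[str, str] = {}
    with opener(path, "rt") as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                continue
            attrs = dict(_ATTR_RE.findall(fields[8]))
            tid, gid = attrs.get("transcript_id"), attrs.get("gene_id")
            if tid and gid and tid not in mapping:
                mapping[tid] = gid
    return mapping


def read_quant_table(path: str | Path) -> list[tuple[str, float]]:
    """Read a two-column (transcript ID, expression value) TSV, order-preserving."""
    rows: list[tuple[str, float]] = []
    with open(path, newline="") as fh:
        for record in csv.reader(fh, delimiter="\t"):
            if not record or record[0].startswith("#"):
                continue
            try:
                rows.append((record[0], float(record[1])))
            except (ValueError, IndexError):
                if not rows:  # tolerate a single header line
                    continue
                raise
    return rows


def build_gene_matrix(
    quant_tables: list[tuple[str, list[tuple[str, float]]]],
    annotation: Mapping[str, str] | str | Path,
) -> GeneMatrix:
    """Collapse transcript-level tables to a samples x genes matrix.

    Transcripts absent from the annotation are dropped; when several rows of a
    table map to the same gene ID only the first occurrence (table order) is
    kept. The gene set is the intersection across samples, sorted by gene ID.
    """
    if not isinstance(annotation, Mapping):
        annotation = parse_gtf_transcript_map(annotation)
    per_sample: list[tuple[str, dict[str, float]]] = []
    for sample_id, table in quant_tables:
        if not table:
            raise EmptyMatrixError(f"{sample_id}: empty quantification table")
        gene_values: dict[str, float] = {}
        for transcript_id, value in table:
            gene_id = annotation.get(transcript_id)
            if gene_id is None or gene_id in gene_values:
                continue
            gene_values[gene_id] = value
        per_sample.append((sample_id, gene_values))

    common: set[str] | None = None
    for _, gene_values in per_sample:
        common = set(gene_values) if common is None else common & set(gene_values)
    if not common:
        raise EmptyMatrixError("no gene IDs shared by all samples after annotation mapping")
    gene_ids = sorted(common)
    values = np.array(
        [[gene_values[g] for g in gene_ids] for _, gene_values in per_sample], dtype=np.float64
    )
    return GeneMatrix(
        sample_ids=[sid for sid, _ in per_sample], gene_ids=gene_ids, values=values
    )


# ---------------------------------------------------------------------------
# labels


def binarize_response(raw_response: str, positive_categories: set[str], sample_id: str = "") -> ClinicalRecord:
    """Map a clinical response category to a binary therapy-response label.

    The set of categories counting as a positive response is a configuration
    input; clinical vocabularies differ across collections and no single
    hard-coded list is safe.
    """
    value = (raw_response or "").strip()
    if not value:
        raise LabelError(f"{sample_id}: empty clinical response value")
    known = {c.strip() for c in positive_categories}
    return ClinicalRecord(sample_id=sample_id, response_label=int(value in known))


# ---------------------------------------------------------------------------
# splitting


def _stratified_indices(
    labels: np.ndarray, n_train: int, rng: np.random.Generator
) -> np.ndarray:
    """Boolean train mask with per-class counts matching n_train by largest remainder."""
    n = labels.size
    classes, class_counts = np.unique(labels, return_counts=True)
    exact = class_counts * n_train / n
    base = np.floor(exact).astype(int)
    remainder = exact - base
    short = n_train - base.sum()
    for idx in np.argsort(-remainder, kind="stable")[:short]:
        base[idx] += 1
    train_mask = np.zeros(n, dtype=bool)
    for cls, take in zip(classes, base):
        members = np.flatnonzero(labels == cls)
        chosen = rng.permutation(members)[:take]
        train_mask[chosen] = True
    return train_mask


def partition_cohort(cohort: Cohort, spec: SplitSpec) -> Cohort:
    """Assign split labels in place (and return the cohort).

    Image-only and gene-only groups are split train:test by the unimodal
    fraction, the dual-modality group by the multimodal fraction; each split is
    stratified by label and fully determined by (seed, sorted sample IDs).
    """
    groups = [
        ("image_only", spec.unimodal_train_fraction, "stage1_image"),
        ("gene_only", spec.unimodal_train_fraction, "stage1_gene"),
        ("dual", spec.multimodal_train_fraction, "stage2"),
    ]
    for group_name, fraction, prefix in groups:
        members = sorted(cohort.group(group_name), key=lambda s: s.sample_id)
        if not members:
            continue
        labels = np.array([s.label for s in members], dtype=int)
        for cls, count in zip(*np.unique(labels, return_counts=True)):
            if count < 2:
                raise SplitError(
                    f"{group_name}: class {cls} has only {count} sample(s); cannot split"
                )
        group_tag = zlib.crc32(prefix.encode()) & 0x7FFFFFFF
        rng = np.random.default_rng([spec.seed & 0x7FFFFFFF, group_tag])
        n_train = int(round(fraction * len(members)))
        train_mask = _stratified_indices(labels, n_train, rng)
        for sample, in_train in zip(members, train_mask):
            sample.split = f"{prefix}_{'train' if in_train else 'test'}"
    return cohort


# ---------------------------------------------------------------------------
# processed-cohort persistence (slice stacks + gene matrix + manifest)


def write_cohort(cohort: Cohort, out_dir: str | Path) -> None:
    """Write a processed cohort: slice NIfTIs, a gene TSV and a manifest CSV."""
    out = Path(out_dir)
    (out / "slices").mkdir(parents=True, exist_ok=True)
    rows = []
    gene_rows: dict[str, np.ndarray] = {}
    for s in cohort.samples:
        if s.has_image:
            img = nib.Nifti1Image(s.image.pixels.astype(np.float64), affine=np.eye(4))
            nib.save(img, out / "slices" / f"{s.sample_id}.nii.gz")
        if s.has_gene:
            gene_rows[s.sample_id] = s.genes
        rows.append(
            {
                "sample_id": s.sample_id,
                "has_image": int(s.has_image),
                "has_gene": int(s.has_gene),
                "label": s.label,
                "split": s.split or "",
                "slice_index": s.image.slice_index if s.has_image else -1,
            }
        )
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
    if gene_rows:
        frame = pd.DataFrame.from_dict(gene_rows, orient="index", columns=cohort.gene_ids)
        frame.index.name = "sample_id"
        frame.to_csv(out / "gene_matrix.tsv", sep="\t")


def read_cohort(in_dir: str | Path) -> Cohort:
    """Inverse of :func:`write_cohort`."""
    root = Path(in_dir)
    manifest = pd.read_csv(root / "manifest.csv", dtype={"sample_id": str})
    gene_path = root / "gene_matrix.tsv"
    gene_frame = (
        pd.read_csv(gene_path, sep="\t", index_col="sample_id") if gene_path.exists() else None
    )
    samples: list[CohortSample] = []
    for row in manifest.itertuples(index=False):
        image = None
        if row.has_image:
            pixels = np.asanyarray(
                nib.load(root / "slices" / f"{row.sample_id}.nii.gz").dataobj
            ).astype(np.float64)
            image = SliceStack(
                sample_id=row.sample_id, pixels=pixels, slice_index=int(row.slice_index)
            )
        genes = (
            gene_frame.loc[row.sample_id].to_numpy(dtype=np.float64) if row.has_gene else None
        )
        samples.append(
            CohortSample(
                sample_id=row.sample_id,
                image=image,
                genes=genes,
                label=int(row.label),
                split=row.split if isinstance(row.split, str) and row.split else None,
            )
        )
    gene_ids = list(gene_frame.columns) if gene_frame is not None else None
    return Cohort(samples=samples, gene_ids=gene_ids)


# ---------------------------------------------------------------------------
# raw-dataset ingestion


def ingest_dataset(
    root: str | Path,
    positive_categories: set[str] | None = None,
    split_spec: SplitSpec | None = None,
) -> Cohort:
    """Build a Cohort from a raw dataset directory.

    Expected layout::

        root/
          volumes/<sample_id>/{t1,t2,t1ce,flair,seg}.nii.gz
          gene_quant/<sample_id>.tsv
          annotation.gtf
          labels.csv            # columns: sample_id,response

    Modality availability follows file presence. Labels are binarized with
    ``positive_categories`` (default ``{"positive"}``); splits come from
    ``split_spec`` (default :class:`SplitSpec` defaults).
    """
    root = Path(root)
    positive = positive_categories or {"positive"}
    labels_df = pd.read_csv(root / "labels.csv", dtype=str)
    records = {
        r.sample_id: binarize_response(r.response, positive, sample_id=r.sample_id)
        for r in labels_df.itertuples(index=False)
    }

    vol_dir, quant_dir = root / "volumes", root / "gene_quant"
    image_ids = sorted(p.name for p in vol_dir.iterdir()) if vol_dir.exists() else []
    quant_files = sorted(quant_dir.glob("*.tsv")) if quant_dir.exists() else []

    slices: dict[str, SliceStack] = {}
    for sid in image_ids:
        paths = {
            ch: vol_dir / sid / f"{ch.lower()}.nii.gz" for ch in CHANNELS
        }
        slices[sid] = extract_max_tumor_slice(load_volume_set(paths, sample_id=sid))

    gene_vectors: dict[str, np.ndarray] = {}
    gene_ids: list[str] | None = None
    if quant_files:
        tables = [(p.stem, read_quant_table(p)) for p in quant_files]
        matrix = build_gene_matrix(tables, root / "annotation.gtf")
        gene_ids = matrix.gene_ids
        gene_vectors = dict(zip(matrix.sample_ids, matrix.values))

    samples = []
    for sid in sorted(set(slices) | set(gene_vectors)):
        if sid not in records:
            raise LabelError(f"{sid}: sample has data but no clinical label")
        samples.append(
            CohortSample(
                sample_id=sid,
                image=slices.get(sid),
                genes=gene_vectors.get(sid),
                label=records[sid].response_label,
            )
        )
    cohort = Cohort(samples=samples, gene_ids=gene_ids)
    return partition_cohort(cohort, split_spec or SplitSpec())
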