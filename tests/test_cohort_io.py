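import numpy as np
import nibabel as nib
import pytest

from twintower.cohort_io import (
    Cohort,
    CohortSample,
    SliceStack,
    SplitSpec,
    VolumeSet,
    binarize_response,
    build_gene_matrix,
    extract_max_tumor_slice,
    ingest_dataset,
    load_volume_set,
    parse_gtf_transcript_map,
    partition_cohort,
    read_cohort,
    write_cohort,
)
from twintower.errors import (
    EmptyMatrixError,
    LabelError,
    ModalityFileError,
    NoTumorError,
    ShapeMismatchError,
    SplitError,
)
from twintower.synthetic_cohort import SynthConfig, generate_cohort, write_raw_dataset

CHANNELS = ("T1", "T2", "T1ce", "FLAIR", "SEG")


def _write_volumes(tmp_path, shapes):
    paths = {}
    rng = np.random.default_rng(0)
    for ch, shape in shapes.items():
        data = rng.random(shape) if ch != "SEG" else (rng.random(shape) > 0.8).astype(float)
        p = tmp_path / f"{ch}.nii.gz"
        nib.save(nib.Nifti1Image(data, np.eye(4)), p)
        paths[ch] = p
    return paths


class TestLoadVolumeSet:
    def test_loads_five_channels_with_shape(self, tmp_path):
        paths = _write_volumes(tmp_path, {ch: (12, 12, 7) for ch in CHANNELS})
        vs = load_volume_set(paths, sample_id="x")
        assert vs.voxel_shape == (12, 12, 7)
        assert set(vs.channels) == set(CHANNELS)

    def test_missing_channel_raises(self, tmp_path):
        paths = _write_volumes(tmp_path, {ch: (8, 8, 4) for ch in CHANNELS[:-1]})
        with pytest.raises(ModalityFileError):
            load_volume_set(paths)

    def test_shape_mismatch_raises(self, tmp_path):
        shapes = {ch: (8, 8, 4) for ch in CHANNELS}
        shapes["T2"] = (8, 8, 3)
        paths = _write_volumes(tmp_path, shapes)
        with pytest.raises(ShapeMismatchError):
            load_volume_set(paths)


def _toy_volume(seg):
    seg = np.asarray(seg, dtype=float)
    channels = {ch: np.random.default_rng(1).random(seg.shape) for ch in CHANNELS[:-1]}
    channels["SEG"] = seg
    return VolumeSet(sample_id="toy", channels=channels, voxel_shape=seg.shape)


class TestExtractMaxTumorSlice:
    def test_counts_2_7_7_picks_lower_tied_slice(self):
        seg = np.zeros((4, 4, 3))
        seg[:2, 0, 0] = 1  # 2 voxels
        seg[:4, :2, 1] = (np.arange(8).reshape(4, 2) < 7).astype(float)  # 7 voxels
        seg[0, :4, 2] = 1
        seg[1, :3, 2] = 1  # 7 voxels
        stack = extract_max_tumor_slice(_toy_volume(seg))
        assert stack.slice_index == 1
        assert stack.pixels.shape == (5, 4, 4)

    def test_all_zero_seg_raises(self):
        with pytest.raises(NoTumorError):
            extract_max_tumor_slice(_toy_volume(np.zeros((4, 4, 3))))

    def test_normalization_ranges(self):
        seg = np.zeros((6, 6, 2))
        seg[2:4, 2:4, 1] = 3.0  # non-binary labels allowed upstream
        stack = extract_max_tumor_slice(_toy_volume(seg))
        assert set(np.unique(stack.pixels[4])) <= {0.0, 1.0}
        assert stack.pixels[:4].min() >= 0.0 and stack.pixels[:4].max() <= 1.0

    def test_agrees_with_exhaustive_count_oracle(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            seg = (rng.random((5, 6, 7)) > 0.7).astype(float)
            if not seg.any():
                continue
            counts = [int(np.count_nonzero(seg[:, :, z])) for z in range(seg.shape[2])]
            expected = int(np.argmax(counts))
            assert extract_max_tumor_slice(_toy_volume(seg)).slice_index == expected


class TestBuildGeneMatrix:
    ANNOT = {"t1": "A", "t2": "A", "t3": "B", "t4": "B", "t5": "C"}

    def test_keep_first_occurrence_rule(self):
        table = [("t1", 1.0), ("t2", 9.0), ("t3", 2.0), ("t4", 8.0), ("t5", 3.0)]
        gm = build_gene_matrix([("s1", table)], self.ANNOT)
        assert gm.gene_ids == ["A", "B", "C"]
        assert gm.values.tolist() == [[1.0, 2.0, 3.0]]

    def test_disjoint_annotated_transcripts_raise(self):
        with pytest.raises(EmptyMatrixError):
            build_gene_matrix(
                [("s1", [("t1", 1.0)]), ("s2", [("t5", 2.0)])], self.ANNOT
            )

    def test_unique_transcripts_reorder_by_gene_id(self):
        annot = {"x": "Zgene", "y": "Agene"}
        gm = build_gene_matrix([("s1", [("x", 5.0), ("y", 7.0)])], annot)
        assert gm.gene_ids == ["Agene", "Zgene"]
        assert gm.values.tolist() == [[7.0, 5.0]]

    def test_unannotated_transcripts_dropped_and_no_duplicates(self):
        table = [("t1", 1.0), ("unknown", 4.0), ("t2", 2.0)]
        gm = build_gene_matrix([("s1", table)], self.ANNOT)
        assert gm.gene_ids == ["A"]
        assert len(set(gm.gene_ids)) == len(gm.gene_ids)

    def test_gtf_parsing_roundtrip(self, tmp_path):
        gtf = tmp_path / "ann.gtf"
        gtf.write_text(
            "# comment\n"
            'chr1\tsrc\ttranscript\t1\t10\t.\t+\t.\tgene_id "G1"; transcript_id "T1";\n'
            'chr1\tsrc\texon\t1\t5\t.\t+\t.\tgene_id "G1"; transcript_id "T1";\n'
            'chr2\tsrc\ttranscript\t1\t10\t.\t-\t.\tgene_id "G2"; transcript_id "T2";\n'
        )
        assert parse_gtf_transcript_map(gtf) == {"T1": "G1", "T2": "G2"}


class TestBinarizeResponse:
    POSITIVE = {"Complete Response", "Partial Response"}

    def test_member_maps_to_one(self):
        assert binarize_response("Complete Response", self.POSITIVE).response_label == 1

    def test_non_member_maps_to_zero(self):
        assert binarize_response("Progressive Disease", self.POSITIVE).response_label == 0

    def test_empty_raises(self):
        with pytest.raises(LabelError):
            binarize_response("", self.POSITIVE)


def _mask_cohort(n_img, n_gene, n_dual, seed=0):
    """Cohort of stub samples (1x1 images) for split bookkeeping tests."""
    rng = np.random.default_rng(seed)
    samples = []
    specs = [("i", n_img, True, False), ("g", n_gene, False, True), ("d", n_dual, True, True)]
    for prefix, n, has_img, has_gene in specs:
        for k in range(n):
            img = (
                SliceStack(f"{prefix}{k:04d}", np.zeros((5, 8, 8)), 0) if has_img else None
            )
            genes = np.ones(4) if has_gene else None
            samples.append(
                CohortSample(f"{prefix}{k:04d}", img, genes, int(rng.random() < 0.5))
            )
    return Cohort(samples=samples, gene_ids=list("ABCD"))


class TestPartitionCohort:
    def test_ratio_arithmetic(self):
        cohort = partition_cohort(_mask_cohort(95, 0, 50), SplitSpec(seed=1))
        assert len(cohort.subset("stage1_image_train")) == 76
        assert len(cohort.subset("stage1_image_test")) == 19
        assert len(cohort.subset("stage2_train")) == 30
        assert len(cohort.subset("stage2_test")) == 20

    def test_deterministic_and_seed_sensitive(self):
        a = partition_cohort(_mask_cohort(40, 30, 20), SplitSpec(seed=5))
        splits_a = {s.sample_id: s.split for s in a.samples}
        b = partition_cohort(_mask_cohort(40, 30, 20), SplitSpec(seed=5))
        assert splits_a == {s.sample_id: s.split for s in b.samples}
        c = partition_cohort(_mask_cohort(40, 30, 20), SplitSpec(seed=6))
        splits_c = {s.sample_id: s.split for s in c.samples}
        assert splits_a != splits_c
        # sizes invariant to seed
        for name in ("stage1_image_train", "stage1_gene_train", "stage2_train"):
            assert len(a.subset(name)) == len(c.subset(name))

    def test_disjoint_and_exhaustive(self):
        cohort = partition_cohort(_mask_cohort(21, 17, 13), SplitSpec(seed=2))
        assert all(s.split is not None for s in cohort.samples)
        img = cohort.group("image_only")
        assert {s.split for s in img} <= {"stage1_image_train", "stage1_image_test"}
        assert len(cohort.subset("stage1_image_train")) + len(
            cohort.subset("stage1_image_test")
        ) == len(img)

    def test_stratification_within_one_sample(self):
        cohort = partition_cohort(_mask_cohort(0, 60, 0, seed=4), SplitSpec(seed=9))
        members = cohort.group("gene_only")
        pos = sum(s.label for s in members)
        train = cohort.subset("stage1_gene_train")
        expected = pos * len(train) / len(members)
        assert abs(sum(s.label for s in train) - expected) <= 1.0

    def test_tiny_stratum_raises(self):
        cohort = _mask_cohort(0, 4, 0, seed=0)
        for s, lab in zip(cohort.samples, [1, 0, 0, 0]):
            s.label = lab
        with pytest.raises(SplitError):
            partition_cohort(cohort, SplitSpec(seed=0))


class TestPersistence:
    def test_processed_cohort_roundtrip(self, tmp_path):
        cfg = SynthConfig(
            n_image_only=8, n_gene_only=10, n_multimodal=6, image_size=16, n_genes=10, seed=5
        )
        cohort = generate_cohort(cfg)
        write_cohort(cohort, tmp_path)
        back = read_cohort(tmp_path)
        assert len(back) == len(cohort)
        for a, b in zip(cohort.samples, back.samples):
            assert a.sample_id == b.sample_id and a.label == b.label and a.split == b.split
            if a.has_image:
                np.testing.assert_allclose(a.image.pixels, b.image.pixels)
            if a.has_gene:
                np.testing.assert_allclose(a.genes, b.genes)
        assert back.gene_ids == cohort.gene_ids

    def test_raw_dataset_ingestion_matches_generator(self, tmp_path):
        cfg = SynthConfig(
            n_image_only=8, n_gene_only=10, n_multimodal=6, image_size=16, n_genes=8, seed=7
        )
        cohort = write_raw_dataset(cfg, tmp_path)
        back = ingest_dataset(tmp_path)
        assert len(back) == len(cohort)
        by_id = {s.sample_id: s for s in back.samples}
        for s in cohort.samples:
            t = by_id[s.sample_id]
            assert t.label == s.label
            assert t.has_image == s.has_image and t.has_gene == s.has_gene
            if s.has_image:
                np.testing.assert_allclose(t.image.pixels, s.image.pixels, atol=1e-12)
            if s.has_gene:
                np.testing.assert_allclose(t.genes, s.genes, atol=1e-12)
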