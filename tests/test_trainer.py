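import dataclasses

import numpy as np
import pytest

from twintower.cohort_io import Cohort
from twintower.errors import EmptyTrainingSetError, FoldError, ModalityError
from twintower.fusion_head import FusionConfig
from twintower.trainer import (
    TrainConfig,
    _stratified_folds,
    cross_validate,
    desk_scale_config,
    load_trained_model,
    run_two_stage,
    save_trained_model,
    train_stage1_gene,
    train_stage1_image,
    train_stage2_transfer,
)

from conftest import make_linear_gene_cohort, make_separable_image_cohort


def _all_params(model):
    states = [model.image_tower, model.gene_tower, model.fusion]
    return [p.value.copy() for s in states for p in s.parameters()]


@pytest.fixture(scope="module")
def trained(small_cohort, train_config):
    return run_two_stage(small_cohort, train_config)


class TestStage1:
    def test_history_lengths_match_epoch_budgets(self, trained, train_config):
        assert len(trained.history["image_loss"]) == train_config.image.epochs
        assert len(trained.history["gene_ae_loss"]) == train_config.gene_ae.epochs
        assert len(trained.history["transfer_loss"]) == train_config.transfer.epochs

    def test_image_training_is_deterministic(self):
        cohort = make_separable_image_cohort(n=24, size=16, seed=1)
        cfg = desk_scale_config(seed=1)
        a = train_stage1_image(cohort, cfg)
        b = train_stage1_image(cohort, cfg)
        for pa, pb in zip(a.parameters(), b.parameters()):
            assert np.array_equal(pa.value, pb.value)

    def test_image_loss_descends_on_separable_cohort(self):
        cohort = make_separable_image_cohort(n=40, size=16, seed=2)
        state = train_stage1_image(cohort, desk_scale_config(seed=2))
        assert state.history["loss"][-1] < state.history["loss"][0]

    def test_missing_image_samples_raise(self):
        cohort = make_linear_gene_cohort(n=20)
        with pytest.raises(EmptyTrainingSetError):
            train_stage1_image(cohort, desk_scale_config())

    def test_ae_loss_descends_and_classifier_leaves_encoder_frozen(self):
        cohort = make_linear_gene_cohort(n=80, n_genes=25, seed=3)
        cfg = desk_scale_config(seed=3)
        state = train_stage1_gene(cohort, cfg)
        assert state.history["ae_loss"][-1] < state.history["ae_initial_mse"][0]
        # re-run the AE phase only and compare encoders: classifier phase must not touch them
        cfg_short = dataclasses.replace(
            cfg, gene_classifier=dataclasses.replace(cfg.gene_classifier, epochs=1)
        )
        a = train_stage1_gene(cohort, cfg)
        b = train_stage1_gene(cohort, cfg_short)
        for pa, pb in zip(a.encoder_parameters(), b.encoder_parameters()):
            assert np.array_equal(pa.value, pb.value)


class TestStage2:
    def test_towers_bitwise_frozen_through_transfer(self, small_cohort, train_config):
        image = train_stage1_image(small_cohort, train_config)
        gene = train_stage1_gene(small_cohort, train_config)
        img_before = [p.value.copy() for p in image.parameters()]
        gene_before = [p.value.copy() for p in gene.parameters()]
        model = train_stage2_transfer(
            small_cohort, image, gene, train_config, FusionConfig(seed=3)
        )
        assert model.image_tower.frozen and model.gene_tower.frozen
        for before, p in zip(img_before, model.image_tower.parameters()):
            assert np.array_equal(before, p.value)
        for before, p in zip(gene_before, model.gene_tower.parameters()):
            assert np.array_equal(before, p.value)

    def test_sample_missing_modality_raises(self, small_cohort, train_config):
        image = train_stage1_image(small_cohort, train_config)
        gene = train_stage1_gene(small_cohort, train_config)
        broken = Cohort(
            samples=[
                dataclasses.replace(s, split="stage2_train")
                for s in small_cohort.group("gene_only")[:6]
            ],
            gene_ids=small_cohort.gene_ids,
        )
        with pytest.raises(ModalityError):
            train_stage2_transfer(broken, image, gene, train_config, FusionConfig())

    def test_two_stage_run_is_bit_reproducible(self, small_cohort, train_config):
        a = run_two_stage(small_cohort, train_config)
        b = run_two_stage(small_cohort, train_config)
        for pa, pb in zip(_all_params(a), _all_params(b)):
            assert np.array_equal(pa, pb)
        assert a.history == b.history

    def test_test_samples_do_not_influence_training(self, small_cohort, train_config):
        reference = run_two_stage(small_cohort, train_config)
        perturbed_samples = []
        rng = np.random.default_rng(0)
        for s in small_cohort.samples:
            if s.split in ("stage2_test", "stage1_image_test", "stage1_gene_test"):
                s = dataclasses.replace(
                    s,
                    genes=None if s.genes is None else s.genes + rng.random(s.genes.shape),
                )
            perturbed_samples.append(s)
        perturbed = Cohort(samples=perturbed_samples, gene_ids=small_cohort.gene_ids)
        model = run_two_stage(perturbed, train_config)
        for pa, pb in zip(_all_params(reference), _all_params(model)):
            assert np.array_equal(pa, pb)


class TestCrossValidation:
    def test_three_folds_produce_three_reports(self, small_cohort, train_config):
        reports, mean = cross_validate(small_cohort, train_config, k=3)
        assert len(reports) == 3
        accs = [r.accuracy for r in reports]
        assert mean.accuracy == pytest.approx(np.mean(accs))

    def test_folds_partition_the_dual_subset(self):
        labels = np.array([0, 1] * 9)
        folds = _stratified_folds(labels, 3, np.random.default_rng(0))
        combined = np.concatenate(folds)
        assert sorted(combined.tolist()) == list(range(18))
        assert all(len(set(f.tolist())) == len(f) for f in folds)
        for f in folds:
            assert 0 < labels[f].sum() < len(f)  # both classes in every fold

    def test_class_smaller_than_k_raises(self):
        with pytest.raises(FoldError):
            _stratified_folds(np.array([0, 0, 0, 0, 1, 1]), 3, np.random.default_rng(0))

    def test_k_below_two_raises(self, small_cohort, train_config):
        with pytest.raises(FoldError):
            cross_validate(small_cohort, train_config, k=1)


def test_trained_model_roundtrips_through_checkpoint(tmp_path, trained, small_cohort):
    from twintower.trainer import predict_fused

    save_trained_model(trained, tmp_path)
    back = load_trained_model(tmp_path)
    test = small_cohort.subset("stage2_test")
    np.testing.assert_array_equal(predict_fused(back, test), predict_fused(trained, test))
    assert back.config == trained.config
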