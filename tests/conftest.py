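import numpy as np
import pytest

from twintower.cohort_io import Cohort, CohortSample, SliceStack
from twintower.synthetic_cohort import SynthConfig, generate_cohort
from twintower.trainer import desk_scale_config


@pytest.fixture(scope="session")
def small_synth_config() -> SynthConfig:
    """A fast cohort: 32x32 volumes, 60 genes, ~80 samples."""
    return SynthConfig(
        n_image_only=24, n_gene_only=40, n_multimodal=14, image_size=32, n_genes=60, seed=3
    )


@pytest.fixture(scope="session")
def small_cohort(small_synth_config) -> Cohort:
    return generate_cohort(small_synth_config)


@pytest.fixture(scope="session")
def train_config():
    return desk_scale_config(seed=3)


def make_separable_image_cohort(
    n: int = 60, size: int = 16, seed: int = 0, split: str = "stage1_image_train"
) -> Cohort:
    """Image-only cohort where class 1 slices are globally brighter: trivially separable."""
    rng = np.random.default_rng(seed)
    samples = []
    for i in range(n):
        label = i % 2
        base = 0.8 if label else 0.2
        pixels = np.clip(base + 0.05 * rng.normal(size=(5, size, size)), 0, 1)
        pixels[4] = (pixels[4] > base).astype(float)
        stack = SliceStack(sample_id=f"s{i:03d}", pixels=pixels, slice_index=0)
        samples.append(CohortSample(sample_id=f"s{i:03d}", image=stack, genes=None, label=label, split=split))
    return Cohort(samples=samples)


def make_linear_gene_cohort(
    n: int = 120, n_genes: int = 20, seed: int = 0, split: str = "stage1_gene_train"
) -> Cohort:
    """Gene-only cohort whose label is a linear function of two genes."""
    rng = np.random.default_rng(seed)
    samples = []
    for i in range(n):
        genes = rng.gamma(2.0, 2.0, size=n_genes)
        label = int(genes[0] > genes[1])
        samples.append(
            CohortSample(sample_id=f"g{i:03d}", image=None, genes=genes, label=label, split=split)
        )
    return Cohort(samples=samples, gene_ids=[f"G{j}" for j in range(n_genes)])
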