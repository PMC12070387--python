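# Methods

## Model

The package predicts a binary therapy-response label from two modalities
with mostly-disjoint coverage. Each modality has its own encoder:

* **Image tower.** Input is a five-channel 2D slice (T1, T2, T1ce, FLAIR,
  segmentation) cut from co-registered 3D volumes at the transverse slice
  with the most nonzero segmentation voxels (ties go to the lowest slice
  index; the transverse axis is the third array axis, indices 0-based).
  The network is three blocks of 3×3 convolution (stride 1, 'same'
  padding) → 2×2 max pooling → ReLU with 8/16/32 filters, then flatten →
  dense(32) → ReLU → dense(16). The 16-d output is the image feature
  vector; a single sigmoid unit on top of it serves stage-1 training and
  the image-only ablation.
* **Gene tower.** Input is a gene-level expression vector. An autoencoder
  with encoder dense(64)–ReLU–dense(32)–ReLU and a mirrored decoder whose
  output layer is linear is trained under mean squared error; the 32-d
  bottleneck activation is the gene feature vector. After AE training a
  classifier head (dense 64 → ReLU → dense 16 → ReLU → sigmoid) attaches
  to the bottleneck; by default the encoder stays frozen during that
  phase so classification cannot distort the learned compression.
* **Fusion.** Image and gene features are standardized separately (per
  dimension, mean 0 / variance 1 with the sample formula, ddof = 1,
  standard deviations floored at 1e-8) using statistics fitted on the
  multimodal *training* subset only; fitting on test features would leak
  information. The scaled features are concatenated image-first into a
  48-d vector and classified by dense 64 → 128 → 16 → sigmoid. The
  alternative mixture-of-experts mode runs `n_experts` copies of that
  head and combines their sigmoid outputs with weights from a softmax
  gating network over the same 48-d input — the minimal classic
  mixture-of-experts realization. With one expert the gate is a constant
  1 and the prediction equals the ungated head.

Training is two-staged: the towers learn from modality-exclusive samples
(80:20 train/test within each unimodal group), then both are frozen and
only the fusion head trains on the dual-modality subset (3:2 train/test).
Freezing is implemented by never handing frozen parameters to an
optimizer, so the contract is bitwise: an entire training epoch leaves
every frozen parameter binary-identical.

## Hyperparameters

| phase | optimizer | momentum/β₁ | loss | learning rate | decay | epochs | batch |
|---|---|---|---|---|---|---|---|
| image tower | SGD | 0.9 | BCE | 2e-5 | 2e-7 | 20 | 16 |
| gene AE | Adam | 0.9 | MSE | 1e-4 | 2e-7 | 20 | 16 |
| transfer | SGD | 0.9 | BCE | 1e-4 | 2e-7 | 10 | 16 |

These are the library defaults (`TrainConfig()`), appropriate for
full-resolution MRI (240×240) and ~19k-gene inputs. "Cross entropy" with
a single sigmoid output is realized as binary cross-entropy, computed
from logits in the overflow-safe `log(1+e^{-|z|})` form. The decay rate
is a per-step multiplicative learning-rate decay, `lr ← lr·(1−decay)`.
SGD uses the heavy-ball recursion `v ← μv + g`, `w ← w − lr·v`. The gene
classifier phase reuses the gene-tower optimizer settings with BCE. No
early stopping or validation-based checkpointing is used; epoch budgets
are fixed.

`desk_scale_config()` serves the synthetic experiments (64×64 slices, 500
genes, 76 image / 362 gene / 30 fusion training samples). At that scale
the default rates are too small to move the loss within the fixed epoch
budgets, so it raises them (image SGD 1e-2, gene Adam 1e-3, transfer SGD
5e-2) and adds mild L2 weight decay (1e-3 on the towers' classification
phases, 3e-2 on the fusion head) against small-sample overfitting —
30 training samples against a ~12k-parameter head need shrinkage.
Optimizers, losses, epochs and batch sizes are unchanged. Weight decay
defaults to 0 everywhere else.

All randomness flows from explicit integer seeds: parameter
initialization from each component's config seed (Glorot-uniform), and
mini-batch order from `(train seed, phase tag, epoch)`, so identical
inputs give bit-identical trained models and reports.

## Preprocessing

* MRI intensity channels are min–max scaled to [0, 1] per extracted
  slice (a constant slice maps to 0); the segmentation channel is
  binarized (≠0 → 1). Volumes are assumed co-registered, resampled and
  skull-stripped upstream.
* Gene quantification tables are transcript-level; transcripts map to
  stable gene IDs through a GTF annotation, the first occurrence of each
  gene is kept and later duplicates dropped ("remove" rather than
  aggregate — deterministic and order-faithful), unannotated transcripts
  are dropped, and the gene set is intersected across samples and sorted.
* Gene vectors pass through log(1+x) and per-gene standardization fitted
  on the gene-training samples before entering the autoencoder; raw
  RNA-seq magnitudes span orders of magnitude and make a global MSE
  objective degenerate. The fitted statistics travel with the tower
  checkpoint. Both transforms can be disabled.
* Which clinical response categories count as "positive response" is a
  required configuration input, not a hard-coded list: response
  vocabularies differ across collections.

## Splits, cross-validation, metrics

Splits are stratified by label within each modality group (largest-
remainder allocation, so class proportions hold within ±1 sample) and are
a deterministic function of the seed and the sorted sample IDs; a stratum
with fewer than two samples is an error. Cross-validation deals each
class round-robin into k stratified folds of the dual-modality subset;
stage-1 towers are trained once and shared across folds, and only the
fusion head is refitted, since stage 1 never sees dual-modality data.
Fold metrics are averaged unweighted.

Precision, recall and F1 use the 0/0 → 0 convention with an explicit
degeneracy flag rather than an exception, because 16-sample folds can
legitimately produce empty prediction classes. Hard labels threshold the
sigmoid output at 0.5. The ROC sweeps thresholds over the unique scores
in descending order with tied scores grouped into one step; AUC is the
trapezoidal area, which equals the Mann–Whitney concordance statistic.
Max-pooling routes gradients to the first maximum within each window —
ties are common because the binarized segmentation channel is piecewise
constant — which keeps backward passes deterministic.

## Synthetic cohorts

The generator reproduces the structural conditions of the study cohort:
95 image-only, 452 gene-only and 50 dual-modality samples (597 total),
binary labels, 80:20 and 3:2 splits. Each sample has a scalar image
latent `z_img` and a gene latent vector `z ∈ ℝ⁴`; the label is Bernoulli
with `P(y=1) = σ(β·(e_img·z_img + e_gene·z₁))`, defaults
`e_img = e_gene = 0.5`, `β = 6`. Under these defaults the population
Bayes accuracy is ≈ 0.88 from both modalities and ≈ 0.73 from either
alone, so fusion has real headroom and either-alone models have a real
ceiling.

Volumes are 64×64×16 by default (resolution-parametric; 240 works but is
slow) with four textured intensity channels and an ellipsoidal lesion
whose radius and contrast are strictly monotone in `z_img`; the
segmentation marks the lesion and is never empty. Expression is
`softplus(3 + L·z + ε)` with fixed seed-derived loadings `L` and noise
standard deviation 0.5; the +3 shift keeps softplus near-linear so the
population covariance stays effectively rank-4. 500 genes by default
keep autoencoder training desk-sized; the input dimension is config-
driven throughout.

What the generator does *not* emulate: MRI physics or artifacts, batch
effects, count-based expression noise (negative binomial), censoring, or
correlated missingness. Passing tests therefore demonstrate that the
pipeline recovers signal under its own statistical assumptions, not
clinical performance on real cohorts.

## Known limitations

* Single-slice 2D modeling; no multi-slice aggregation or 3D context.
* The published full-scale results require the original TCGA-derived
  cohort and its label mapping, which are not redistributable inputs;
  the synthetic experiments are a scaled-down analog, and their absolute
  accuracies are not comparable to the published ones.
* With 50 dual-modality samples, 20-sample test sets quantize accuracy
  in steps of 0.05, so single-seed comparisons between fused and
  unimodal models are noisy; the experiments report medians over seeds.
* The mixture-of-experts head has more parameters and a harder,
  non-convex gated objective on the same 30 training samples, and
  typically underperforms plain concatenation here — consistent with its
  role as an alternative rather than the default.
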