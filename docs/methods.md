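# Methods

## The problem

Meningiomas are dural-based tumors that sit at the border of the brain on
MRI. Automating their volumetric segmentation is attractive for growth
monitoring, but clinical meningioma datasets are small and heterogeneous
(solid, cystic, calcified and heterogeneously enhancing lesions), and
lesion-free "normal" brains — which carry useful negative evidence — are
useless under the standard soft Dice loss. This package implements a
training methodology for that regime: transfer learning from a larger
tumor domain, augmentation with lesion-free brains, a *balanced Dice loss*
that makes those brains informative, patient-grouped data splitting, and
five-fold cross-validated epoch selection. Everything runs at desk scale on
synthetic phantoms.

## Losses

With network output `P ∈ [0,1]^V` and binary ground truth `T ∈ {0,1}^V`,

    DSC(P, T)     = 2 Σ P·T / (Σ P + Σ T)
    L_Dice(P, T)  = 1 − (2 Σ P·T + ε) / (Σ P + Σ T + ε)

The smoothing constant ε (default 1e-5) keeps the ratio defined when both
maps are empty, making a perfect empty prediction cost exactly 0. For a
lesion-free image (ΣT = 0) the loss reduces to `1 − ε/(ΣP + ε)`: it sits at
essentially 1 whatever the network does, and its gradient
`ε/(ΣP + ε)²` is vanishingly small — normal brains barely train the model.
The balanced Dice loss (BDL) re-weights exactly those images. With
`α = max(T)` per image:

    L_BD = L_Dice            if α = 1  (lesion present)
    L_BD = β · L_Dice        if α = 0  (lesion-free)

The weight β (default 100, the value selected by five-fold cross-validation
in the study this methodology follows) multiplies both the value and the
gradient of the loss on empty-mask images. Batch losses are *summed* over
images, not averaged. One subtlety worth recording: the branch form above
follows the prose definition of the loss (β multiplies the loss when
ΣT = 0); a literal one-line algebraic composition of the two branches would
be degenerate, since both branches contain the same `L_Dice` term.

The `aggregate_metrics` summary defaults to the sample standard deviation
(ddof=1); the population flavor is available via `ddof=0` and is the one
that reproduces, at two decimals, the conventionally printed spread of the
five fold scores used in the tests (sample sd of {0.88, 0.82, 0.86, 0.92,
0.80} is 0.048 → 0.05, population sd is 0.043 → 0.04).

## Network

A 3D U-Net in the encoder/decoder style established for brain-tumor
segmentation: a context pathway whose filter count doubles per level
(`base_filters · 2^l`), stride-2 convolutions for downsampling, and a
localization pathway of nearest-neighbor upsampling, a channel-halving
3×3×3 convolution, skip concatenation, and a 3×3×3 + 1×1×1 localization
module. Instance normalization (statistics per sample per channel, so
inference is batch-independent and training is stable at batch size 1) and
leaky ReLU (slope 0.01) follow every convolution. The head is a 1×1×1
convolution with a sigmoid producing a single foreground-probability
channel; pre-training therefore uses the same binary whole-lesion head as
fine-tuning and transfer needs no head surgery. Deep supervision is not
used.

The layers (3D convolution via im2col with analytic backprop, instance
norm, upsampling, sigmoid) and the Adam optimizer are implemented in numpy
inside `bdlseg.nn` and verified by central finite-difference gradient
checks and a closed-form parameter-count oracle in the test suite. Two
initialization choices matter:

* He-style weight scaling for leaky-ReLU fan-in, seeded and reproducible;
* the head bias starts at −4, so the initial sigmoid output is ≈ 0.018
  everywhere. With an unbiased head the Dice loss spends most of its early
  budget suppressing the dominant background; the background-prior bias is
  standard practice for sparse-foreground heads and makes the single-case
  capacity check converge in well under 120 epochs.

## Training protocol

* **Optimizer**: Adam, initial learning rate 1e-4, halved every 30 epochs
  (`lr(e) = lr₀ · 0.5^⌊e/30⌋`). The toy presets use 1e-3 since the phantom
  problems are far smaller than 128³ clinical volumes.
* **Splitting**: the test set is drawn only from non-follow-up lesion
  cases; follow-up patients contribute several scans each and must never
  straddle the train/test boundary. Normal brains always remain in
  training.
* **Cross-validation**: k folds partition lesion *patients* (all scans of a
  patient share a fold; fold patient counts balanced within one). Normal
  brains join every training side and no validation side, and the
  validation score is the unweighted soft Dice loss over lesion cases only,
  so model selection stays comparable between strategies that do and do not
  train on normals.
* **β selection**: `optimize_beta` grid-searches {1, 10, 100, 1000} by the
  same cross-validation, scoring each candidate by its best fold-averaged
  validation loss; 100 is the packaged default.
* **Epoch selection**: epoch* = argmin over epochs of the fold-averaged
  validation loss (earliest epoch on ties); the final model retrains from
  the same initialization on the full training set through epoch*.
* **Fine-tuning**: all layers unfrozen; a checkpoint carries its
  architecture config and transfer across mismatched architectures is
  refused.

## Phantoms

Each case is an ellipsoidal brain (semi-axes ≈ 0.42 of the grid edge with
seeded jitter) with smoothed-Gaussian-field tissue texture in four channels
(T1, contrast-enhanced T1, T2, FLAIR) and exact zeros outside the brain.
Lesions are perturbed-sphere blobs whose voxel count is driven to a target
fraction of brain volume by bisection on the blob radius. `target-like`
lesions are centered within 15% of the grid edge from the brain boundary
(the dural-based phenotype); `pretrain-like` lesions are interior and carry
a FLAIR-bright edema halo that is *not* part of the mask. Four appearance
classes modulate the channel contrasts: solid (enhancing), cystic
(T2-bright core, enhancing rim), calcified (hypointense everywhere) and
heterogeneous (enhancing rim, necrotic core). Additive Gaussian noise
(default sd 0.05 of the tissue contrast scale) is applied inside the brain.

Cohorts mirror a follow-up-heavy registry: `CohortSpec(35, 115, 56, 10)`
reproduces the 181-scan / 101-subject shape used throughout the tests, with
follow-up scan counts per patient drawn as a seeded partition (minimum two
each). Appearance classes cycle deterministically through the cohort and
lesion volume fractions are jittered by ×[0.5, 1.5]; class prevalences in
real cohorts are not documented quantitatively, so uniform cycling is an
arbitrary but reproducible default.

What the phantoms deliberately do **not** model: MRI physics (bias fields,
partial volume, acquisition protocol differences), registration error,
multi-institution variation, or anatomically realistic tissue. Passing
tests therefore demonstrate that the losses, splitting rules, selection
machinery and training dynamics behave as specified — not that the network
would reach any particular Dice score on clinical data.

## Scaled-down ablation

The five training strategies are: [A] pre-training domain only, [B] target
domain from scratch, [C] pre-train then fine-tune, [D] C plus normal brains
with soft Dice loss, [E] C plus normal brains with BDL. The desk-scale
analog in `bdlseg.experiments` uses a 19-scan target cohort (4 follow-up
patients / 8 scans, 8 single-scan patients, 3 normal brains) on a 16³ grid,
a depth-3 / 4-filter U-Net, 8 pretrain-like phantoms, 30 epochs per
strategy and a 4-scan test set, with one patient-grouped fold held out for
the validation curve. The reportable quantities are directional: the median
over seeded replicates of mean-test-Dice(E) − mean-test-Dice(B), and the
gap between the initial validation losses of C and B (pre-training should
provide the better starting point). Absolute Dice values at this scale are
not comparable to GPU-scale results on clinical volumes and are not
claimed.

## Numerical notes

* Losses and metrics are computed in float64; network training in float32.
* DSC of two empty maps is defined as 1 (perfect agreement on emptiness);
  recall/precision use the analogous empty-set conventions.
* Evaluation binarizes probabilities at 0.5 by default (configurable).
* Finite-difference loss-gradient checks need a well-conditioned operating
  point: on an empty-truth image the loss is flat to within float64
  resolution when ΣP is large and ε tiny, so the checks use small grids
  with moderate ε.
* Z-score normalization is applied over the union-of-channels nonzero
  region, after resizing by default (the order is configurable); masks are
  resampled nearest-neighbor so they stay strictly binary.
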