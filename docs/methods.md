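# Methods

## Problem and model

The package classifies H&E-stained histopathology scene images of bile-duct
tissue as benign or malignant. The classifier (DCFCNN) fuses two
convolutional pathways applied to the same pre-processed RGB patch:

* **Spatial branch** — five residual stages RS_1..RS_5 with channel plan
  3→32→64→128→256→512. Each stage opens with a stride-2 projection block
  (two 3×3 convolutions; the shortcut is a 1×1 convolution with matching
  stride) followed by one shape-preserving block with an identity shortcut
  (two such blocks in RS_5). The projection shortcut is preferred over
  pooling so downsampling itself is learned.
* **Channel branch** — a multiscale stem (MSF) of four parallel
  convolutions (1×1, 3×3, 5×5, 7×7; 64 filters each; the three large
  kernels at stride 2 with same-dimension padding, the 1×1 path at stride 1
  followed by a 3×3/stride-2 max-pool) whose outputs are fused by
  element-wise sum, then a chain of multilevel blocks (MLF). An MLF is four
  sequential 1×1 convolutions; with *feature reuse* enabled the fourth
  convolution consumes the element-wise sum of the first three activations
  (re-using shallow channel features at zero extra convolution cost), and a
  trailing 3×3/stride-2 max-pool halves the resolution. The first MLF keeps
  64 channels; each later MLF doubles them.
* **Fusion and head** — with *k* MLFs the channel branch output matches the
  spatial branch exactly after stage RS_{k+1} (same H×W×C), where the two
  maps are summed; the fused map runs through the remaining stages, a
  3×3×1024 convolution, global average pooling and a 1024→2 fully connected
  classifier. Softmax probability of the malignant logit is the score.

All fusion nodes are element-wise sums, not concatenations: the published
layer table reports 64 channels out of the MSF (concatenation would give
256) and a 256-channel input to RS_5 at the branch-fusion point, and only
sum fusion reproduces the published parameter total.

### Bias/normalisation micro-layout

Batch normalisation follows every convolution (before the activation);
residual additions happen after the second BN and before the final ReLU.
The reference total of 20,949,378 trainable elements pins the remaining
free choices. A closed-form audit of the candidate layouts shows the total
is matched *exactly* when spatial-branch convolutions (including the
projection shortcuts) carry no bias — the standard residual-network
convention — while the channel-branch (MSF, MLF) and head convolutions do
carry biases (+256, +1,792 and +1,024 elements respectively over the
bias-free baseline of 20,946,306). The package implements exactly this
layout, and a unit-walking oracle in the test suite re-derives the count
from kernel arithmetic (k·k·C_in·C_out + biases + 2C per BN) independently
of the builder.

### Ablation variants

The ablation grid toggles the channel branch, the multiscale stem and
feature reuse. Variants without the MSF replace it with a single stride-1
1×1 convolution lifting RGB to 64 channels (the minimal-parameter stem) and
set the first spatial stride to 1 — without a downsampling stem the channel
branch runs one halving short, and the stride-1 spatial opening restores
alignment. Misaligned configurations fail fast with an error naming both
branch shapes.

## Preprocessing

Short-edge resize (bilinear) → center crop → scale to [0,1] → per-channel
standardisation. The long edge is *floor*-scaled: 2304×1728 at target 512
gives 682 (= ⌊2304·512/1728⌋), matching the reference shape table;
round-half-up would give 683. Crop offsets are ⌊(dim−size)/2⌋ with
half-open, 0-based intervals. No padding is ever applied: a crop larger
than the image is an error. Four resize/crop strategies are built in
(256-224, 384-336, 512-448, 640-560); 512-448 is the default, consistent
with the reference layer table, with 384-336 available by configuration.
Channel statistics default to "computed from the training split" (the
estimator recomputes them per fold); explicit constants may be supplied.

## Training protocol

Plain SGD — learning rate 0.001, momentum 0.9, weight decay 1e-6, batch
size 16, 200 epochs (defaults; tests and the acceptance script use 15
epochs on small synthetic tasks) — minimising cross-entropy over the two
logits. No augmentation, no schedule, no early stopping. Scenes are split
by stratified five-fold cross-validation; a patient-grouped mode is
provided for leakage-safe splits but is off by default because the
reference per-fold benign counts are only achievable by splitting at scene
level. Per fold, the checkpoint with the highest overall training-set
accuracy is selected, earliest epoch on ties.

The selection accuracy is computed by a full-training-set forward pass
using batch statistics with running statistics frozen. This makes the
recorded history a pure function of the weights: a zero learning rate
provably yields a constant history, and the record does not depend on the
per-epoch shuffle. Test-set prediction uses evaluation mode (running
statistics). Per-epoch shuffling is reseeded deterministically from
(seed, fold, epoch); the incomplete final batch is kept.

The whole network stack (im2col/GEMM convolutions, batch normalisation,
max-pooling, explicit backpropagation, SGD) is implemented in NumPy in
`dcfcnn.nn`; every analytic gradient is validated against central finite
differences in the test suite. Forward/backward passes are bit-reproducible
for a fixed seed on a fixed BLAS.

## Metrics

Malignant is the positive class: SN = TP/(TP+FN), SP = TN/(TN+FP),
accuracy from the pooled confusion counts, macro F1 as the unweighted mean
of per-class F1, AUC as the trapezoidal area under the ROC of the malignant
score (identical to the Mann–Whitney statistic with ties counted ½ — the
test suite asserts the two routes agree to 1e-12). Single-class folds
report AUC (and the undefined one of SN/SP) as `None` with a warning rather
than zero. Because the source tables do not state the aggregation rule,
both the unweighted mean of per-fold metrics (the headline) and pooled
metrics over concatenated predictions are reported. Percentages are
rendered to 2 decimals, AUC to 3.

## Synthetic data

The generator emulates the study collection's composition — 690
partial-cancer scenes from 125 patients, 48 full-cancer from 14, 142
cancer-free from 35 (880 scenes; labels merge to 738 malignant / 142
benign) — with patients private to their category and assigned round-robin.
Images are eosin-pink multi-octave value-noise backgrounds overlaid with
anti-aliased hematoxylin-purple elliptical blobs. Categories differ in blob
coverage (≈1–4% / 20–55% / 90–96% of the canvas), cluster spread and
opacity; a `separability` knob in [0,1] linearly interpolates all blob
parameters between a common midpoint (0: categories identically
distributed) and the full category profiles (1: a one-feature
mean-green-intensity threshold already separates the classes with AUC ≈ 1).
Default separability is 1.0: the emulator's role is to give the pipeline a
cleanly learnable signal, not to calibrate difficulty. Each scene draws
from a stream derived from (seed, scene id), so content is independent of
generation order and regeneration is byte-identical.

The default canvas is 576×432 (a quarter of the source material's
2304×1728) to keep generation desk-fast; tests use 32–96 px canvases.

**What passing tests show — and don't.** The synthetic task exercises
shapes, gradients, determinism, the protocol and the metric pipeline, and
shows the network can fit a separable texture/colour contrast. It does not
emulate nuclear morphology, stain variability or the hard inter-class
ambiguity of real histopathology, so synthetic accuracies say nothing about
clinical performance, and the published headline accuracies are not
reproduction targets here.

## Problem sizes

Desk-scale defaults were chosen so the full suite runs on one CPU: the
learning-direction check trains on 40 scenes (20 benign / 20 malignant, a
30/10 stratified split) at 64×64 for 15 epochs with the published SGD
recipe, comparing the full model against the spatial-only ablation over
five seeds; structural checks (parameter total, shape table, dataset
accounting, resize arithmetic) are exact and instant.

## Known limitations

* NumPy training is CPU-bound; the defaults (448×448, 200 epochs) are
  faithful but impractical at that scale — use small crops/epochs for
  experimentation.
* Best-*training*-accuracy model selection follows the reference protocol
  but risks selecting overfitted weights; a validation-based mode is the
  obvious extension.
* Scene-level splitting can place one patient's scenes in both train and
  test folds; use `grouping="patient"` for leakage-safe evaluation.
* Batch-normalisation running statistics converge slowly in very short
  runs; evaluation-mode predictions after a handful of epochs lag the
  training-mode state.
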