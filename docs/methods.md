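# Methods

## Model

The package classifies groups of images that share one (possibly
unknown) class label. A shared CNN trunk feeds two branches:

* **General branch** — per image: last-stage feature map → global average
  pooling → dropout (rate 0.5 by default; the embedding, not the feature
  map, is dropped) → shared FC → softmax.
* **Improving branch** — per group: feature-space localization (EFLM) →
  global average pooling of the last localized block → gated attention
  fusion (AFFM) → the *same* FC → softmax → soft voting.

Both branches contribute a mean cross-entropy; the total loss is their
sum and every parameter, including the trunk, receives gradient from
both.

### Localization (EFLM)

For each block of the last convolutional stage the channel-summed
activation map A is thresholded at λ·Ā with *strict* inequality — ties
drop to zero, which matters at λ = 1 where a constant map loses every
position. The per-block masks are intersected; the minimal bounding box
(0-based, half-open) of the surviving positions is cropped from every
block and resized back to (h, w) by corner-anchored bilinear
interpolation, chosen so that a full-map crop is exactly the identity.
An empty intersection falls back to the whole-map box, so localization
never discards an image. λ is scheduled Epoch/(Epochs−1) during training
and validation (with λ ≡ 1 when Epochs = 1, the schedule's endpoint) and
fixed at 0.5 at test time. The interpolation is expressed as two
matrix contractions, so gradients flow through the crop into the trunk
while the mask/box decisions themselves are discrete and detached.

### Fusion (AFFM)

Within one group of n embeddings (rows of X ∈ ℝ^{n×d}), each of h heads
projects X to queries, keys and values of width d/h (d_k = d_v = d, and
the score scale is √d_k). Queries and keys are filtered by sigmoid gate
masks computed from a joint linear map of Q and K (two parallel FC
layers, one per mask — the parameter shapes only support the parallel
reading). After the row softmax, scores below the probability threshold
p = 1/(2·N_t) are zeroed by a hard selection mask with **no
renormalization**, and no gradient flows through the comparison. The
selection mask is computed from the same score matrix it masks (one
pass). Head outputs are concatenated, batch-normalized and added
residually to X. Defaults: h = 4 heads (the head count is a free
parameter of the architecture), one AFFM layer, no positional encoding —
group members are unordered, and the layer is permutation-equivariant
over them.

### Batch normalization placement

One training step processes a *batch* of 16 anchor groups (16 × N_t = 80
rows). Attention is strictly within-group, but the fusion BN normalizes
over all rows of the batch. This is deliberate and load-bearing: a
training group is single-class, so normalizing each group by its own
statistics makes the BN mean carry the class signal and lets the
variance collapse once attention has mixed the rows (the normalized
output then amplifies noise into the residual). Normalizing over the
mixed-class batch is the standard BN regime, and the running statistics
it accumulates are consistent at inference, where groups arrive one at a
time and the running estimates are used (also for n = 1 groups, whose
batch statistics are degenerate). Measured on the synthetic study
conditions, per-group normalization inverts the architecture's expected
ordering (group accuracy 0.15–0.27 vs single-image 0.54), while batch
normalization restores it (0.55 vs 0.22).

### Voting, losses, metrics

Soft voting averages the group's probability rows and takes the argmax
(lowest index on ties). Hard voting — kept as an ablation baseline —
takes the modal per-image label and defers ties to the soft vote.
Branch losses are per-image cross-entropies reduced by the mean, making
gradients invariant to group size; probabilities at the true class are
clamped at 1e-12 with a logged warning. Metrics are overall accuracy and
support-weighted one-vs-rest F1 from an explicit confusion matrix;
0/0 ratios report as 0 and zero-support classes carry no weight.

## Training protocol

SGD with momentum 0.9 and weight decay 1e-4; learning rate 1e-3,
multiplied once by 0.1 after 10 epochs (i.e. from the 11th epoch of a
20-epoch run). Each epoch visits every training image once as an anchor;
the anchor draws N_t − 1 = 4 more images from its own class, uniformly
without replacement when the class is large enough, with replacement
otherwise. Sampling, dropout and weight initialization all derive from
one seed, and the run log records the configuration hash and every
ablation switch. Validation shares the training λ of the current epoch
(exposed as a config knob via `eflm.test_lambda` for the test phase
only).

At test time the general branch scores single images; the improving
branch groups test images *by their true label* — an oracle grouping
that mirrors the evaluation protocol of same-category fusion — chunks
each class into groups of `n_test`, padding the last chunk by resampling
(with a warning when a class is smaller than `n_test`), and scores one
soft-vote decision per group. Group-level accuracy is what the reports
state. The deployment path (`pestfusion predict`) never sees labels: the
caller supplies the group.

## Synthetic data

The generator emulates the failure modes of field-collected pest photos
at desk scale. Each class is a textured blob — shape from
{ellipse, rectangle, cross, ring, triangle} with a class-specific color
and sinusoidal texture frequency — planted at a random position and size
(between ¼ and ½ of the image side) on a background cluttered with
random distractor rectangles and Gaussian pixel noise. Independent
Bernoulli draws make a fraction of images target-absent (background
only; the recorded box is empty), a fraction label-corrupted (assigned a
different class; ground truth records both labels), and a fraction
Gaussian-blurred (σ = 1.2 px). The split takes the first 70% of each
class for training. Generation is byte-reproducible from (spec, seed).

The default study conditions used by the tests and the acceptance
script: 5 classes × 58 images (200 training, 90 test), 64×64 px, 10%
label errors, 10% target-absent, 10% blur, 5 training epochs, three
seeds. What passing at these conditions shows is qualitative: the loss
decreases, fusing 5 same-class images beats single-image
classification, and removing the attention fusion costs more than
removing localization — the orderings, not the absolute accuracies, are
the reproducible content. What it does not show: behavior on real pest
photos (no photorealism, no class taxonomy, no scale/pose variation),
nor absolute accuracy at production scale, which requires a pretrained
deep backbone and full-size datasets.

Feature-space fixtures (`generate_feature_stack_fixture`) plant a hot
rectangle directly in a 3-block feature stack and return the
analytically expected mask and box. The recovery property is measured
at contrast 20:1 (hot 10, background 0.5) with per-channel noise at 5%
of the hot value and targets 3–5 cells wide on an 8×8 map — the target
size the image generator induces at feature scale. Targets of only 2
cells at that noise level begin to lose the box to background positions
that survive the 3-block intersection; localization of near-point
targets under maximal noise is a known limitation of mean-threshold
masking.

## Reference backbone

A deliberately small 3-stage CNN (stride-2 3×3 stem and two stride-2
stages, then three stride-1 3×3 blocks at 32 channels with ReLU) stands
behind the adapter contract (`list_stage_blocks()`,
`forward_with_hooks()`). Its last stage has exactly three same-size
blocks so the three-way mask intersection is exercised, and its hooks
are post-ReLU so activation maps are nonnegative. Any backbone exposing
the same two methods can be substituted. Default image side is 224 in
principle; all desk-scale work uses 64 (feature maps 8×8, embedding
dimension 32).

## Numerical choices

* Autodiff: reverse-mode over float64 numpy arrays; convolution via
  im2col with an explicit col2im backward; softmax and log-softmax are
  max-shifted; BN ε = 1e-5, running-stat momentum 0.1 (unbiased variance
  in the running estimate, biased in the normalization, the usual
  convention).
* Weight init: He-uniform for convolutions, Glorot-uniform for linear
  maps and attention projections; zero biases; all from one
  `numpy.random.Generator` seeded per run.
* Ties: threshold masks drop ties (strict >); soft-vote and hard-vote
  ties resolve to the lowest class index after the soft-vote deferral.
* Degenerate inputs: empty masks fall back to the whole map; n = 1
  groups skip group statistics and use running BN estimates; classes
  smaller than N_t sample with replacement; a non-finite loss aborts
  training with a diagnostic rather than continuing.

## Known limitations

* The improving branch's evaluation grouping assumes same-class groups;
  grouping by predicted label instead would compound single-image errors
  and is not implemented.
* One box per image: multi-instance images are localized to a single
  region (by design, matching the one-box architecture).
* The desk-scale backbone saturates around 60–90% on the synthetic task
  in 5 epochs; absolute numbers move with the seed, which is why every
  qualitative claim is asserted over three seeds.
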