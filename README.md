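# pestfusion

Multi-image fine-grained pest recognition for field-collected photos.

Crop-pest images taken in the field are hard to classify one at a time:
the insect is a small target on a cluttered background, shots are often
blurred or low-resolution, some frames contain no pest at all, and a
fraction of labels are simply wrong. `pestfusion` implements a two-branch
architecture that attacks these problems by classifying *groups* of
same-class images instead of single frames:

* **EFLM** (effective feature localization) finds the target in feature
  space: the last-stage CNN feature maps are summed over channels into an
  activation map **A**, thresholded at λ·Ā (strict inequality, where Ā is
  the spatial mean), the per-block binary masks are intersected, and the
  minimal bounding box of the surviving positions is cropped and
  bilinearly upsampled back to (h, w). λ ramps linearly 0 → 1 over the
  training epochs (λ = Epoch/(Epochs−1)) and is fixed at 0.5 at test
  time; an empty intersection falls back to the whole map.
* **AFFM** (adaptive filtering fusion) fuses the group's embedding matrix
  X ∈ ℝ^{n×d} with multi-head self-attention whose information flow is
  filtered twice: learned sigmoid *gate masks* M_Q, M_K damp query/key
  features, and a hard *selection mask* zeroes any post-softmax attention
  score below p = 1/(2·N_t), with no renormalization. Head outputs are
  concatenated, batch-normalized, and added residually to X.
* **Soft voting** averages the group's class-probability rows and takes
  the argmax, one decision per group.
* A **general branch** (backbone → pooled embedding → dropout → shared
  FC) and the **improving branch** (EFLM → pool → AFFM → shared FC → SV)
  are trained jointly with L_total = L_general + L_improving, both plain
  cross-entropies through one shared classifier.

Everything — including a compact reverse-mode autodiff engine, the
reference 3-stage CNN backbone, SGD with the momentum/decay schedule, and
a synthetic-data generator that reproduces the field pathologies (clutter,
label errors, target-absent frames, blur) — runs on numpy at desk scale;
no GPU, downloads, or pretrained weights.

## Worked example

```sh
# a 5-class synthetic dataset with 10% label errors, 10% no-target
# frames and 10% blurred images (spec.yaml fields: n_classes,
# images_per_class, label_error_rate, no_target_rate, blur_rate, seed)
pestfusion synth --out-dir data --seed 11

# train both branches for 5 epochs (defaults mirror the reference
# protocol: SGD momentum 0.9, weight decay 1e-4, lr 1e-3, groups of
# N_t = 5 around 16 anchors per step)
pestfusion train --manifest data/manifest.csv --checkpoint model.npz \
    --seed 1 --set optim.epochs=5

# single-image accuracy vs 5-image fused group accuracy
pestfusion evaluate --checkpoint model.npz --manifest data/manifest.csv \
    --mode general --seed 1
pestfusion evaluate --checkpoint model.npz --manifest data/manifest.csv \
    --mode improving --n-test 5 --seed 1
```

On this dataset (seed 1) the general branch reaches `"accuracy": 0.233`
per image while the improving branch reaches `"accuracy": 0.55` per
5-image group — fusing and voting over several images of the same class
absorbs the per-image failures (wrong labels, empty frames, blur) that
cap single-image accuracy. The evaluate commands print a JSON
`MetricsReport` with overall accuracy, support-weighted F1 and per-class
precision/recall/F1.

```sh
# classify one group of images of the same (unknown) class
pestfusion predict --checkpoint model.npz img1.png img2.png img3.png
```

prints the soft-vote decision, its top-5 averaged probabilities and the
per-image localization boxes in feature coordinates.

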