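# Methods

`tilscope` implements a three-stage pipeline for quantifying
tumor-infiltrating lymphocytes (TILs) in H&E-stained lung-adenocarcinoma
sections, plus the statistics used to compare its counts with pathologist
counts. This note records the models, the parameters that matter, the
numerical choices, and what the synthetic test bed does and does not show.

## Stage 1 — deterministic tissue contour

A thumbnail at 2.5x-objective-equivalent resolution (downsample factor =
scan magnification / 2.5, area averaging) is processed through two parallel
channels that are intersected:

* **Edge channel.** Grayscale (ITU-R 601 luma) → Roberts cross gradient
  magnitude (L2 of the two 2x2 diagonal differences; the paper-style
  operator does not fix L1 vs L2, we use L2) → Otsu binarisation over the
  256-bin histogram → morphological closing, three iterations of dilation
  followed by three of erosion with the 3x3 disc. At that size the discrete
  disc is the 5-pixel cross. Iterated dilation-then-erosion is used because
  a literal "closing applied three times" is a no-op after the first pass
  (closing is idempotent); the iterated form is what imaging libraries mean
  by `iterations=3` and actually bridges wider gaps. The closing is
  computed on a zero-padded canvas so it realises the extensive closing of
  the infinite grid (no border clipping).
* **Colour channel.** HSV gate H ∈ [18, 180] on the 0–180 half-degree hue
  scale, S ∈ [9, 255], V ∈ [0, 255] — the range implies the half-degree
  convention, which we adopt throughout — followed by a radius-4 (9x9)
  median filter. White glass fails the gate through saturation (S of white
  is 0); pure red hues fail through H < 18.

The AND of the two channels is the tissue mask. Outer contours of its
connected components (holes filled per component) are exported as polygons
in source coordinates. Small-fragment suppression (`min_area`) exists but
is off by default: scattered small tissue fragments are kept deliberately.

## Stage 2 — nested-U tumor-parenchyma segmentation

The segmenter is the small nested-U configuration: six encoder stages and
five decoder stages of residual U-blocks (RSU-7/6/5/4 plus two
dilation-only RSU-4F blocks), each block a little U-net with an input
residual, mixing standard and dilated 3x3 convolutions
(conv + batch norm + ReLU). Each decoder stage emits a side map; the six
side logits are fused by a 1x1 convolution into the final sigmoid map.
With the default widths (mid 16, out 64 channels) the model counts
**1,131,181 trainable parameters ≈ 1.13 M**, which the test suite pins as
an architectural invariant.

The attention-guided fusion of the side maps is implemented as a
parameter-free gate: side logits are reweighted by a softmax over their
global mean sigmoid activations (scaled to mean weight 1) before the
fusion convolution. It is a flag (default on) and adds no parameters, so
the budget above is unchanged.

Because no deep-learning framework is a dependency, the network runs on a
compact reverse-mode autodiff core (`tilscope.nn`) written on numpy:
broadcasted arithmetic, conv2d with stride/dilation, 2x2 ceil-mode max
pooling, nearest-neighbour resampling, batch norm, gather/concat, SGD and
AdamW, and a closed-form cosine schedule. All gradients are verified
against central finite differences in the test suite (1e-4 relative on the
composite loss).

**Loss.** `L_total = α·L_WBCE + β·L_Dice` with weighted binary
cross-entropy (positive-class weight `w`) and a Dice loss smoothed by
ε = 1e-6 in numerator and denominator. α, β and w are not pinned by any
published value; defaults are α = β = 1, w = 1, all configurable.
Probabilities are clipped to [1e-7, 1 − 1e-7] before logs. Deep
supervision: the side-output losses are averaged and added with weight
0.25 (configurable). Equal weighting measurably degrades desk-scale
training because the coarse sides (down to 1/32 resolution) cannot resolve
boundaries and drag the fused map toward blur; 0.25 keeps their
regularising effect without that cost.

**Training.** AdamW (β₁ = 0.9, β₂ = 0.999, ε = 1e-8), initial lr 1e-4,
cosine annealing with T_max = 50, batch 16, 640-px patches, up to 300
epochs with early stopping on validation Dice (patience 20, F1 as
tie-break); the best-Dice checkpoint is restored. These are the config
defaults; the desk-scale protocol below trains a narrow variant with
adapted sizes.

**Inference.** Images are resampled to 5x-objective-equivalent resolution
(2.0 µm/px; when only the nominal power is known we use mpp ≈ 10 /
magnification), tiled (default 640 px, 64 px overlap) with probabilities
averaged on overlaps, thresholded at 0.5, and mapped back to source
resolution by nearest-neighbour. Tiled and whole-image inference agree to
< 1e-5 when the image fits one tile (tested).

## Stage 3 — single-stage lymphocyte detection

A compact anchor-based detector: a small strided-conv backbone, a feature
pyramid with top-down and bottom-up (PAN-style) aggregation, and decoupled
heads (classification branch separate from the regression branch, with
objectness off the regression branch) at strides 8/16/32 (P3–P5). The
backbone is deliberately compact — the full E-ELAN topology is out of
scope — while the loss composition, multi-scale heads and post-processing
follow the standard single-stage recipe.

* **Anchors.** Three per scale, sized to lymphocyte diameters 6–12 µm over
  the magnifications the detector targets (0.25–1.0 µm/px): 8–16 px at P3,
  20–38 px at P4. P5 priors (84–136 px) cover only large aggregates, so
  isolated cells never assign there and the coarse head learns silence;
  with cell-sized P5 priors it receives contradictory supervision on its
  4x4 grid and sprays false positives.
* **Assignment.** A ground-truth box assigns to every anchor whose width
  and height ratios lie within [1/4, 4] at the grid cell containing its
  center (half-open convention); a box matching no anchor falls back to
  the single best-ratio anchor, so every in-frame object gets at least one.
  During training the two side cells nearest the sub-cell offset are added
  as positives with the same box target.
* **Decode.** Bounded YOLO-style decode: center offset (2σ(t) − 0.5) cells
  (range −0.5..1.5, so neighbour cells can regress onto the object, and
  duplicates merge in NMS instead of surviving as badly localised
  near-misses), size anchor·(2σ(t))² clamped to ≥ 0.5 px.
* **Loss.** BCE for classification, BCE for objectness, CIoU for box
  regression: `L_CIoU = 1 − IoU + ρ²(b, b_gt)/c² + αv` with
  v = (4/π²)(arctan(w_g/h_g) − arctan(w/h))² and the standard completion
  α = v/((1 − IoU) + v), treated as a constant in the backward pass. The
  objectness BCE weights the rare positive anchors up (default 32x); the
  box term gets weight 5 (cls/obj weight 1) — localisation of 10–20 px
  objects is the precision bottleneck and benefits from the stronger
  gradient. All weights are configurable.
* **Training.** SGD, lr 1e-2, weight decay 5e-4, momentum 0.937 (the
  conventional value for this detector family; not pinned by a published
  number), cosine annealing, up to 250 epochs, 640-px inputs, batch 8 by
  default; the best validation-F1 checkpoint is restored.
* **Post-processing.** Confidence threshold 0.25, greedy NMS at IoU 0.45
  (both configurable), applied globally after de-tiling; stromal gating
  (box center must lie on a stroma pixel) is applied after NMS.

## Stage 4 — TILs quantification and agreement

Stroma = tissue ∧ ¬parenchyma. Counts are taken in `n_fields` (default 5)
square windows of one high-power-field area — default 0.237 mm², the
standard FN22 eyepiece field at 400x; the field area is nowhere pinned by
a published value and is configurable — centered on seeded random stromal
pixels. A detection is counted when its center lies in the window
(boundaries inclusive) and on stroma. A hotspot mode (top-count candidate
windows) is available behind a flag; random placement is the default.

Per-HPF counts grade as low / moderate / high at <100 / 100–300 / >300
cells per HPF; both 100 and 300 belong to "moderate".

Agreement battery on an n_subjects x k_raters count matrix:

* **ICC(A,1)** — single-measures, two-way random effects, absolute
  agreement, from the ANOVA mean squares; 95% CI by the F-distribution
  method (McGraw & Wong). Single measures is chosen because raters are
  compared individually. Verified against `pingouin` to 1e-9.
* **Cohen's κ** per rater pair and **Fleiss' κ** overall on the grades,
  with seeded bootstrap percentile CIs (2,000 resamples by default; the CI
  method for κ is a package choice). Point estimates verified against
  `statsmodels`. Degenerate tables (both raters constant and identical)
  report κ = 1 with a flag.
* **Bland–Altman** per pair: bias = mean(a−b), limits of agreement
  bias ± 1.96·SD (sample SD, n−1).

Strength labels follow Cicchetti (1994) for ICC (≥0.75 excellent) and
Landis & Koch (1977) for κ (0.41–0.60 moderate, ≥0.81 almost perfect).

## Synthetic scenes

`synthetic_histology.generate_scene` renders seeded scenes with exact
truth: a flat near-white glass background (one level in 245–255 with faint
sensor noise), star-convex pink stroma blobs whose union is rescaled to a
target tissue fraction of the frame, darker-purple parenchyma blobs
rescaled to the target tumor fraction of tissue, and dark blue-violet
lymphocyte discs (diameter drawn 6–10 µm, converted by mpp) whose count is
Poisson(density x stromal area) with centers uniform over stroma. Stain
colours sit inside the HSV tissue gate; tissue texture (Gaussian, SD 26 in
stroma and 31 in parenchyma, on 8-bit channels) is strong relative to the
flat glass so that the Roberts/Otsu edge channel separates tissue from
background the way stained tissue separates from glass at thumbnail scale.
A `stain_fade` control blends the stains toward white for faded-section
scenarios.

What the scenes do **not** emulate: nucleus-level chromatin texture,
stain-vector variation between laboratories, folds, pen marks, blur,
tertiary lymphoid structures, or cell overlap/crowding beyond what random
placement produces. Passing the recovery checks below therefore shows the
pipeline's machinery is correct and trainable, not that the trained
weights transfer to real slides.

The preprocessing recipe around the scenes: Gaussian/median denoising;
flip / 90°-rotation / crop (area fraction uniform in 0.85–1.00, resized
back) / HSV jitter augmentation applied identically to image, masks
(nearest-neighbour so they stay binary) and points (transformed
analytically, dropped only by crop exclusion); hue jitter is ±10% of the
full hue circle and saturation/value are multiplicative factors in
[0.85, 1.15] / [0.90, 1.10] — the reference scales are a package decision,
configurable. Slide-level 70/15/15 splitting rounds the validation and
test sizes (at least 1 each) and gives the remainder to training.
Mask-guided nearest-neighbour inpainting of missing regions is exposed but
not used by default.

## Desk-scale evaluation protocols

`tilscope.protocols` fixes the problem sizes used by the test suite and
`scripts/acceptance.py`; they are chosen so the whole battery runs on one
CPU in a few minutes while keeping every architectural and algorithmic
element of the full-scale recipe:

* tissue stage: 50 scenes of 128x128 at 2.5x; Dice vs truth.
* segmenter: narrow nested-U (mid 4, out 8), 12 training scenes of 64x64
  at 2 µm/px, lr 3e-3 (a small-model/small-data choice; the full-scale
  default stays 1e-4), 60 epochs; Dice on 4 held-out scenes.
* detector: base width 8, 22 scenes of 128x128 at 0.5 µm/px with sparse
  cells (2000/mm² of stroma, ~2–4 per scene), 200 epochs; recall and
  precision at IoU 0.5 on 8 held-out scenes.
* ICC recovery: five independent panels of 200 subjects x 2 raters with
  σ_subject = 20, σ_rater = 10 (true ratio 0.8); the mean estimate is
  compared to the truth, averaging over panels so the check reflects the
  estimator rather than one panel's sampling noise.
* Fleiss null: 500 subjects x 3 raters rating independently and uniformly.

## Numerical choices and degenerate inputs

* Otsu ties break toward the smallest threshold; constant images raise.
* Dice coefficient of two empty masks is 1.0 (agreement that nothing is
  present), flagged where reported.
* Undefined ratios (precision with no positive calls, etc.) are reported
  as None with an `undefined` flag, never silently 0.
* AP uses all-point interpolation (area under the precision envelope);
  AP with no ground truth is 1.0 without detections, 0.0 with.
* NMS sorts by confidence with ties broken by earlier index; it is
  idempotent and verified against an O(n²) reference.
* All randomness flows from explicit seeds through per-purpose
  `SeedSequence` streams; re-running any stage with the same inputs and
  seed is byte-identical (single-threaded).

## Known limitations

* Accuracy numbers from the original clinical setting (TCGA and hospital
  cohorts, expert annotations, trained weights) are not reproducible here;
  the synthetic recovery checks are deliberately easier than real H&E.
* The numpy autodiff core is single-threaded and desk-scale; training the
  full-width models at 640-px patches is out of its intended range.
* The detector's compact backbone trades capacity for CPU trainability;
  on crowded scenes (>1500 cells/mm² at low magnification) its precision
  degrades before its recall does.
* QuPath GeoJSON import follows current QuPath practice
  (`properties.classification.name`); other dialects map through the same
  module but are not round-trip tested against QuPath itself.
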