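# Methods

This note documents the models implemented in `histotools`, the choices
made where the design was genuinely open, what the synthetic data generator
does and does not emulate, and the numerical conventions that matter when
reproducing results.

## Segmentation

### Architecture

DRAN is an encoder–decoder for binary per-pixel prediction (nucleus blob or
nucleus border vs. background; the two tasks are trained as separate
two-class networks, `n_classes = 2`).

*Contracting path.* A pre-activated 50-layer bottleneck residual encoder
(batch-norm → ReLU → convolution layout), modified in two ways: the 7×7 stem
convolves with stride 1 and **no padding**, and the max pooling after the
stem is removed. Stage strides are 1/2/2/2 with output channels
256/512/1024/2048, so a 102×102 input produces stage sides 96/96/48/24/12.

*Expanding path.* All decoder convolutions are valid (no padding), stride 1.
The path is: 2×2 stride-2 transpose convolution 2048→1024 (12→24); addition
merge with the stage-3 skip; decoder3; nearest-neighbor ×2; merge with the
center-cropped stage-2 skip; decoder2; nearest ×2; merge with the cropped
stage-1 skip; decoder1; 1×1 convolution and softmax. Decoder blocks are
5×5 → grouped 3×3 → 1×1 with channel plans (1024, C=256, 512),
(512, C=128, 256) and (256, C=64, 128); each valid decoder shrinks the
spatial side by exactly 6 (4 from the 5×5, 2 from the 3×3). Every grouped
convolution keeps 4 channels per group, the invariant a `width_divisor`
preserves when building reduced desk-scale variants.

Open points resolved here:

* **Skip-size mismatch.** Valid convolutions make skip tensors larger than
  the expanding tensors they merge with (96 vs 60, 48 vs 36). Merges
  center-crop the larger operand; this is the unique choice under which
  102 → 54 holds, which the shape oracle (`dran_output_side`) and the
  forward pass verify against each other.
* **Transpose convolution.** "Transpose convolution and up-sampling" is
  realized as a single 2×2 stride-2 transpose convolution: it doubles 12→24
  exactly and matches the stage-3 channel count.
* **Decoder batch-norm placement.** Each decoder convolution is followed by
  batch-norm and ReLU; the layout within the block is not otherwise pinned
  by the architecture's published summary.

MDRAN resizes the input by ×0.5 and ×2 (nearest neighbor), runs a DRAN per
scale, removes the per-branch softmax heads, resizes each branch's
128-channel decoder1 output to the ×1 output grid and **sums** them —
addition rather than concatenation is forced by the aggregation decoder's
128-channel input. decoder4 mirrors the decoder layout (5×5 128→256,
grouped 3×3 C=64, 1×1 → classes) but uses *same* padding, so the output
grid equals the ×1 branch's (54×54 for a 102×102 input). Odd intermediate
sides in the ×0.5/×2 branches are handled by the same dynamic
crop-to-smaller merge rule; branch outputs of any side are resized to the
×1 grid before fusion.

### Training

Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8), batch size 32, L2 penalty factor
1e-5 (reported losses include the penalty; with factor 0 the loss is
exactly the data loss). He-normal initialization everywhere; pre-trained
encoder weights can be injected via `load_state_dict` but are not required.

* DRAN, phase 1 (35 epochs): contracting path frozen; learning rate 1e-4,
  then 5e-5 / 1e-5 / 7.5e-6 at epochs 1 / 15 / 25.
* DRAN, phase 2 (40 epochs): everything trainable. The phase-2 rate is not
  pinned by the published schedule; the default continues at 5e-6, the rate
  phase 1 ends on.
* MDRAN: 10 epochs decoder4-only at 1e-4, then 35 epochs that also train
  the branch expanding paths at 1e-4 / 1e-5 / 1e-6 (epochs 0 / 15 / 30);
  contracting paths stay frozen throughout.

Freezing a subtree pins both its weights and its batch-norm running
statistics, so a frozen branch is bit-identical after a phase — this is
tested. The weighted segmentation loss is the mean over pixels of
`w(t, ĉ) · (−ln p_t)` with `w` = 5.0 for a correctly predicted border
pixel, 6.0 for a border pixel predicted background, 1.0 for background, 4.0
for background predicted border (used for the border task; the blob task
uses uniform weights). The predicted class `ĉ` is the argmax with ties
resolved to the border/foreground class, consistent with the pipeline's
inclusive ≥ 0.5 thresholding; `p_t` is clamped at 1e-7. The weights
multiply the loss but are constants in the gradient (one reading of
"miss-classification gains a weight"; the rule is isolated in one function).

### Training-patch datasets

From 200×200 annotated patches: **NBL** — window-slide crops at a 54 px
step plus 30 uniform random crops per tile; **NBD** — one patch per nucleus
centered on its centroid, skipping nuclei whose floored centroid is within
100 px (half a patch) of a tile edge so the patch fits without padding;
**SN** — NBL patches whose centered 54×54 window holds ≤ 50 % nuclear
pixels (inclusive), duplicated 3 times, used only for blob training.
Augmentation: shift ±5 % of the side, rotation ±45°, per-axis flips with
probability 0.5, shear ±0.4π, resize ratio 0.6–2.0, three repeats per
patch; targets are warped with nearest-neighbor so they stay binary, and
out-of-support samples are filled by reflection (the 200×200 context exists
precisely so the eventual 102×102 center crop avoids zero padding). The
border ground truth is the 1 px inter-id/background boundary thickened
inward to 2 px — the thickness is not pinned by the published description;
2 px keeps the class learnable while the 3×3 inference dilation stays
meaningful.

### Inference and separation

Tiles are reflection-padded by 24 px (= (102−54)/2) and covered by 102×102
windows at stride 54, whose 54×54 outputs tile the image exactly.
Probabilities are thresholded inclusively at 0.5. Separation: dilate the
border mask once with a 3×3 square ("kernel of size 3×3" read literally),
subtract from the blob mask, label the 8-connected cores, and grow them
back over the blob support with a marker-controlled watershed on the
negative Euclidean distance transform. The watershed *is* the
"assign each removed boundary pixel to its closest core" step, with
geodesic distances so labels cannot leak across background; an independent
brute-force Euclidean nearest-core assigner is kept as a test oracle for
simply-connected supports. A blob component whose core is entirely consumed
by the dilated border falls back to being its own marker, so detections are
never silently deleted. Finally the area filter removes objects smaller
than 13 μm²: the published phrasing ("eliminate artifacts (>13 μm²)") is
grammatically ambiguous, but since nuclei exceed 13 μm² and the step
removes artifacts, objects **below** the threshold are removed and objects
exactly at it survive. At 0.25 μm/px the pixel threshold is 208, at
0.5 μm/px it is 52.

## Classification

Patches are 256×256 RGB at 20×. Reinhard stain normalization maps each
image's per-channel mean/std in the Ruderman lαβ space (log-LMS basis;
constants frozen in code and unit-tested against a hand-computed pixel)
onto a designated target image's statistics; zero-variance channels are
ε-guarded. Training augmentation is a random 224×224 crop, per-axis flips
and a random 90° rotation; inference uses the deterministic center crop.

ResNet32 is a bottleneck residual network with a 3×3 stem (stride 2,
followed by 3×3/2 max pooling) and stage plan (2, 3, 3, 2):
1 stem + 10 units × 3 convolutions + 1 classifier = 32 weighted layers
(projection shortcuts are excluded from the count, the usual depth-naming
convention). The plan is a configuration key so alternatives summing to 10
units can be compared; (2, 3, 3, 2) preserves the 50-layer network's stage
structure. The optimizer is not pinned by the published description;
default Adam 1e-4, batch 32, matching the segmentation half. The selected
epoch is the one with the greatest validation accuracy, ties to the
earliest. After each epoch the batch-norm running statistics are
re-estimated over the training data (cumulative average of batch
statistics): with small batches and a deep network the running estimates
otherwise lag the co-adapted batch statistics enough to distort eval-mode
accuracy.

## Slide aggregation

Per-patch probability vectors (ND, LUAD, LUSC) are placed at their (row,
col) grid cells; missing cells become pure ND; duplicates are an error.
The 50-feature manifest (the published description lists categories, not a
manifest; this is a declared reconstruction with stable names): per map
m ∈ {LUAD, LUSC} — mean, median, variance (6); positive-cell count and
fraction at τ = 0.5 (4); top-5 8-connected component sizes (cells,
descending, zero-padded) at τ ∈ {0.5, 0.7, 0.9} (30); plus LUAD:LUSC
ratios with ε = 1e-6 — mean, median, variance, total mass (4),
positive-count ratios (3) and largest-component ratios (3) at the three
thresholds. "Class separability" for the top-25 selection is the Fisher
score (μ₁−μ₂)²/(σ₁²+σ₂²+ε), deterministic with ties in manifest order.

Max voting counts argmax-positive cells for LUAD vs LUSC; ties fall through
to the larger summed probability mass, then LUAD. The random forest is a
10-tree bagged regression (scikit-learn), ⌈p/3⌉ candidate variables per
split, minimum leaf size 5, labels encoded LUAD = 0 / LUSC = 1, prediction
the mean of tree outputs, binarized at a configurable threshold
(default 0.5, LUSC inclusive; the published method selected a threshold
without stating it).

## Synthetic data

The fixture generator emulates the two data regimes every test runs on:

* **Tiles** — filled ellipses (radius 5–12 px, eccentricity 0.6–1, random
  orientation) with hematoxylin-like dark-purple fill on an eosin-pink
  background plus Gaussian noise; exact labeled masks with contiguous ids;
  a configurable fraction of nuclei placed as touching pairs that share an
  8-connected interface while each keeps a ≥ 2 px interior. Contested
  pixels belong to the later-placed nucleus, so masks are partitions.
  Default 30 nuclei per 256×256 tile approximates the density of the
  benchmark tiles this emulates.
* **Patch grids** — per-slide 256×256 patches whose mean color and smooth
  blob texture depend on a latent class (LUAD purple-leaning, LUSC
  green-leaning, ND yellow-leaning), with balanced alternating slide labels
  and an optional non-diagnostic patch fraction.
* **Probability maps** — Dirichlet(1,1,1) cells mixed toward the dominant
  class's one-hot vector by an `effect` weight, giving uniform argmax at 0
  and certainty at 1, monotone in between.

What this does **not** emulate: real stain chemistry and scanner
variation, chromatin texture, the fragmented/imperfect borders real
networks predict on overlapping nuclei, non-exhaustive region annotations,
and nucleus density/shape heterogeneity across cancer types. Passing tests
therefore demonstrate correctness of the algorithms and trainability of
the architectures, not benchmark-level accuracy on real tissue.

## Problem sizes and determinism

Desk-scale runs use width-reduced networks (`width_divisor` 8–16, one
residual unit per stage for segmentation) chosen so the full suite trains
and evaluates on a single CPU: the reduced DRAN overfits five synthetic
tiles to held-out blob Dice > 0.9 in a few dozen Adam steps, and the
reduced ResNet32 plus random forest recovers 20 synthetic slide labels
(leave-one-slide-out for the forest) with both slide classifiers at 1.0 on
the pinned seed. The patch network is deliberately fit on the same slides
whose maps feed the forest, mirroring the use of over-fit late-epoch maps
for forest training. All generators and training loops are pure functions
of their seeds; the only nondeterminism left is floating-point
non-associativity inside numpy reductions, which does not change any test
outcome.

## Known limitations

* Full-width DRAN/MDRAN training at the published schedules (75 epochs,
  thousands of patches) is out of desk scope; the schedules are
  implemented and unit-tested, but headline benchmark scores require the
  original tiles/WSIs and GPU-scale compute.
* The Ensemble Dice pseudo-code is published only as a figure; the
  maximal-overlap matching rule implemented here is symmetric, reduces to
  the pixel Dice for single objects and penalizes splits/merges, but other
  readings are conceivable — the rule is isolated in one function so an
  alternative can be swapped in without touching callers.
* Labeled masks are partitions; overlap-aware (multi-label) instance
  output is out of scope.
* SVS/whole-slide file parsing is out of scope; patches and tiles are the
  ingestion units.
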