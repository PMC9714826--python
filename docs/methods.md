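# Methods

This note documents the models, the numerical conventions and the
design choices behind `strokeloc`, and what the synthetic benchmark
does and does not demonstrate.

## Problem and data model

The task is per-pixel localization of acute ischemic infarcts on
non-contrast CT, supervised by perfusion-derived label maps.  A case is
a stack of axial slices in Hounsfield Units (HU), indexed
(slice, row, col), with a paired label map on its own pixel grid whose
classes are {0 background, 1 normal tissue, 2 infarct core,
3 hypoperfused tissue}.  "Left"/"right" always mean image columns, not
anatomical sides.  By default both core and hypoperfused tissue count
as training-positive (`label_positive = "core+penumbra"`); the stricter
core-only labeling is a config switch.

## Preprocessing

* **Skull stripping.** Soft tissue is −200 HU < HU < 300 HU; these are
  standard CT tissue boundaries and both thresholds are exposed.  The
  largest 4-connected component is kept, interior holes filled, and
  bone pixels are never foreground.  An all-air slice yields an empty,
  flagged mask.
* **Registration.** The label map is aligned to the CT via the convex
  hulls of one representative mid-stack slice pair.  The objective is
  the area of the symmetric difference between the fixed hull and the
  transformed moving hull — a scalar area difference could not
  constrain rotation or translation at all, so the symmetric difference
  is the reading that makes the optimisation well-posed.  The transform
  family is a similarity with per-axis scale (the label grid has a
  different aspect ratio): p = M(q − c_m) + c_f + t with M = R(θ)·S.
  Search: per-axis scale initialised from the hull bounding-box ratios;
  coarse grid θ ∈ [−15°, 15°] step 1°, t ∈ [−20, 20] px step 2 px; then
  a restarted Nelder–Mead simplex over all five parameters.  A simplex
  is used for the polish because rotation and anisotropic scale form a
  strongly correlated valley in which coordinate-wise step-halving
  stalls; with the simplex, transforms applied at the polygon level are
  recovered to ~10⁻⁶.  Ties on the coarse grid go to the smallest |θ|,
  then the smallest |t_x|+|t_y|.  A near-flat objective across the θ
  grid (rotationally symmetric hulls, e.g. discs) sets a
  `low_confidence` flag.
* **Label transfer.** One transform (the mid-stack pair's) is applied
  to every slice pair; labels resample onto the CT grid by
  nearest-neighbour lookup, with off-grid pixels becoming background.
  Per-slice transforms are available as an option.  The transfer
  direction is label-grid → CT grid, the only direction that supports
  training on the CT.

An intrinsic accuracy limit is worth stating: a near-elliptical brain
outline gives rotation only a ~0.3 px/degree boundary signature, below
the ±0.5 px quantization ripple of a binary mask, so sub-half-degree
recovery through a *re-rasterized* mask cannot be guaranteed; the
rendered path is instead validated by its symmetric-difference residual
(≤ 2 % of the hull area in ≥ 90 % of seeded cases), which is what label
transfer actually depends on.

## Hand-crafted features and F4

Per pixel, the feature vector P concatenates, in this order: own-cell
C statistics (max, mean, median over in-mask HU of the pixel's cell),
contralateral-cell C statistics, K statistics per window scale
(max, mean, median over the in-mask window, plus the bilateral-filtered
value at the pixel), and global G statistics (max, mean, median over
the whole brain).  Defaults: 16×16 px cells; window scales {8, 16, 32}
(21 components); `scales=(16,)` reproduces the 13-component listing.
The bilateral filter (spatial σ = 3 px, range σ = 10 HU, truncated at
3σ) is applied once per slice.  These σ values are chosen so the filter
smooths the ~3 HU noise without erasing the ~5–20 HU lesion contrast.

Conventions chosen so that **horizontally mirroring slice+mask mirrors
the C and K maps bit-exactly** (a structural sanity property of any
contralateral feature):

* the patient midline v is the column centroid of the brain mask,
  carried as an exact integer ratio; contralateral pairing (nearest
  mirrored cell center, same row) is decided in integer arithmetic;
  mirrors falling outside the grid get a sentinel and are imputed;
* an even nominal window size w denotes the symmetric window of radius
  w//2 (so (w+1)² pixels in the interior), clipped at the image border
  rather than padded — clipping is reflection-equivariant and makes a
  window covering the whole slice agree exactly with G;
* every statistic is computed over sorted values (sums over the sorted
  order), making results independent of pixel enumeration order;
* the bilateral filter accumulates mirrored offset pairs together.

Empty cells/windows and off-grid mirrors are imputed with the global
in-mask mean — a value that carries no lesion-location signal.

F4 is a fully-connected network (D → 64 → 32 → 2, ReLU, softmax) over
standardized P vectors, trained with class-weighted cross-entropy
(inverse-frequency weights capped at 50), Adam (lr 10⁻³), and early
stopping on a 15 % validation split.  The final layer starts near zero
so the untrained network is near-uniform.

## F1–F3 extractors

Each extractor is a miniature encoder–decoder: three stride-2 3×3
convolutions (widths w, 2w, 4w), two dilated 3×3 convolutions
(dilations 2 and 4) that widen the receptive field without losing
coverage, bilinear upsampling to the half-resolution skip connection,
one 3×3 fusion convolution and a 3×3 output head; inputs are the
normalized HU ((HU − 35)/15, zeroed outside the mask) and the mask
itself.  The three variants differ in width (6, 8, 10) and seed,
supplying the feature diversity the ensemble fuses — the premise is
diversity, not any specific backbone identity.  Labels are training
targets only, never inference inputs (feeding them at inference would
leak ground truth).  Bilinear resizing is an explicit linear operator,
so its gradient is the exact transpose.  Inputs of any shape are padded
internally to a multiple of 8 and cropped back.

## Ensemble

Input blocks stack [F1, F2, F3, F4, h] per slice over a 1-, 3- or
5-slice neighborhood (5·b channels; volume ends replicate the edge
slice).  Architecture: 64 kernels 3×3 stride 1 + ReLU, multiplicatively
gated by the center-slice mask (the concrete reading of the mask
"manipulating the values in the region of interest"); then 3 kernels
1×1 + ReLU + softmax.  The three output classes are mapped to
{background, normal tissue, infarct} — a choice, since only the infarct
channel L is semantically fixed.

The ReLU-before-softmax output needs two stabilisations.  The 1×1
biases start at +0.1 so no class channel begins all-negative.  More
subtly, at pixels where *every* class pre-activation is negative the
ReLU blocks all gradient and those pixels freeze at uniform 1/3 while
the rest of the image trains on — exactly what happens inside lesions
when the background-dominated early gradient pushes the logits down.
The final ReLU therefore keeps its exact forward but leaks gradient
(slope 0.1) in its backward pass.

Training: class-weighted cross-entropy over all pixels, Adam with
lr 3·10⁻³ (at the desk-scale step budget the 15-channel fuser is
undertrained at 10⁻³, while the narrower single-map comparison models
converge faster — an inverted comparison; 3·10⁻³ brings the fuser to
its plateau at the same cost and applies identically to the comparison
models), minibatches of 4 whole blocks.  Default block size is 3.

## Postprocessing and evaluation

L is thresholded at τ = 0.5 (the boundary value counts positive).
Hemisphere selection computes 4-connected components per slice on each
side of the midline, sums each side's largest-component sizes across
slices, and zeroes the losing side — one side is kept for the whole
volume; ties go to the larger total positive count, then image-left.

The cell-wise protocol subsamples pixel masks into 32×32 cells by
strict majority (an exact half is negative); cells without any in-mask
pixel are excluded from the confusion matrix, since background cells
would inflate accuracy arbitrarily.  Accuracy is (TP+TN)/(valid cells)
— a documented choice.  Undefined ratios (0/0) are reported as missing
and excluded from aggregates.  IoU is pixel-level by default,
cell-level optionally.  Note that at the 96×96 benchmark resolution a
32×32 cell is a third of the image: lesions rarely claim a strict cell
majority, so the cell-level counts are near-vacuous there and the
pixel-level scores are the informative ones; at clinical resolution
(512×512) the same cells are ~1/16 of the image width and the protocol
is discriminative.

## Phantom generator

A phantom emulates what the pipeline must cope with: a −1000 HU
background, a ~1000 HU skull ring, a brain of Gaussian(35, 3) HU whose
outline is an ellipse (semi-axes 44×35 px at 96×96) with a 15 % linear
frontal taper — real axial sections are egg-shaped, and a pure ellipse
would leave hull orientation nearly unidentifiable — and a one-sided
lesion contiguous across slices: a core circle (HU decrease Δ) inside a
hypoperfused rim (0.6·Δ, width 3 px).  Difficulty sets Δ: easy 20 HU,
medium 10 HU, hard 5 HU; the default medium sits in the subtle
early-AIS regime relative to the 3 HU noise.  The label map renders the
analytic classes on a 128×128 grid under a random similarity transform
(θ, t ∈ ±10; scale_row 1.05–1.15, scale_col 0.85–0.95, i.e. a different
aspect ratio), so registration does real work.  Datasets alternate
lesion sides and derive per-case seeds from a master seed; the manifest
regenerates the identical dataset.

What the phantoms do **not** emulate: anatomical texture
(grey/white-matter structure, ventricles, sulci), partial-volume edges,
beam-hardening and scanner-protocol variation, stroke mimics, and
non-circular lesion shapes.  Passing the synthetic benchmark therefore
demonstrates that the pipeline's machinery — registration, features,
fusion, postprocessing, evaluation — is correct and learns subtle
one-sided hypodensity from few cases; it does not demonstrate clinical
accuracy.

## Benchmark sizes and determinism

The standard benchmark is 18 medium phantoms of four 96×96 slices,
leave-one-out, block size 3 — small enough to run on one CPU in about
ten minutes while leaving every stage non-trivial.  Desk-scale training
lengths (45 steps × batch 6 per extractor, 40 steps × batch 4 per
fuser, 80 epochs for F4 on ≤ 12 000 sampled pixels) are chosen as the
plateau of these easy problems.  Every random path — phantom rendering,
weight init, minibatch order, subsampling — flows from explicit
`numpy` Generators seeded from the master seed via `SeedSequence`
spawning, so datasets and trained weights are bit-reproducible on one
platform.  Float32 is used inside the networks, float64 everywhere
statistics are compared against oracles.

## Known limitations

* The hull registration assumes the brain outline is the dominant
  connected structure and only corrects similarity misalignment; no
  deformable or intensity-based registration.
* One transform for all slice pairs assumes the misalignment is common
  to the stack (true for the rendered phantoms; an approximation for
  scanner data).
* The encoder–decoder extractors are deliberately miniature stand-ins
  for large pretrained segmentation backbones; their absolute accuracy
  on clinical data is not the point, their diversity is.
* Hemisphere selection assumes a unilateral lesion; bilateral strokes
  would lose one side's true positives.
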