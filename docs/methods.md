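# Methods

This note records the scientific and numerical choices behind the package:
what each stage assumes, which parameters matter, what the synthetic
phantoms do and do not emulate, and where the design was genuinely open.

## The phantom generator

Real abdominal CT slices are emulated by a bright elliptical "kidney"
(intensity ≈ 0.6 of full scale) on a dark background (≈ 0.1), with one
class-specific lesion per image:

| class  | lesion                                   | intensity |
|--------|------------------------------------------|-----------|
| normal | none                                     | —         |
| cyst   | round fluid-dark inclusion               | 0.22      |
| tumor  | irregular (sinusoidally perturbed) mass  | 0.42      |
| stone  | ≤ 5-px near-saturated calcified speck    | 0.97      |

Geometry is randomised per sample (centre ± 5 % of the frame, semi-axes
0.28–0.36 / 0.18–0.24 of the frame, free rotation; lesions are placed within
45 % of the kidney semi-axes and clipped to the organ).  Additive Gaussian
noise (σ = 0.03 in intensity units) models detector noise; 2 % salt-and-
pepper impulses give the median filter a realistic removal target.  These
defaults were chosen once as plausible desk-scale analogues of contrast CT
and are the package's study conditions.

On noise-free phantoms the mean lesion intensity orders
stone > parenchyma > tumor > cyst, which is the separability the statistical
features exploit.

**What the phantoms do not emulate:** anatomy (two kidneys, cortex/medulla
structure, neighbouring organs), Hounsfield calibration, partial-volume
texture inside tissue, slice-thickness effects, multiple or subtle lesions,
scanner-specific artefacts.  Passing the phantom study therefore shows the
pipeline is implemented correctly and can learn the intended contrasts at
small scale — not that it reaches clinical accuracy on hospital data.

## Preprocessing

A 3×3 median filter (edge replication) is the default: the smallest window
that removes isolated impulses while preserving edges.  Note a consequence
that matters downstream: a ≤ 5-px stone loses its outer pixels to the
median, so the stone/normal margin after filtering is carried by a handful
of bright interior pixels.

## Segmentation

The ENet follows the canonical bottleneck recipe (projection ratio 4, PReLU,
batch norm between convolutions and nonlinearities, no bias in projections,
spatial dropout on the expansion).  Encoder stages 2–3 cycle through
regular / dilated (2, 4, 8, 16) / asymmetric-5 main convolutions; the two
decoder stages unpool with the encoder's pooling indices; the final
upsampler is a learned transposed convolution, since the initial block's
pooling indices are not reusable at the input channel count.  Three
downsamplings require input dimensions divisible by 8.

Two configurations are provided: the canonical widths (16 initial channels,
stages 64/128/128, repeats 4/8/8/2/1) for structural fidelity, and
`EnetConfig.small()` (8 initial, 16/32/32, repeats 1/2/2/1/1, no dropout)
used for the 64×64 phantom experiments, where it reaches ≈ 0.96 training
IoU in 15 epochs of Adam at lr 3e-3 on 128 images.  Training minimises
per-pixel softmax cross-entropy and is deterministic given the seed.

## Augmentation

Rotation uses bilinear interpolation (values stay in range); exact
multiples of 90° are dispatched to pure pixel permutations so conservation
properties hold to the last bit.  Translation is integer-pixel with a
Bernoulli(0.5) black-or-white fill per draw.  Augmentation is applied to
training folds only — validation and test folds are never augmented — and
each source sample contributes multiplier−1 transformed copies with fresh
seeded draws.  Masks follow the image geometry with nearest-neighbour
resampling.

## Feature bank

* **SURF.**  Two octaves of box-filter sizes (9, 15, 21, 27 / 15, 27, 39,
  51), Hessian-determinant weight 0.81 on the mixed term, area-normalised
  responses, 3×3×3 non-maximum suppression with quadratic refinement,
  default threshold 1e-4 on [0, 1] images, top-5 points by response.  The
  descriptor is the canonical oriented 20σ square (4×4 subregions × 5×5
  samples, Haar size 2σ, Gaussian weights), L2-normalised — hence invariant
  to affine illumination scaling.  On 64-px frames the 20σ window exceeds
  the image for nearly every point, so the record extractor samples on an
  edge-replicated canvas (`pad_border=True`); the plain operation keeps the
  skip-with-warning border contract.
* **Texture.**  One orthonormal Haar analysis level; the LL, LH and HH
  subbands feed the chain (HL is computed for energy accounting — the four
  subbands satisfy Parseval — but is not forwarded).  The Weber excitation
  arctan[Σ(fᵢ−f₀)/f₀] is computed over the 8-neighbourhood after an affine
  shift of the subband to [1e-3, 1+1e-3] (the ratio needs a strictly
  positive centre value).  HOG uses 16×16-px cells at stride 8 on the 64×64
  window — the only geometry consistent with a 7×7×9 = 441 output — with
  magnitude-weighted soft binning over 9 unsigned bins and global L2
  normalisation.
* **Shape.**  `area, perimeter, major axis, minor axis, solidity` from the
  moment-matched region properties of the mask; the eccentricity accessor
  returns minor/major (1 for a circle, → 0 when elongated).
* **Statistics.**  Masked mean plus GLCM entropy (−Σ p log₂ p), correlation
  and contrast at 8 grey levels, distance 1, angle 0°, symmetric,
  normalised.  The region is **eroded by 2 px** before the GLCM (skipped if
  fewer than 16 px would remain): boundary pixels carry partial-volume
  gradient values that flood the co-occurrence matrix with mixed-level
  pairs; on phantoms this erosion raises the normal-vs-stone separability
  of the statistical block from ≈ 0.76 to ≈ 0.99 (cross-validated), because
  the stone signal is precisely a few high-level pairs.

## Classifier and training protocol

The fusion blend coefficients (1, ½, ⅙, 1/24) are fixed; the gate is a
logistic function of a learned affine map of (p, p1, p2), keeping U ∈ (0, 1)
and all blend coefficients bounded.  p, p1, p2, C1, C2 share a fusion width
of 64; the "weighted sums" are realised as learnable linear maps from each
block.  C2 enters the ZFNet head through a learned lift to an 8×8
single-channel grid; the desk-scale head uses 3×3 convolutions with
channels (16, 32, 32, 32, 32), 2×2 pools and FC widths 64→32→4.  The
SpinalNet branch consumes the masked image at 64×64, split into 8 segments
with hidden width 32 (the historical two-neuron width is configurable but
far too narrow to learn the phantoms).

Three training-design choices matter at n ≈ 160 and are deliberate:

1. **Block-balanced feature scaling.**  Features are z-scored with training
   statistics, then each block's z-scores are divided by √(block length).
   Without this the 1323-dim texture block contributes two orders of
   magnitude more aggregate variance to the learned projections than the
   4-dim statistical block purely by count, and optimisation follows the
   high-dimensional (positionally variant, non-generalising) directions.
2. **Branch-weighted regularisation.**  The raw-image spinal branch and the
   full-feature map receive weight decay 0.05; the compact statistical and
   shape paths 1e-3.  Ablations showed the high-capacity branches memorise
   the training set at this sample size; heavier shrinkage lets them
   contribute only where their gradient signal is consistent.
3. **Augmentation multiplier 5** on training folds: more optimisation steps
   per epoch and more geometric diversity within the ≤ 30-epoch budget.

The optimiser is Adam at lr 0.001 (SGD and RMSProp selectable), batch 32,
softmax cross-entropy; the controller halves the LR after 5 validation-
accuracy epochs without a ≥ 1e-4 improvement, stops after 50 non-improving
epochs, and restores the best-validation checkpoint.  Sample order is
canonicalised by stable ids before the seeded shuffle, so permuting the
input set does not change the result.

## Metrics

The binary definitions (accuracy, sensitivity, precision, specificity, F1)
are reduced one-vs-rest per class and macro-averaged, reported in percent.
Zero-denominator cases return 0 with an explicit flag rather than raising,
so fold aggregation stays total.  ROC curves are one-vs-rest with a pooled
micro average and an interpolated macro average; AUC is trapezoidal.
Classes absent from the truth get `None` AUCs.

## Numerical notes

* All network math is float64 on a numpy reverse-mode autodiff engine;
  composite layers (batch norm, PReLU, response normalisation, losses) are
  built from primitives so gradients follow from the chain rule, and the
  suite checks them against central finite differences (≤ 1e-4 relative).
* Max pooling is non-overlapping (kernel = stride) and records argmax
  indices; unpooling scatters to exactly those positions.
* GLCM probabilities are renormalised after dropping the out-of-mask
  sentinel level, so only within-mask pixel pairs contribute.
* Median-filter ties cannot occur (odd windows); borders replicate edges so
  constant images are exact fixed points.

## Problem sizes

The default experiments use 160 phantoms (40 per class) at 64×64, an 80/20
stratified split, 15 segmenter epochs and ≤ 30 classifier epochs — sizes at
which the full study runs in a few minutes on one CPU.  At these conditions
the pipeline reaches ≈ 0.96 training IoU and ≈ 0.86–0.97 held-out accuracy
across seeds (the residual errors concentrate on the normal/stone axis,
whose margin after median filtering is intrinsically the smallest).

## Known limitations

* The SURF block, while populated, is dominated by kidney-boundary
  structure at 64 px and contributes little class signal.
* The HOG texture block is positional; with randomly placed lesions and
  only ~10² training images it acts mostly as a nuisance dimension (hence
  choices 1–2 above).  At the dataset scales the architecture was designed
  for, these blocks would be learnable signal.
* The phantom study validates implementation and desk-scale learnability
  only; no claim transfers to clinical CT without retraining and
  re-validation on real data.
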