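# Methods

## Problem and model

`octpre` segments macular OCT B-scans into four vertically ordered regions —
vitreous (0), preretinal space (1), retina (2), space under the retina (3) —
delimited by three boundary lines: the posterior cortical vitreous (PCV),
the inner limiting membrane (ILM), and the outer border of the retinal
pigment epithelium (RPE).  The clinically relevant quantity is the
preretinal space between PCV and ILM, which distinguishes vitreomacular
adhesion (VMA, the PCV rests on the ILM) from vitreomacular traction (VMT,
the PCV is elevated with a residual central adhesion).  Segmentation is
pixel-wise semantic segmentation with fully convolutional networks; because
the vitreous and the preretinal space have near-identical intensity, the
network additionally receives a *relative distance map* (RDM) as a second
input channel and/or uses enlarged, possibly rectangular convolution
kernels, both of which reduce violations of the fixed vertical class order.

Coordinates are 0-based with row 0 at the top and y growing downward.  A
boundary value is the row coordinate of the first pixel of the region below
it: class 1 occupies rows `[pcv, ilm)` and class 2 rows `[ilm, rpe]`.
Boundary inputs may be float-valued; maps compare pixel rows against them
without rounding.

## Relative distance maps

* **2NetR** (retina-anchored): `M = (y - ILM(x)) / (RPE(x) - ILM(x))`;
  0 on the ILM, 1 on the RPE, negative above, above 1 below.  No clipping is
  applied.
* **2NetPR** (preretinal-anchored): piecewise linear with anchors 0 at the
  PCV, 0.5 at the ILM, 1 at the RPE; outside `[pcv, rpe]` it continues the
  retina-plus-preretinal ramp `(y - pcv)/(rpe - pcv)`.  Continuity at all
  three anchors is exact for rational boundary values.
* **CumSum**: per-column cumulative intensity sum divided by the column
  total, hence bounded to [0, 1] and invariant to positive intensity
  scaling; all-zero columns map to zero.  It needs no prior segmentation.
* **BasicOrient**: a [0, 1] ramp along the axis tilted by a single global
  retina orientation, estimated as the gradient-magnitude-weighted mean
  gradient direction after Gaussian smoothing (sigma = 3 px) and Sobel
  differentiation.  Gradient pairs are sign-aligned downward before
  averaging so the opposite-signed gradients of a band's two edges do not
  cancel.  A single global angle (not a per-pixel field) is used because the
  map is one arrangement of linearly spaced values per image.  Sign
  convention: positive angle = layers descend toward the right.

Degenerate columns: at full adhesion (`pcv == ilm`) or zero retina height
the affected denominator is clamped to one pixel, and the single boundary
pixel takes the retina-branch value 0.5.  Adhesion is a defined, frequent
VMT feature, so it must not raise an error.

The boundary-anchored maps need prior boundaries.  These may come from
ground truth, from the graph-search baseline, or from any caller-supplied
model; the original scheme's cascaded re-training is not reproduced.

## Loss

`L = alpha * L_log + beta * (1 - sum_c lambda_c * Dice_c)` with defaults
alpha = 1, beta = 0.5.  `L_log` is categorical cross-entropy, normalised by
the per-class pixel count and weighted per pixel by
`w_c = 1 + q1 * [vertical edge of class c] + q2 * [c in {1, 2}]`
(q1 = 10, q2 = 5): boundary pixels and the two thin classes of interest are
emphasised.  The edge indicator is the one-pixel vertical difference of the
binary class mask, applied per the class of the ground-truth term it
multiplies.  `Dice_c` is soft (probability-valued) during training; reported
metrics use hard argmax masks.  Class weights
`lambda_c = (1/n_c) / sum(1/n_c')` are computed once over the training
split's pixel counts, not per batch.  Numerical conventions: epsilon = 1e-7
floors the logarithm and smooths the Dice ratio, which makes an absent class
with near-zero predicted mass score 1 (perfect handling of absent classes is
not penalised); classes absent from the ground truth contribute 0 to
`L_log`.  The analytic gradient with respect to the probability map is
implemented alongside the loss and is finite-difference checked in the test
suite.

## Architectures and the numpy engine

Four encoder-decoder networks share one forward contract (any input size;
softmax probabilities the same size out): UNet (5 levels of double conv,
channel doubling, skip concatenation), Attention UNet (additive attention
gates on the skips, gated by the upsampled decoder signal, intermediate
width F/2), ReLayNet (constant width, conv + batch norm + ReLU, 3
pool/unpool stages with max-pool index passing, default 7x3 kernel), and
LFUNet (UNet encoder, dual concatenation/addition decoders, fused through
three parallel dilated 3x3 convolutions with rates 1, 2, 4).  All
convolutions are stride-1, same-padded, with odd (possibly rectangular)
kernel dims; inputs are reflection-padded to the pooling granularity (16, or
8 for ReLayNet) and cropped back, so random-crop training sizes are
handled exactly.  Weight init is He-uniform, seed-controlled.

The networks run on a small tape-based autodiff engine written for this
package (`octpre.nn`), implemented with numpy sliding-window views and
`tensordot` so convolution forward/backward stays inside BLAS.  Float32 is
used throughout; reflection padding has an exact scatter-add backward.

## Graph-search baseline

Boundaries are minimum-cost left-to-right paths over the rectified,
min-max-normalised vertical gradient (dark-to-bright or bright-to-dark
polarity), with edge weight `2 - (g_a + g_b) + w_min`, `w_min = 1e-5`, and
virtual zero-cost endpoint columns.  Paths are restricted to monotone
left-to-right moves (up-right/right/down-right), which admits an exact
O(HW) dynamic program; optimality is verified against exhaustive
enumeration on small instances.  Ties break toward smaller row indices.
The sequence is ILM (whole image), RPE (rows below ILM + margin; default
margin 20 px assumes a ~64 px retina and should be scaled with image size),
then PCV (rows at or above the ILM, with the ILM's own edge suppressed in a
one-pixel band so the search does not simply rediscover it).  When the PCV
path has almost no gradient support (below 20% of the ILM's), the line was
effectively invisible; the output degenerates to the ILM and is flagged
low-confidence — the documented weakness of gradient-based PCV search.
Pre-smoothing is exposed as an option but off by default.  One caveat
measured on phantoms: the RPE is rendered as a thin hyperreflective line,
and Gaussian pre-smoothing can shift its rising-flank gradient peak up by
one row, so smoothing may cost up to ~1 px of RPE accuracy while it
improves noisy PCV paths.

## Synthetic phantoms

The generator emulates the statistical structure of 640x384 px macular
scans (width 384 rather than the acquisition's 385 to match the networks'
pooling granularity; voxel 3.125 x 18.18 x 49.65 um):

* ILM: tilted (orientation sampled within +-20 degrees), low-frequency
  profile with a central foveal pit, vertical position varying within
  +-10% of the image height; RPE follows at a sampled thickness of
  64 +- 10 px (about 200 um), retina thinner under the pit.
* PCV: both case types are a detached perifovea around an exact central
  adhesion zone (`pcv == ilm`), reached through a continuous bounded-slope
  soft threshold; VMA detaches shallowly (default amplitude 30 px) around a
  wide attachment, VMT pulls the cortex off a narrow residual adhesion
  (default amplitude 110 px).  The amplitudes are calibrated so mean
  per-column gaps (about 14 px VMA, 88 px VMT at 640-px scale) land inside
  the clinically reported preretinal-volume bands for the two groups; the
  exact mm^3 means are not reproduced.  VMT phantom volumes therefore
  exceed VMA volumes by several-fold.
* Intensities: vitreous and preretinal space share base level 0.05 —
  deliberately identical so that only the thin PCV line (2 px at 0.55,
  rendered on a `pcv_visibility` fraction of columns, default 0.7, and only
  where the PCV is at least one pixel off the ILM) separates classes 0 and
  1.  The varying visibility, not the line's contrast, is the difficulty
  the phantoms model.  The retina is a bright superficial band (0.85) over
  a 0.40 body with a 1-px hyperreflective RPE line (0.90) at its last row;
  below-retina is 0.2.  Multiplicative gamma speckle (unit mean, shape 8 by
  default) is applied last.  PCV line thickness and contrast are plausible
  defaults, not calibrated to any measurement.
* Masks are rasterised from float boundaries by nearest-pixel rule, so
  boundary extraction from a mask recovers the generating lines within
  0.5 px, and every generated mask is topologically valid by construction.

What the phantoms do *not* emulate: acquisition optics, A-scan physics,
vessel shadows, motion artefacts, real speckle correlation, pathology
other than VMA/VMT geometry, or 3D coherence between neighbouring B-scans.
Passing tests on phantoms therefore demonstrates the correctness and
trainability of the pipeline, not clinical-grade accuracy on real scans.

## Data curation and augmentation

Five per-image quality scores (robust post-median-filter residual scale,
RMS contrast, mean intensity minus near-black fraction, Laplacian variance,
mean run length between strong vertical edges) are z-scored and fitted with
a minimum-covariance-determinant Gaussian (support fraction
1 - contamination); the `ceil(contamination * N)` samples with the highest
Mahalanobis distances are flagged, 3% by default, pooled over all B-scans.
The feature definitions are standard operationalizations tested for their
monotonicity contracts; no bit-compatibility with any external scorer is
claimed.

Augmentation applies one joint draw of horizontal flip (p = 0.5), rotation
(+-20 degrees), vertical translation (+-10% of height) and per-axis random
crop (80-100%) to image, mask and map, in that fixed order.  Images and
maps are interpolated bilinearly with reflective fill; masks use nearest
neighbour with out-of-view rows filled class 0 at the top and class 3 at
the bottom, followed by a per-column running maximum that repairs the rare
single-pixel aliasing of thin bands, so augmented ground truth always
remains topologically ordered.  Offline expansion produces a fixed
`1 + copies` pool (4 copies by default, matching dataset-level
bookkeeping); image-derived maps (CumSum, BasicOrient) are recomputed from
the augmented image, boundary-derived maps would have to be re-derived and
are deliberately not supported in offline mode.

## Training protocol

Adam (lr 5e-6, beta1 0.9, beta2 0.999), batch size 1, at least 50 epochs,
early stopping once the validation loss has not improved for 5 consecutive
epochs (the patience counter is armed only after the minimum epoch count),
and evaluation always from the lowest-validation-loss checkpoint.  The
5e-6 rate suits long runs on large pools; the documented phantom-scale
preset is lr 1e-4.  Splits default to 80/10/10 with floor rounding and the
remainder to training, grouped by synthetic volume to avoid near-duplicate
leakage (a per-image mode is available).  Evaluation uses full-size,
uncropped scans.

## Evaluation metrics

Per-class hard Dice (absent-in-both classes score 1), per-boundary MAE in
pixels with SD across scans, the Topology Incorrectness Index (TII: the
percentage of masks whose labels decrease anywhere down any column —
zero-tolerance, a single stray pixel makes a mask incorrect), and the
preretinal volume in mm^3 from class-1 voxel counts.  Boundaries are
extracted from masks by first-transition scanning (PCV = first row >= 1,
ILM = first row >= 2, RPE = last row <= 2); degenerate columns (missing
transitions, clipped extremes, broken ordering) are flagged so MAE can be
reported with or without them.

## Scaled-down experiment sizes

The desk-scale benchmarks train on synthetic phantoms: the main run uses a
UNet (8 initial features, 3x3 kernel, lr 1e-4) on 200 train / 20 val / 40
test phantoms at 128x128 px for 10 epochs; the trend comparisons (distance
maps, kernel shape, versus graph search) use 95 train / 10 val / 20 test
phantoms at 64x64 px trained at lr 1e-3 for 20 epochs, closer to
convergence, so that topology differences between variants are measurable
and several runs fit in one test session.  These sizes are the package's
chosen study conditions for the property suite; headline numbers from
GPU-scale training on real data are out of scope.

## Known limitations

* The numpy engine is single-threaded BLAS-bound; it is meant for
  correctness and phantom-scale training, not production training speed.
* BasicOrient's global-angle estimate degrades on images whose dominant
  gradients are not layer-like.
* Anomaly flags from the MCD fit are deterministic given the seed, but the
  exact boundary between the flagged and unflagged middle of the pool can
  shift under reordering when scores are nearly tied; the planted-outlier
  regime is stable.
* Training reproducibility is bit-exact on one platform/BLAS build and
  "within tolerance" across builds.
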