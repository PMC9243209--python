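# Methods

## Overview

The package grades diabetic-retinopathy (DR) severity from fundus
photographs by texture alone. The processing chain is: image
standardisation → block-wise uniform local-binary-pattern (LBP) histograms
→ zero-run encoding → SVM on the token vector, or a small CNN on the token
vector rendered as a square image. A synthetic fundus phantom generates
graded test data so the whole chain can be exercised and validated without
clinical images.

## Standardisation

All images are resized to 512×512 (bilinear) before anything else, so
every later parameter (filter kernels, block grid) is scale-stable. Only
the green channel is processed: among the RGB channels it has the best
contrast between retinal structures and background.

Stage order: histogram matching → median filter → CLAHE → unsharp masking.
The FOV mask (retina foreground vs black corners) is computed from the
*raw* green channel — threshold at intensity 10, keep the largest connected
component, fill holes — so contrast enhancement can never leak background
into the foreground. Defaults, all overridable via `PreprocessConfig`:

| parameter | default | why |
|---|---|---|
| median kernel | 3×3 px | smallest denoising kernel; preserves ~5 px microaneurysms |
| CLAHE tiles / clip | 8×8, 0.01 | gentle, local contrast without strong noise amplification |
| unsharp radius / amount | σ = 2 px, 1.0 | emphasises lesion edges at the LBP sampling scale |
| FOV threshold | 10 | black corners are near 0; retina interior ≫ 10 |

**Histogram matching** uses the classic 8-bit cumulative-histogram lookup
table: source level *g* maps to the smallest reference level whose CDF
reaches the source CDF at *g*. The construction is monotone, idempotent to
within one grey level, and collapses to a constant when the reference is
constant.

**The reference image** is the one genuinely delicate choice. The method
requires a "well-balanced" reference; the packaged default is a noise-free
healthy (grade-0) rendering of the synthetic phantom — an image from the
same family as the inputs. This matters more than it may look: matching to
a target with an alien histogram shape produces a terraced lookup table
whose steps move when anything in the source histogram moves. Because LBP
codes are *thresholded* comparisons, a one-level terrace shift in a smooth
region flips bits, and we measured that such a reference scrambles a large
fraction of all block codes between two images of the same grade. With a
same-family reference the matching transform stays near the identity for
well-exposed images and the codes are stable. Any reference can be
supplied via `PreprocessConfig.reference_image` or the CLI `--reference`.

## Feature extraction (the core method)

At radius R the block side is `2R + 1` and a 512-sided image carries
`divisions = 5·⌊512/(5·(2R+1))⌋` blocks per axis (70 at R = 3). Blocks
containing *any* background pixel are skipped entirely. Within a block,
only pixels whose full circular neighbourhood fits inside the block
contribute — for block side `2R + 1` that is exactly the centre pixel, so
each block histogram is one-hot. This reading is the only one consistent
with the published worked example (233581 = 3959 surviving blocks × 59
bins at (P, R) = (8, 3)).

LBP conventions (fixed; any consistent set works, these are pinned for
reproducibility): neighbour 0 at angle 0 (east), counter-clockwise;
sample offsets snap to the nearest pixel when within 0.3 px per axis —
which makes P = 8 the classic square-neighbourhood operator at every
radius, as in rounded-coordinate LBP implementations — and genuinely
between-pixel angles (larger P) are bilinearly interpolated; neighbour ≥
centre → bit 1 (ties count as 1, the standard convention); bit 0 least
significant.
Interpolated samples within 1e-6 of the centre count as ties, so constant
patches code deterministically despite float rounding. Uniform codes (≤ 2
circular transitions) occupy bins 0 … P(P−1)+1 in ascending raw-code
order; all non-uniform codes share the last bin. The mapping is stored as
a sorted array of the P(P−1)+2 uniform codes (they are exactly the two
constant codes plus every rotation of a run of ones), so even P = 24 costs
a few kilobytes rather than a 2²⁴-entry table.

**Zero-run encoding**: each nonzero value v preceded by z zeros becomes
the pair (z, v); a final (trailing-zero-count, 0) pair terminates the
stream. Decoding is an exact inverse, and for one-hot blocks the token
count is at most `2·blocks + 2`, which is why the per-radius capacities
(16150 / 8200 / 4950 / 3300 for R = 2…5) hold with room to spare. The
padded vector (right-padded with zeros to capacity) feeds the SVM; an
overflow raises rather than truncates.

**Feature image**: the padded vector is reshaped row-major into the
smallest enclosing square (side ⌈√capacity⌉, 91 at R = 3), min-max
normalised to [0, 255] (an all-constant vector maps to black), and CLAHE
with the preprocessing defaults spreads the token dynamic range.

## Classifiers

*SVM.* Features are standardised with train-set statistics; multi-class
problems use one-vs-one voting; the regularisation constant defaults to
1.0. Kernels as published: linear `x·y`; RBF `exp(−γ‖x−y‖²)`; polynomial
`(1 + x·y)^q`; Gaussian `exp(−‖x−y‖²/(2σ))`. Note the Gaussian
denominator is 2σ, not the conventional 2σ² — it is implemented exactly as
printed, with `gaussian_conventional=True` switching to 2σ². With
γ = 1/(2σ) the two coincide, which the tests exploit as a cross-check.

*CNN.* A fixed stack — three groups of (1×5 convolution, stride 1, padding
1 on all four sides; batch-norm; ReLU; 1×2 max-pool with stride 2 on both
axes) with 8/16/8 filters, then dense layers of width 100 and
`n_classes`, and softmax. Padding both axes while convolving only along
rows makes the height grow by 2 and the width shrink by 2 per convolution:
91×91 → 93×89×8 → 47×44×8 → 49×42×16 → 25×21×16 → 27×19×8 → 14×9×8 = 1008
features before the dense head, which `cnn_output_shapes` reproduces and
the tests pin. The final dense width follows the grading scheme's class
count (2, 3 or 5). The engine is plain NumPy: He initialisation,
mini-batch Adam (lr 1e-3, batch 32, 50 epochs default), cross-entropy,
early stopping on a 10 % validation split (patience 10), batch statistics
in training and running statistics at inference. All seeded.

*Protocol.* 70/30 stratified train/test split (seeded, deterministic).
`mirror_augment` doubles images by mirroring about the vertical axis —
optionally only grades 1–4, the balancing trick for the sparse abnormal
grades.

## Evaluation

Confusion matrix (rows = truth), per-class one-vs-rest precision, recall
(sensitivity), specificity and F1; accuracy = trace/total; zero
denominators yield 0 with a warning flag rather than NaN, keeping reports
total. Multi-class summaries report both macro and support-weighted
averages, since a single printed figure cannot reveal which averaging
produced it. AUC is the rank-based (Mann–Whitney) estimator with ties
counting ½ — invariant under monotone score transforms.

## The synthetic phantom

The generator emulates what the pipeline needs from a fundus photograph:
a bright elliptical FOV (semi-axes 0.48/0.46 of the image side — black
corners, ~69 % foreground), a green-dominant interior, a radial
illumination falloff, background texture, dark random-walk vessels, and a
graded lesion burden —

- microaneurysms: dark discs, ~5 px diameter at 512 scale, count 3g (+0/1)
  for grade g ≥ 1;
- haemorrhages: dark blobs 10–25 px, count max(0, 2(g−1));
- exudates: bright irregular blobs 8–30 px, count max(0, 2(g−1));
- contrasts: dark lesions 35 % darker, exudates 40 % brighter than the
  local background; grade 0 renders no lesions at all.

**Controlled-phantom design.** The anatomy — vignette shape, a
choroidal-mottle texture field (Gaussian-filtered noise, amplitude 25 grey
levels, correlation scale 4 px at the 768 px rendering), and the vascular
tree — is a fixed template drawn from `anatomy_seed`, shared by every
image the way a screening series from one camera shares gross retinal
architecture. Per-image randomness covers the illumination tilt (2 % of
the vignette amplitude), additive sensor noise (σ = 0.5 grey levels), and
all lesion counts, sizes and placements. This split is deliberate:
thresholded LBP codes on 8-bit images sit on quantisation knife edges, so
a generator that randomises the whole background per image buries the
lesion signal under code noise that no classifier — linear or not — can
recover at desk scale. Fixing the anatomy makes grade the only systematic
factor, which is precisely what an end-to-end signal check needs. The
mottle amplitude/scale were calibrated once so that background codes are
texture-determined rather than noise-determined, then frozen.

What the phantom does **not** model: optic disc, macula, camera defocus,
over/under-exposure, colour variation between eyes, clinical lesion
morphology (lesions are scaled discs), or between-patient anatomical
variation. Passing the end-to-end checks therefore shows that the
implementation preserves and recovers a lesion-burden signal through the
full chain — it says nothing about clinical performance on real
photographs, which depends on texture variation this phantom deliberately
excludes.

## Numerical choices and degenerate inputs

- All stages are pure functions of (input, config, seed); repeated runs
  are bit-identical on a fixed BLAS.
- CLAHE on a constant image returns it unchanged; min-max normalising a
  constant feature vector yields all zeros; an all-dark image produces an
  all-false FOV mask with a warning; an all-background mask raises.
- Neighbour offsets are snapped to 9 decimals so axis-aligned samples land
  on exact integer coordinates.
- Grid origin is the top-left corner; pixels beyond `divisions·block_size`
  on the right/bottom are ignored (the remainder is < 5 blocks by
  construction). Coordinates are 0-based (row, col) throughout.
- Capacities are configuration, not hard truths: synthetic overflow raises
  rather than truncates, and any capacity can be overridden.

## Problem sizes used in the checks

The end-to-end checks run 100 healthy + 100 grade-4 phantom images at
(P, R) = (8, 3) with a 70/30 split — large enough for a stable accuracy
estimate, small enough to run on a laptop CPU in a few minutes. The CNN
check trains 20 epochs on the same images' feature images. Unit and
property tests use 16×16 to 512×512 rasters and 1000-case coding
round-trips.
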