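# Methods

## Scope and model of the problem

`microderm` classifies a single pigmented lesion in a dermoscopy image as
benign or malignant. The pipeline assumes: one lesion per image, darker
than the surrounding skin; roughly homogeneous healthy skin occupying the
image corners; and the usual dermoscope artifacts (black adapter frame,
hairs, immersion-fluid air bubbles). Every stage is deterministic given its
inputs; all randomness in the package lives in the synthetic generator and
in fold shuffling, and is seeded explicitly.

## Synthetic data: what it emulates and what it does not

The generator produces the only data the test suite uses. A sample is a
star-convex lesion with boundary radius
`r(θ) = R·(1 + a·Σ_{k=2..5} aₖ sin(kθ + φₖ))` (harmonic weights normalized
to sum to 1, so `a` is the total radial perturbation amplitude), rendered
over a noisy skin tone with `n_colors` pigment tones laid out as
nearest-seed cells, spatially correlated intensity noise of standard
deviation `texture_contrast` gray levels inside the lesion, quadratic-Bézier
hair strokes (width 1–3 px, lightness < 60), a black border ring, and
bright bubble discs (+40 gray levels, kept clear of the lesion).

Defaults are 192×192 px images with lesion radius 40 px, hair_count 3,
frame_width 6, bubble_count 2. The image/lesion scale was fixed so that a
one-pixel boundary uncertainty corresponds to roughly `2/R ≈ 5 %` relative
border error — the resolution regime in which sub-6 % segmentation error is
meaningful. Class-conditional parameter ranges mirror the clinical cues the
features target:

| parameter          | benign    | malignant  |
|--------------------|-----------|------------|
| asymmetry_amp      | U[0, 0.1] | U[0.25, 0.6] |
| n_colors           | {1, 2}    | {3..6}     |
| texture_contrast   | U[0, 5]   | U[15, 40]  |

A sample's label is deterministic from its parameters (malignant iff
`asymmetry_amp ≥ 0.2` and `n_colors ≥ 3`). Each sample owns an independent
random stream keyed by `(dataset seed, sample index)`, and within a sample
the shape, coloring, noise, hair and bubble draws use separate child
streams — removing hairs from a spec changes hair pixels only, which is
what makes inpainting testable against the artifact-free render.

What the generator does *not* emulate: dermoscopic local structures
(pigment network, globules, streaks), skin lines, illumination gradients,
lens vignetting, camera noise statistics, or the intra-class ambiguity of
real lesions. The classes are separated by construction, so perfect
cross-validated accuracy on synthetic data demonstrates that the pipeline
recovers the generating structure without leakage — not that it would reach
any particular accuracy on clinical images.

## Preprocessing

*Frame*: pixels with HSL lightness < 15 (on the 0–255 scale) that are
4-connected to the image border. Removal is by cropping to the maximal
axis-aligned frame-free rectangle (largest-rectangle-in-binary-matrix
sweep): cropping cannot invent pixel values and so cannot bias the color
statistics. An image whose frame covers more than half its pixels is
rejected as unusable.

*Hairs*: black top-hat of the NTSC grayscale with a disc of diameter 7 px
(the hair-width scale at ~0.05 mm/px; configurable). The response is
thresholded at Otsu-over-nonzero-responses with an absolute floor of 10
gray levels (so noise-only images produce nothing), restricted to pixels
darker than 100 (hairs are dark; the halo a closing leaves around bright
bubbles is not), and filtered to components of at least 30 px whose
skeleton-length/mean-width ratio is ≥ 4 (hairs are curvilinear; compact
blobs are not). On strongly textured lesions a few dark texture filaments
can pass this filter and get inpainted; this slightly smooths the lesion
interior and is an accepted trade-off — the texture-contrast gap between
the classes is far larger than the effect.

*Inpainting* fills the (1-px-dilated) hair mask layer by layer, each masked
pixel taking the mean of its unmasked 8-neighbors; it converges in at most
max(H, W) iterations and touches only masked pixels.

*Smoothing*: per-channel Gaussian, σ = 1.5 px, reflective boundaries.
Order: frame → hair → smooth, so hair edges do not smear before detection.

## Segmentation

Region growing starts at pixel (5, 5) of the cropped image — on healthy
skin by the frame-crop construction, offset from (0, 0) to dodge residual
border pixels. 4-connected neighbors join the region when their gray value
is within a tolerance of the running region mean (frontier processed FIFO;
rejected pixels are not revisited; deterministic). The fixed-seed-value
criterion variant is also provided; only that variant is monotone in the
tolerance, which the tests exploit.

The default tolerance is **half the typical skin–lesion contrast**:
`(median of gray above the Otsu threshold − median below)/2`. Background
growth then stops at the half-amplitude crossing of the lesion edge, the
unbiased boundary estimate for an edge blurred by a symmetric kernel. A
substantially smaller tolerance stops the background early on the blur ramp
and systematically inflates the lesion by about the blur width (≈ 1.3 px
here, which alone costs ~3 % border error at radius 40); a substantially
larger one risks leaking through low-contrast boundary sections. The
tolerance is exposed (`--tolerance`) for images where the bimodal-histogram
assumption fails.

The lesion is the largest 4-connected component of the background's
complement, interior holes filled. Its boundary is traced with
Moore-neighbor tracing (clockwise from the topmost-leftmost boundary pixel,
terminating when the initial trace state recurs).

## Features

All 23 features are finite by construction (guards below) and, except for
the two axis lengths, invariant to rotation and scale up to digitization
effects.

*Shape*: axis lengths of the second-moment ellipse; eccentricity as their
ratio; elongation `1 − short/long` of the minimum-area rotated bounding
box (shapely); compactness `4πA/P²` with the Crofton perimeter (the
chain-length perimeter overestimates by ~5 % on digitized discs, which
would push a disc's compactness to 0.91; Crofton keeps it ≥ 0.97), clipped
at 1; rectangularity area/box-area; convexity hull-perimeter over contour
perimeter; solidity from regionprops. *Ellipse variance* is the variance of
the radial residuals between contour points and the fitted second-moment
ellipse, normalized by the squared mean radius.

*Symmetry distance*: the contour is resampled to n = 64 equal-arc-length
vertices, centered on the vertex centroid and scaled to unit mean radius —
making SD translation/scale invariant exactly. For each mirror axis on a
180-step grid the vertices are matched to their reflected, order-reversed
images over all cyclic shifts (the nearest mirror-symmetric shape averages
matched pairs, so per-vertex displacement is half the pair distance); the
best grid cell is then refined by bounded scalar minimization over the axis
angle, which restores rotation invariance to ~1e-9 despite the finite grid.
Self-intersecting input contours are rejected; the pipeline repairs raster
traces (which may self-touch at one-pixel spurs) through a polygon
`buffer(0)` before resampling.

*Color*: `ln(σ/μ)` per channel (R, G, B, intensity norm) over lesion
pixels, population σ. A constant channel (σ = 0) is floored at −10 — a
value below anything a nonconstant 8-bit channel can produce.

*Texture*: gray values are uniformly quantized to 64 levels (256
available). Co-occurrence counts include only pixel pairs with **both**
endpoints inside the lesion mask — the reason this is hand-vectorized
rather than delegated to a library GLCM, none of which mask the pairs —
and are symmetrized. Eight Haralick statistics (max probability, energy,
entropy in bits with 0·log 0 = 0, dissimilarity, contrast, inverse
difference, inverse difference moment, correlation with a zero-marginal-σ
guard) are averaged over the four single-pixel offsets (1,0), (0,1),
(1,1), (1,−1); the variance of entropy over the orientations is emitted as
an anisotropy cue. The bank is 23 features (8 shape + SD + 4 color + 8
texture means + entropy variance + ellipse variance).

*Scaling*: per-feature min–max from training rows only, mapping to exactly
[−1, 1]; constant training columns map to 0; test values are not clipped.

## Selection, classifier, evaluation

CFS uses absolute Pearson correlations (point-biserial against the 0/1
label) on raw feature values and Hall's square-root merit. The search is
greedy-forward with patience 5: keep adding the single best feature
(lexicographic tie-break), stop after five consecutive additions that fail
to improve the best merit seen, return the best subset. On ≤ 12 features
this provably-heuristic search matched exhaustive enumeration in all test
instances. Note the merit does not forbid co-selecting correlated features
in general — with several informative features a duplicate of the strongest
can raise the merit — but two copies of a lone informative feature among
noise are never co-selected.

The SVM solves the standard soft-margin problem via an established dual
solver (scikit-learn's SVC); the fitted model is stored explicitly (support
vectors, signed dual coefficients, bias) so the decision function
`Σᵢ αᵢyᵢ K(svᵢ, x) + b` is evaluated by this package and round-trips
through JSON. Defaults C = 10, γ = 0.1; a 4×4 grid (C ∈ {0.1, 1, 10, 100},
γ ∈ {0.01, 0.1, 1, 10}) is searchable by stratified-CV balanced accuracy.
Decision value exactly 0 classifies as malignant.

Cross-validation is stratified (plain shuffled folds when k exceeds the
smaller class, e.g. leave-one-out), with CFS and scaling refitted inside
every training fold; per-fold confusion counts are summed and the ROC pools
the held-out decision values. Sensitivity is TP/(TP+FN), specificity
TN/(TN+FP) — note TN+FP, the count of truly negative samples, in the
denominator. AUC is trapezoidal over the threshold sweep and equals the
normalized Mann–Whitney U statistic, which the tests assert to 1e-10.

## Problem sizes and numerical choices

The acceptance-grade checks run at: 200 images per dataset (70 malignant /
130 benign) for segmentation error and classifier recovery (five
independent dataset seeds for the latter), 20 label-permutation repeats for
the null-AUC check, 50 random 8×8 images for the GLCM oracle, 3600 axis
angles for the symmetry-distance oracle, and exhaustive subset enumeration
up to 10 features for CFS. Degenerate inputs are rejected with explanatory
errors rather than silently patched: masks under 10 px, empty truth masks,
single-class training data, k outside [2, n], non-positive C/γ, frames
covering > 50 % of an image.

## Known limitations

- The synthetic classes are cleanly separable; expected accuracy on real
  dermoscopy images is far below the synthetic figures and must be
  established on clinical data.
- Hair detection assumes dark hairs; light hairs are only attenuated by the
  Gaussian smoothing. Dense hair meshes that occlude the lesion boundary
  will degrade segmentation.
- Region growing assumes a bimodal gray histogram; multi-lesion images or
  strong illumination gradients violate the single-background model.
- The symmetry-distance axis search is exact only up to the 1° grid plus
  local refinement; a pathological contour whose cost landscape has minima
  narrower than the grid step could be mis-scored.
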