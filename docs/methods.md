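# Methods

This note records the model, the defaults and the design decisions of
`lesionbow` in enough detail to reimplement it.

## Problem and data model

The system retrieves patients with similar focal liver lesions from
triple-phase contrast-enhanced CT. Inputs are 2-D grayscale slices, one
binary lesion mask per slice, and a CSV manifest
(`patient_id,label,phase,image,mask`) with labels in
{HCC, hemangioma, cyst} and phases in {AP, PVP, DP}. Every feature
computation happens in a fixed 8-bit gray domain with background 0;
DICOM input is converted by applying the rescale slope/intercept and a
linear window (default liver window WL = 60, WW = 200 HU, configurable)
that maps the window center to gray 128 and saturates exactly at the
window edges. The windowing default is our choice — the 8-bit domain is
required both by the raw-intensity patch descriptors and by the
background-is-zero patch filter, but no canonical normalization exists
for this task. 8-bit rasters (e.g. phantom fixtures) pass through
unchanged. Masks and images are indexed (row, col), 0-based; all boxes
are half-open.

## Lesion partitioning

The city-block (L1) distance transform is used because its values are
integers, making the layer grouping exact; the grid border counts as
background, so a lesion touching the crop edge still starts at layer 1.
With L layers and s regions, `p = L // s`, `q = L % s`: regions
1..s−1 (outer) get p layers each and the innermost gets p + q, which
tiles {1..L} for every (L, s). (A per-region reading of "p, q, p+q"
layers does not sum to L; the implemented rule is the consistent
variant.) When L < s, the outermost regions get one layer each and the
rest stay empty rather than failing — small cysts must remain
processable. The surrounding parenchyma region s+1 is the
margin-expanded (2 px per side) bounding box minus the lesion,
including box corners: the box, not a morphological ring, defines it,
and all non-lesion box pixels are kept because the method has no tissue
segmentation to exclude non-liver content. The ROI crop is the expanded
box clipped at image borders.

## Regional bag of visual words

* Patches: 7×7 raw-intensity windows centered at every crop pixel with
  a nonzero region label (parenchyma included — its words carry the
  enhancement contrast that distinguishes the classes). Windows
  reaching past the crop are zero-padded.
* Filter: a patch is kept only if strictly more than 15 of its 49
  values are nonzero (background gray is 0).
* Codebook: one global K-means vocabulary shared by all regions and
  phases; region identity is carried by concatenation position, not by
  per-region vocabularies. Training pools all kept patches of the
  training-fold images (of the configured phase subset), subsampled
  uniformly with a seed to at most 100 000 descriptors. K-means uses
  k-means++ initialization, a single seeded restart, ≤ 300 iterations,
  relative tolerance 1e-4; requesting more words than distinct
  descriptors fails with advice to shrink N.
* Assignment: nearest word by Euclidean distance, ties to the lowest
  index (so duplicating a word never changes any assignment).
* Histograms: per-region counts divided by the region's kept-patch
  count ("probability density over the code words"); an empty region
  contributes an all-zero block. Raw counts are retained as
  `n_patches` for auditing. Image descriptor = concatenation over
  regions 1..s, s+1, dimension (s+1)·N.
* Patient features: element-wise mean of the patient's image features
  whose phase lies in the configured subset; a patient without any such
  image raises an explicit skip signal.

## Low-level feature bank (93 values)

Computed per ROI in a fixed order; intensity, GLCM and Gabor statistics
are restricted to lesion pixels (region labels 1..s).

* Intensity (5): mean, population sd, base-2 entropy of the 256-bin
  normalized histogram, skewness, non-excess kurtosis; skewness and
  kurtosis are defined 0 for a constant region.
* GLCM (16): gray levels quantized to 32 bins (`g*32//256`); symmetric,
  normalized co-occurrence matrices at distance 1 and angles
  0°/45°/90°/135° counting only pairs whose both pixels are lesion
  pixels; statistics contrast, homogeneity `Σ P/(1+(i−j)²)`, energy
  `sqrt(Σ P²)` and correlation (defined 0 when a marginal variance is
  0), ordered statistic-major over ascending angles. A pair-less angle
  contributes (0, 1, 1, 0) with a warning. Quantization to 32 bins and
  the symmetric matrix are standard practice and keep small lesions
  from producing near-singular matrices.
* Gabor (48): 4 center frequencies one octave apart (0.05, 0.1, 0.2,
  0.4 cycles/pixel) × 6 orientations kπ/6; per filter the response
  magnitude over lesion pixels summarized by mean and sd
  (frequency-major, mean before sd). Filtering uses reflective
  boundaries, so crops smaller than the kernel are handled without
  failure. "Energy" is read as response magnitude rather than an
  FFT-domain sum; the two differ only by Parseval bookkeeping for the
  summaries used here.
* Wavelet texture (12): 3-level 2-D Daubechies-4 decomposition of the
  crop with non-lesion pixels replaced by the lesion mean gray value
  (so a constant lesion yields exactly zero detail statistics, and the
  features do not depend on parenchyma content), padded to at least
  16×16 with the same fill; per level the horizontal and vertical
  detail subbands give mean and sd of absolute coefficients, coarse to
  fine. Keeping two of the three detail subbands (diagonal dropped) is
  what makes the count 12 rather than 18; the diagonal subband of
  near-isotropic lesions carries the least signal, so it is the one
  discarded.
* Shape (12): the radial-distance signature
  `S(i) = sqrt((x(i)−C_x)² + (y(i)−C_y)²)` is computed from the outer
  boundary polygon of the (largest, if several) lesion component,
  traced at the half-pixel silhouette level with a fixed clockwise
  orientation and topmost-then-leftmost start, arc-length resampled to
  128 points; the centroid is that of the filled region. A 5-level 1-D
  Daubechies-4 decomposition gives 6 subbands (approximation + 5
  details, coarse to fine), each summarized by mean and variance of
  absolute coefficients. The subpixel contour is used instead of pixel
  centers because staircase corners of rasterized shapes otherwise
  deviate from the true silhouette by up to a pixel; 128 samples exceed
  the advisory maximum depth for 5 levels (4), which only means the
  coarsest subband is boundary-dominated — acceptable for summary
  statistics and kept for the fixed 6-subband layout.

## Metric learning

Features are z-scored with training statistics before any fit; the
statistics live in the fitted model so query-time transforms match.
Identity models (plain L1/L2) deliberately skip normalization — they
operate in the raw feature space.

* PCA: centered, full SVD, deterministic sign convention
  (largest-magnitude loading positive).
* RLDA: PCA to min(M−1, d) (M training patients; the BoW dimension far
  exceeds M), then the leading generalized eigenvectors of
  `S_b v = λ (S_w + αI) v` with raw (unnormalized) scatter matrices and
  unscaled α = 0.001; C−1 directions kept for C classes. Classes with
  fewer than 2 samples are rejected.
* LDP: covariance A of within-class and B of between-class sample
  differences over all pairs (seeded uniform subsample above 10⁵ pairs
  per kind); projection = top out_dim generalized eigenvectors of
  `B v = λ (A + εI) v`, ε = 1e-6·trace(A)/d, default
  out_dim = min(64, M−1). This difference-covariance construction is
  normative for this package: it has the defining properties claimed
  for the approach (descriptor-level, no nearest-neighbor search,
  fast), and the generalized eigenbasis whitens within-class
  differences (`Wᵀ(A+εI)W = I`), which the tests verify.
* Learned projections pair with L2 in the projected space; the
  post-projection metric is a package choice.

## Evaluation protocol

Patients are the unit of query and retrieval. Folds are stratified by
label (each class dealt, after a seeded shuffle, to the currently
smallest fold), so fold sizes differ by at most one; stratification is
a package choice over plain even division, and the splitter is a small
hand-rolled routine because the per-class deal must balance overall
fold sizes simultaneously. Per fold, the codebook, any projection and
all normalization statistics are fitted on training folds only; each
test patient then queries the training-patient database (querying the
training folds avoids both self-retrieval and leakage; the alternative
— querying everything but the query — would let test patients see each
other). Relevance is same-disease. Ties in ranking break by patient id.

P(n) is the mean over queries of Eq.-style precision after n retrieved
patients, for every n up to the database size (no truncation at the
relevant count). MAP is the mean of P(n) over n = 1..T — *not* the
conventional IR mean average precision — and therefore saturates at
`(R + R·(H(T) − H(R)))/T` for R relevant in T. Reports carry P(n), MAP
(mean of per-fold MAPs), per-fold breakdowns with fold membership for
leakage audits, and uninterpolated PR-curve points; "combined" features
concatenate the regional-BoW and 93-feature blocks after per-block
z-scoring with training statistics.

## Phantom generator

The generator emulates the class-conditional enhancement patterns on
which the method's discriminative power rests, not liver anatomy. Per
patient one elliptical lesion geometry (semi-axes 8–16 px in a 96×96
frame) is reused across 3–10 images covering all three phases (the
lower bound is 3 because phase coverage is required), with one-pixel
center jitter per image. Zone means (8-bit gray): parenchyma 110/150/130
in AP/PVP/DP (peaking in PVP); HCC lesion 170/110/105; hemangioma rim
200/170/150 and core 90/120/145 (rim = outer third of the city-block
layers, reusing the partition machinery, so hemangioma phantoms
genuinely exercise the regional structure); cyst 40 in every phase.
Additive Gaussian noise (default sd 5) is clipped to [0, 255]; masks
are exact ellipse rasters. Everything is a pure function of
(parameters, seed), to the byte.

What the phantoms do **not** model: anatomical context, vessels,
partial-volume and beam-hardening effects, CT noise spectra,
inter-patient texture variability beyond i.i.d. noise. Passing the
end-to-end tests therefore shows the pipeline is correct and the
features separate the encoded enhancement patterns — it does not
predict clinical retrieval accuracy on hospital data.

## Problem sizes and numerical conventions

The default experiment used by tests and the reproduction script runs
15 phantom patients (5 per class), a 64-word codebook, s = 3 and 5-fold
cross-validation; with 12-patient databases and 4 relevant per query a
perfect ranking yields P(4) = 1, P(5) = 0.8 and MAP ≈ 0.6733, and the
pipeline reaches exactly those ceilings for both L2 and RLDA. The
codebook-training pool cap (100 000 descriptors), k-means tolerance
(1e-4), RLDA α (0.001), LDP ε (1e-6·trace(A)/d) and the degenerate-case
conventions (empty-region zero histograms, correlation 0 at zero
marginal variance, skewness/kurtosis 0 for constant regions, one-layer
regions for L < s) are stated above next to their operations. All
randomness flows from explicit integer seeds; per-fold seeds are
derived from the experiment seed by fixed affine maps.

## Known limitations

* MAP follows the mean-of-P(n) definition; numbers are not comparable
  to conventional IR MAP without the ceiling correction given above.
* The LDP construction is normative for this package (see above);
  other difference-based discriminant projections exist.
* GLCM gray-level binning (32) and the Gabor bank parameters are
  standard but not canonical; changing them changes the 93-feature
  bank's values, though not its layout.
* Only single-frame 2-D slices are supported — no 3-D volumes,
  multi-frame DICOM, or automatic segmentation (masks are inputs).
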