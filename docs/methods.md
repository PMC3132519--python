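# Methods

## Segmentation model

Boundary detection is cast as binary per-pixel classification: 1 = boundary
(foreground), 0 = background. The classifier is a soft-margin SVM over a
33-dimensional description of each pixel's 3 × 3 neighbourhood:

* columns 1–9: the raw intensity patch, row-major, centre at position 5;
* columns 10–27: the orientation dominance field sampled at the same nine
  positions, two vector components per position (v1 before v2);
* columns 28–33: median, range, energy ΣI², and central moments
  M_r = (1/9) Σ (I_i − μ)^r for r = 2, 3, 4 of the intensity patch.

The intensity patch lets the classifier distinguish a supported boundary
pixel from an isolated pixel of identical intensity; the orientation patch
adds illumination-robust structural context; the statistics summarise local
contrast and spread. All 3 × 3 extractions (and the filter banks) use
reflect padding so border pixels have well-defined features without
fabricating dark rims that would mimic boundaries.

### Orientation dominance field

The field is computed from a Gaussian structure tensor: image derivatives
from Gaussian-derivative (band-pass) filters at scale σ_d = 1 px, smoothed
outer products at integration scale σ_i = 2 px. The output vector at each
pixel is

    (v1, v2) = −(Jxx − Jyy, 2 Jxy) / (Jxx + Jyy + ε),   ε = 1e−6,

whose direction is the double angle 2θ of the dominant structure
orientation (θ and θ + 180° coincide, removing the sign ambiguity of thin
lines) and whose magnitude is the anisotropy (λ₁ − λ₂)/(λ₁ + λ₂) ∈ [0, 1]:
0 on isotropic neighbourhoods, ≈1 on an ideal line. The negation converts
the tensor's dominant *gradient* direction into the *structure* direction.
Because the inputs are derivative filters, constant offsets vanish exactly
and slow illumination trends nearly so; on the standard noisy phantom a
shading trend of amplitude 0.02 changes the orientation columns by < 1 %
RMS while the raw intensity columns move several times more. The ε floor
means that on *exactly flat, noiseless* regions an added linear ramp can
register as oriented structure; in any image with realistic noise the noise
gradients dominate the denominator and the quasi-invariance holds.

### Normalisation

Feature columns are standardised to zero mean and unit variance using
statistics of the *training* matrix only (population 1/N convention, stated
so train and test transforms agree exactly). Zero-variance training columns
are centred but not scaled, flagged in the stored statistics, and warned
about. Test images are always transformed with the embedded training
statistics.

### SVM

Kernels: RBF (default), sigmoid, polynomial, linear, via libsvm
(scikit-learn `SVC`). Default operating point: C = 1, γ = 0.14 — the
published setting for this feature space. Solver tolerance is fixed at
1e−3 and shrinking is deterministic, so training twice on identical input
yields identical decision functions. No class weighting by default (a
`class_weight='balanced'` flag exists). Masks are stored with 1 = boundary;
PNG export renders boundaries black on white.

The (C, γ) grid search uses stratified k-fold cross-validation on per-pixel
accuracy. The default grid is desk-scale (log₁₀C ∈ −4…4 step 1,
γ ∈ 0.02…0.2 step 0.02); the full published-protocol grid (step 0.1 in
log₁₀C, γ 0.1…2 step 0.001 — a cluster-scale search of ~150k points) is
available behind `full_grid=True`. Ties resolve toward lower C, then lower
γ. The γ sweep (0.02…0.14 step 0.01, C = 1, all four kernels) reports
pooled accuracy over the supplied test sets; the linear kernel ignores γ,
so its column is constant by construction.

## Classical baselines

* **Otsu**: threshold maximising between-class variance w₀w₁(μ₀ − μ₁)² on a
  256-level histogram spanning the image's intensity range.
* **Kittler–Illingworth**: threshold minimising the two-Gaussian
  minimum-error criterion J(t) = 1 + 2(w₀ln σ₀ + w₁ln σ₁) − 2(w₀ln w₀ +
  w₁ln w₁); candidates with an empty or zero-variance class are skipped.
* Both return their full criterion curve; ties across flat plateaus (an
  empty histogram valley makes the criterion exactly constant) resolve to
  the plateau centre. Dark side = boundary by default.
* **Canny**: scikit-image's implementation (Gaussian gradients, non-maximum
  suppression, hysteresis) with quantile thresholds; σ = 1 px default. The
  comparison operating point is (low, high) = (0.7, 0.9) gradient
  quantiles — a practitioner's strong-edge setting. On thin dark lines
  Canny marks the two flanking edges rather than the centreline, which
  structurally limits its per-pixel accuracy against centreline ground
  truth.

ROC families: 63 evenly spaced global thresholds for the histogram methods
and a 31 × 31 hysteresis grid (31 high-threshold quantiles in [0, 0.98] ×
31 low/high fractions in [0, 1], all 961 settings valid) for Canny.

## mRMR feature ranking

Features are discretised to three levels at mean ± 0.5σ (the convention of
the original mRMR work). Mutual information is the empirical plug-in
estimate in bits. Ranking is greedy forward selection in the MID
(difference) form — relevance minus mean redundancy with the selected set —
with ties broken toward the lower column index; MIQ is available by flag.
Because patch-based properties contribute nine (or eighteen) correlated
columns each, single positions of one property scatter through the ranking;
`grouped_relevance` therefore counts each property group's members among
the top-K ranks, reports the group's enrichment relative to its share of
all 33 features, and flags a group for whole-patch inclusion when its
members exceed half the group size within the top K.

## Phantom generator

The generator emulates stained-monolayer images with exact ground truth:

* **Mosaic**: n_cells random sites; a pixel is boundary when it lies within
  boundary_width/2 of the bisector between its two nearest sites ((d₂ −
  d₁)/2 is the exact distance to the Voronoi edge). Defaults: 50 cells on
  256 × 256 px, boundary_width 2 px (cells ≈ 32 px across, boundary
  fraction ≈ 0.15). The evaluation suite uses 128 × 128 / 16 cells — the
  same cell scale at the published test-patch size.
* **Intensities**: boundary 0.10, background 0.50. The silver stain is
  nearly black, so with realistic noise the boundary class clips at 0 and
  is visibly non-Gaussian — a property real stained material shares, and
  the reason the minimum-error threshold loses its usual edge over Otsu
  here (the two end up statistically tied, as in the original comparison).
* **Noise**: additive Gaussian, σ = 0.12 by default, clipped to [0, 1] —
  strong enough that boundary/background histograms overlap substantially
  and no global threshold approaches the SVM. (Gaussian is the minimal
  model for this overlap; Poisson noise is out of scope.)
* **Gaps**: 5 % of boundary pixels revert to background intensity in the
  image; the ground-truth mask keeps the complete network, so gap pixels
  are unavoidable errors for any intensity-only segmenter.
* **Speckles**: isolated boundary-intensity pixels (density 0.002 px⁻²)
  placed ≥ 2 px from any boundary so they have no supporting neighbours —
  the canonical confusable case for thresholding.
* **Illumination / seams**: an additive second-order polynomial surface on
  coordinates normalised to [−1, 1] (x = col, y = row) and an additive
  intensity step right of a seam column; both off by default and matched by
  the corrections in `preprocess`.

Identical config + seed gives bit-identical output. What the phantoms do
*not* model: optics/PSF blur, Poisson photon statistics, stain-uptake
texture within cells, montage stitching geometry. Passing results on
phantoms therefore demonstrate the machinery and its qualitative behaviour
(feature discrimination, method ordering, illumination robustness), not
performance on any particular microscope's data.

## Evaluation protocol

Accuracy is strict per-pixel (no tolerance band; an optional ±k px
tolerant mode exists behind a flag but is never used in the shipped
protocol), borders included. The standard comparison runs ten phantoms
(seeds base…base+9 at the standard difficulty), trains the SVM on a
62 × 62 patch of each (3844 training pixels), applies it to the full
128 × 128 image (16 384 pixels), and evaluates the baselines at their
automatic operating points. Under these conditions the mean accuracies
order SVM-RBF > Otsu ≈ Kittler > Canny, with the SVM roughly ten points
clear of the best threshold.

Two sanity regimes bound the difficulty: with all degradations off the
image is two-level and both midpoint thresholding and the SVM (trained on
the full phantom) reach exactly 100 %; a 62 px training patch reaches
99.9 %+ but can miss rare junction geometries absent from the patch. At the
standard difficulty an SVM trained on a noiseless speckled phantom rejects
every isolated speckle while keeping > 99 % of true boundary pixels of the
same intensity.

## Known limitations

* The orientation-dominance construction implements the stated properties
  (band-pass origin, double-angle direction, [0, 1] anisotropy magnitude);
  other constructions with the same properties would differ in detail.
* Kittler's criterion can collapse to an extreme threshold on strongly
  non-bimodal histograms (e.g. under heavy uncorrected shading); this is a
  property of the method, not a bug, and is why illumination correction
  precedes thresholding in practice.
* Per-pixel accuracy rewards thin predictions near dense boundaries; it is
  kept as the headline metric for comparability, with ROC curves available
  for operating-point-free comparison.
* The mixture analysis in `preprocess` uses supervised class histograms
  (64 bins on [0, 1] by default); unsupervised EM fitting is out of scope.
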