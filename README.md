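# endoseg

Pixel-wise SVM segmentation of thin cell-boundary networks in light
microscopy, with classical thresholding/edge baselines and a synthetic
phantom benchmark.

## The problem

Silver staining renders the boundaries between endothelial cells (the
monolayer lining blood vessels) as thin — one to two pixel — dark curves on
a noisy, unevenly illuminated background. The intensity histograms of
boundary and background pixels overlap strongly, so no global threshold
separates the classes: an isolated noise pixel can have exactly the
intensity of a boundary pixel. What distinguishes them is the *spatial
configuration of their neighbourhood*, which is what this package exploits.

Accurate boundary maps matter because endothelial cells elongate and align
with blood flow; segmenting tens of thousands of cells automatically makes
it possible to map patterns of haemodynamic shear stress around arterial
branches from cell morphology.

## The method

Every pixel is mapped to a 33-dimensional feature vector from its 3 × 3
neighbourhood:

    FV = [ I(3×3),  O(3×3),  Med, Range, E, M2, M3, M4 ]

* **I(3×3)** — the nine raw intensities (row-major, centre fifth);
* **O(3×3)** — the orientation dominance field at the nine positions, two
  components per position. The field encodes the locally dominant structure
  orientation in double-angle form with magnitude (λ₁ − λ₂)/(λ₁ + λ₂) ∈
  [0, 1] of the Gaussian-derivative structure tensor — 0 on isotropic
  neighbourhoods, 1 on strongly oriented ones. Being built from band-pass
  filters, these 18 features are quasi-invariant to slow illumination
  trends;
* **Med, Range, E, M₂, M₃, M₄** — median, range, energy ΣI², and the
  central moments (1/n)Σ(Iᵢ − μ)^r, r = 2, 3, 4, of the intensity patch.

Features are standardised per column (training statistics, population
variance) and classified by a support vector machine — RBF kernel, C = 1,
γ = 0.14 by default — trained on a small labelled sample region (62 × 62
px = 3844 pixels). Per-pixel accuracy is

    Accuracy% = 100 · (TP + TN) / (TP + TN + FP + FN)

against ground-truth masks. The package also provides Otsu and
Kittler–Illingworth minimum-error thresholding and Canny edge detection as
baselines, mRMR (minimum-redundancy maximum-relevance) feature ranking, ROC
sweeps (63 thresholds for the histogram methods, a 31 × 31 hysteresis grid
for Canny), and a monolayer phantom generator (Voronoi mosaic, boundary
gaps, boundary-intensity speckles, polynomial illumination, montage seams)
with exact ground truth.

## Worked example

```python
from endoseg import (PhantomConfig, generate_monolayer_phantom,
                     sample_training_patch, PixelBoundarySVM,
                     otsu_threshold)
from endoseg.evaluate import mask_accuracy

cfg = PhantomConfig(width=128, height=128, n_cells=16, seed=0)
image, mask = generate_monolayer_phantom(cfg)

patch, patch_mask = sample_training_patch(image, mask, 62, seed=1)
model = PixelBoundarySVM().fit_image(patch, patch_mask)   # rbf, C=1, γ=0.14
print("support vectors:", model.n_support_vectors_)
print("SVM accuracy:   %.2f%%" % mask_accuracy(model.predict_image(image), mask))
print("Otsu accuracy:  %.2f%%" % mask_accuracy(otsu_threshold(image).mask, mask))
```

prints

```
support vectors: 1139
SVM accuracy:   99.04%
Otsu accuracy:  91.85%
```

The SVM recovers ~99 % of pixels on this standard-difficulty phantom while
the automatic global threshold stays several points behind — the
neighbourhood features, not the intensity alone, carry the decision.

The same pipeline is available from the shell:

```
endoseg pipeline --out run/ --seed 5        # simulate → train → segment → evaluate
endoseg baseline --method kittler --image run/phantom.png --out kittler.png
```

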