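"""Illumination correction and intensity-mixture analysis.

The spatially varying sensitivity of microscope + camera shades each
acquisition; this is modelled as an additive second-order polynomial surface
and removed by a least-squares fit.  Montage seams (intensity steps between
adjacent acquisitions) are compensated additively from strip means on either
side.  A supervised two-component intensity mixture

    P(i) = P_O * P(i|O) + P_b * P(i|b)

fitted from labelled boundary (object, O) and background (b) pixels
quantifies how strongly the two class-conditional intensity histograms
overlap — the reason global thresholding fails on this material.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import quadratic_surface, _normalized_grid


def _design_matrix(shape):
    X, Y = _normalized_grid(shape)
    x, y = X.ravel(), Y.ravel()
    return np.column_stack([np.ones_like(x), x, y, x * x, x * y, y * y])


def fit_quadratic_background(image: np.ndarray) -> np.ndarray:
    """Least-squares coefficients of the second-order illumination surface.

    Uses the same (c0, cx, cy, cxx, cxy, cyy) basis on [-1, 1]-normalised
    coordinates as :func:`endoseg.phantom.apply_illumination`, so fit and
    forward model round-trip.
    """
    image = np.asarray(image, dtype=float)
    if image.size < 6:
        raise ValueError("need at least 6 pixels to fit 6 coefficients")
    A = _design_matrix(image.shape)
    coeffs, _, rank, _ = np.linalg.lstsq(A, image.ravel(), rcond=None)
    if rank < 6:
        raise ValueError(
            f"rank-deficient design (rank {rank} < 6); image shape "
            f"{image.shape} cannot constrain a quadratic surface"
        )
    return coeffs


def subtract_background(image: np.ndarray, coeffs) -> np.ndarray:
    """Remove the polynomial trend, preserving overall brightness.

    The surface's global mean is added back so the corrected image stays in
    displayable range; output is clipped to [0, 1].
    """
    image = np.asarray(image, dtype=float)
    surface = quadratic_surface(image.shape, coeffs)
    return np.clip(image - surface + surface.mean(), 0.0, 1.0)


def compensate_seam(image: np.ndarray, column: int, strip_width: int) -> np.ndarray:
    """Additively match strip means across a montage seam.

    Adds (mean of the strip left of ``column`` - mean of the strip right of
    it) to every pixel with col >= column.
    """
    image = np.asarray(image, dtype=float)
    w = image.shape[1]
    if strip_width < 1:
        raise ValueError("strip_width must be >= 1")
    if column - strip_width < 0 or column + strip_width > w:
        raise ValueError(
            f"strip of width {strip_width} does not fit on both sides of "
            f"column {column} in an image of width {w}"
        )
    left = image[:, column - strip_width : column].mean()
    right = image[:, column : column + strip_width].mean()
    out = image.copy()
    out[:, column:] += left - right
    return out


@dataclass
class MixtureModel:
    """Supervised two-class intensity mixture over an equal-width bin grid."""

    prior_object: float
    prior_background: float
    bin_edges: np.ndarray          # n_bins + 1 edges on [0, 1]
    conditional_object: np.ndarray      # P(i|O), sums to 1
    conditional_background: np.ndarray  # P(i|b), sums to 1

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def total(self) -> np.ndarray:
        """P(i) = P_O P(i|O) + P_b P(i|b)."""
        return (
            self.prior_object * self.conditional_object
            + self.prior_background * self.conditional_background
        )

    def overlap_coefficient(self) -> float:
        """Histogram overlap sum_i min(P(i|O), P(i|b)) in [0, 1]."""
        return float(
            np.minimum(self.conditional_object, self.conditional_background).sum()
        )

    def bayes_accuracy(self) -> float:
        """Accuracy (%) of the optimal per-bin intensity classifier."""
        correct = np.maximum(
            self.prior_object * self.conditional_object,
            self.prior_background * self.conditional_background,
        ).sum()
        return float(100.0 * correct)


def fit_intensity_mixture(image, mask, n_bins: int = 64) -> MixtureModel:
    """Fit the supervised mixture from labelled boundary/background pixels.

    Priors are the class pixel fractions; conditionals are normalised
    per-class histograms over ``n_bins`` equal-width bins on [0, 1].
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask)
    if image.shape != mask.shape:
        raise ValueError("image and mask shapes differ")
    obj = image[mask == 1]
    bg = image[mask == 0]
    if obj.size == 0 or bg.size == 0:
        raise ValueError("mask must contain both boundary and background pixels")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    h_obj, _ = np.histogram(obj, bins=edges)
    h_bg, _ = np.histogram(bg, bins=edges)
    n = obj.size + bg.size
    return MixtureModel(
        prior_object=obj.size / n,
        prior_background=bg.size / n,
        bin_edges=edges,
        conditional_object=h_obj / obj.size,
        conditional_background=h_bg / bg.size,
    )


def best_global_threshold_accuracy(image, mask, n_candidates: int = 256):
    """Best achievable accuracy (%) of any single global intensity threshold.

    Scans ``n_candidates`` thresholds on [0, 1] with the dark side labelled
    boundary; reports the maximum per-pixel accuracy against the mask.  Used
    to demonstrate that no global threshold matches the patch-feature SVM on
    overlapping class histograms.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask).astype(bool)
    thresholds = np.linspace(0.0, 1.0, n_candidates)
    best_acc, best_t = -1.0, thresholds[0]
    n = mask.size
    for t in thresholds:
        pred = image <= t
        acc = 100.0 * np.count_nonzero(pred == mask) / n
        if acc > best_acc:
            best_acc, best_t = acc, t
    return best_acc, float(best_t)
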