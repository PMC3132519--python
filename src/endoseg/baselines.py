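"""Classical segmenters used as comparison baselines.

Otsu (maximum between-class variance) and Kittler-Illingworth (minimum
classification error under a two-Gaussian histogram model) global
thresholding, and Canny edge detection.  Boundaries are dark in
silver-stained material, so by default the sub-threshold side of a threshold
is labelled boundary.

Both thresholding methods return their full criterion curve so the selected
threshold can be checked against an exhaustive scan, and sweep helpers
produce the mask families used for ROC construction: a 63-point threshold
sweep for the histogram methods and a 31 x 31 = 961-setting
(low, high)-hysteresis sweep for Canny.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.feature import canny as _skimage_canny


@dataclass
class ThresholdResult:
    """Outcome of an automatic histogram-thresholding method."""

    threshold: float
    mask: np.ndarray                 # 1 = boundary
    candidates: np.ndarray           # candidate thresholds evaluated
    criterion_curve: np.ndarray      # criterion value per candidate (NaN = skipped)
    method: str = ""


def _plateau_argopt(criterion, opt) -> int:
    """Index of the optimal criterion value; ties (flat plateaus, e.g. an
    empty histogram valley) resolve to the middle of the optimal set."""
    best = opt(criterion)
    ties = np.flatnonzero(criterion == best)
    return int(ties[ties.size // 2])


def _histogram(image, n_levels):
    image = np.asarray(image, dtype=float)
    lo, hi = image.min(), image.max()
    if lo == hi:
        raise ValueError("image is constant; no threshold exists")
    counts, edges = np.histogram(image, bins=n_levels, range=(lo, hi))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return counts.astype(float), centers


def otsu_threshold(image, n_levels: int = 256, dark_boundary: bool = True) -> ThresholdResult:
    """Threshold maximising between-class variance on an n_levels histogram.

    Candidate t splits the histogram after bin t; the criterion is
    w0 * w1 * (mu0 - mu1)^2.  The dark side is labelled boundary unless
    ``dark_boundary=False``.
    """
    counts, centers = _histogram(image, n_levels)
    n = counts.sum()
    p = counts / n
    w0 = np.cumsum(p)                       # weight of the class <= candidate
    m = np.cumsum(p * centers)
    mu_total = m[-1]
    w1 = 1.0 - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m / w0
        mu1 = (mu_total - m) / w1
        criterion = w0 * w1 * (mu0 - mu1) ** 2
    criterion = np.where((w0 > 0) & (w1 > 0), criterion, np.nan)
    # last bin cannot split: force it invalid
    criterion[-1] = np.nan
    best = _plateau_argopt(criterion, np.nanmax)
    threshold = float(centers[best])
    image = np.asarray(image, dtype=float)
    mask = (image <= threshold) if dark_boundary else (image > threshold)
    return ThresholdResult(threshold, mask.astype(np.uint8), centers, criterion, "otsu")


def kittler_threshold(image, n_levels: int = 256, dark_boundary: bool = True) -> ThresholdResult:
    """Kittler-Illingworth minimum-error threshold.

    Models the histogram as two Gaussians split at the candidate and
    minimises

        J(t) = 1 + 2 (w0 ln s0 + w1 ln s1) - 2 (w0 ln w0 + w1 ln w1)

    over candidates where both tentative classes are non-empty with positive
    variance (others are skipped).
    """
    counts, centers = _histogram(image, n_levels)
    p = counts / counts.sum()
    w0 = np.cumsum(p)
    w1 = 1.0 - w0
    m0c = np.cumsum(p * centers)
    m1c = m0c[-1] - m0c
    s0c = np.cumsum(p * centers ** 2)
    s1c = s0c[-1] - s0c
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m0c / w0
        mu1 = m1c / w1
        var0 = s0c / w0 - mu0 ** 2
        var1 = s1c / w1 - mu1 ** 2
        criterion = (
            1.0
            + w0 * np.log(var0)
            + w1 * np.log(var1)
            - 2.0 * (w0 * np.log(w0) + w1 * np.log(w1))
        )
    valid = (w0 > 0) & (w1 > 0) & (var0 > 0) & (var1 > 0)
    criterion = np.where(valid, criterion, np.nan)
    if np.all(np.isnan(criterion)):
        raise ValueError("no valid Kittler threshold candidate")
    best = _plateau_argopt(criterion, np.nanmin)
    threshold = float(centers[best])
    image = np.asarray(image, dtype=float)
    mask = (image <= threshold) if dark_boundary else (image > threshold)
    return ThresholdResult(threshold, mask.astype(np.uint8), centers, criterion, "kittler")


def canny_edges(image, sigma: float = 1.0, low: float = 0.1, high: float = 0.2) -> np.ndarray:
    """Canny edge map: Gaussian-derivative gradients, non-maximum suppression
    and double-threshold hysteresis.

    ``low`` and ``high`` are gradient-magnitude quantile fractions in [0, 1]
    with low <= high.  Returns a binary mask of edge pixels.
    """
    if not (0.0 <= low <= high <= 1.0):
        raise ValueError("need 0 <= low <= high <= 1")
    image = np.asarray(image, dtype=float)
    edges = _skimage_canny(
        image, sigma=sigma, low_threshold=low, high_threshold=high, use_quantiles=True
    )
    return edges.astype(np.uint8)


# ------------------------------------------------------------------- sweeps
def threshold_sweep(image, n_thresholds: int = 63, dark_boundary: bool = True):
    """Masks at ``n_thresholds`` evenly spaced global thresholds.

    Thresholds span the image intensity range; used to trace the ROC curve
    of the histogram thresholding methods.  Returns a list of
    ``(mask, setting)`` pairs where setting is the threshold value.
    """
    image = np.asarray(image, dtype=float)
    lo, hi = image.min(), image.max()
    if lo == hi:
        raise ValueError("image is constant")
    thresholds = np.linspace(lo, hi, n_thresholds)
    out = []
    for t in thresholds:
        mask = (image <= t) if dark_boundary else (image > t)
        out.append((mask.astype(np.uint8), float(t)))
    return out


def canny_sweep(image, sigma: float = 1.0, n_low: int = 31, n_high: int = 31):
    """Canny masks over an n_low x n_high hysteresis-threshold grid.

    The high threshold takes ``n_high`` gradient quantiles in [0, 0.98] and
    the low threshold is a fraction (``n_low`` values in [0, 1]) of the high
    one, so every one of the n_low * n_high settings is valid.  Returns a
    list of ``(mask, (low, high))`` pairs.
    """
    image = np.asarray(image, dtype=float)
    highs = np.linspace(0.0, 0.98, n_high)
    fracs = np.linspace(0.0, 1.0, n_low)
    out = []
    for h in highs:
        for f in fracs:
            low = f * h
            mask = canny_edges(image, sigma=sigma, low=low, high=h)
            out.append((mask, (float(low), float(h))))
    return out
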