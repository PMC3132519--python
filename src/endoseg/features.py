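"""The 33-dimensional per-pixel feature space.

Every pixel is described by:

* columns 1-9   — the 3x3 intensity neighbourhood, row-major, centre at
  position 5 (reflect padding at borders);
* columns 10-27 — the 3x3 neighbourhood of an orientation dominance field,
  two vector components (v1, v2) per patch position, v1 before v2;
* columns 28-33 — six statistics of the 3x3 intensity patch: median, range,
  energy sum(I_i^2), and the second, third and fourth central moments
  M_r = (1/n) sum (I_i - mu)^r with n = 9.

The orientation dominance field encodes, at each pixel, the locally dominant
structure orientation in a sign-unambiguous double-angle representation with
a magnitude in [0, 1] measuring anisotropy (0 on isotropic neighbourhoods, 1
on strongly oriented ones).  It is built from a local second-moment
(structure-tensor) description using Gaussian-derivative band-pass filters,
so constant offsets and slow illumination ramps leave it nearly unchanged —
the property that lets the classifier cope with uncorrected shading.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.ndimage import gaussian_filter

#: Column names in feature-vector order.
FEATURE_NAMES: tuple = tuple(
    [f"I{k}" for k in range(1, 10)]
    + [f"O{k}_{c}" for k in range(1, 10) for c in ("v1", "v2")]
    + ["Med", "Range", "E", "M2", "M3", "M4"]
)

#: Property group of each column: intensity (9), orientation (18), statistic (6).
FEATURE_GROUPS: tuple = tuple(["intensity"] * 9 + ["orientation"] * 18 + ["statistic"] * 6)

N_FEATURES = 33


def orientation_dominance(
    image: np.ndarray,
    scale: float = 1.0,
    integration_scale: float = 2.0,
    eps: float = 1e-6,
) -> np.ndarray:
    """Per-pixel orientation dominance vectors (v1, v2).

    Gaussian-derivative filters at ``scale`` give band-pass gradient images;
    their smoothed outer products (integration at ``integration_scale``) form
    the local structure tensor J.  The returned vector is

        (v1, v2) = -(Jxx - Jyy, 2 Jxy) / (Jxx + Jyy + eps)

    whose direction is the double angle 2*theta of the dominant *structure*
    orientation (so theta and theta + 180 deg coincide) and whose magnitude
    equals the anisotropy ratio (l1 - l2) / (l1 + l2) in [0, 1].

    Parameters
    ----------
    image : 2-D array
    scale : float
        Standard deviation (px) of the derivative filters; must be > 0.
    integration_scale : float
        Standard deviation (px) of the tensor-smoothing filter.
    eps : float
        Regulariser keeping flat regions at magnitude ~0.

    Returns
    -------
    (H, W, 2) array of dominance vectors with magnitude in [0, 1].
    """
    if scale <= 0 or integration_scale <= 0:
        raise ValueError("filter scales must be positive")
    image = np.asarray(image, dtype=float)
    # x = col, y = row; derivatives via Gaussian band-pass filters
    ix = gaussian_filter(image, scale, order=(0, 1), mode="reflect")
    iy = gaussian_filter(image, scale, order=(1, 0), mode="reflect")
    jxx = gaussian_filter(ix * ix, integration_scale, mode="reflect")
    jxy = gaussian_filter(ix * iy, integration_scale, mode="reflect")
    jyy = gaussian_filter(iy * iy, integration_scale, mode="reflect")
    trace = jxx + jyy + eps
    # negate: dominant eigenvector of J is the gradient direction, which is
    # perpendicular to the structure; in double angle that is a sign flip
    v1 = -(jxx - jyy) / trace
    v2 = -(2.0 * jxy) / trace
    return np.stack([v1, v2], axis=-1)


def dominant_angle(field: np.ndarray) -> np.ndarray:
    """Structure orientation in degrees in [0, 180) from a dominance field."""
    return np.degrees(0.5 * np.arctan2(field[..., 1], field[..., 0])) % 180.0


def patch_intensities(image: np.ndarray, row: int, col: int) -> np.ndarray:
    """The 3x3 neighbourhood of (row, col) in row-major order (centre = 5th).

    Borders use reflect padding, so every pixel — including corners — has a
    well-defined patch.
    """
    image = np.asarray(image, dtype=float)
    padded = np.pad(image, 1, mode="reflect")
    return padded[row : row + 3, col : col + 3].ravel()


def patch_statistics(patch: Sequence[float]) -> np.ndarray:
    """(Med, Range, E, M2, M3, M4) of a 9-element intensity patch."""
    p = np.asarray(patch, dtype=float)
    if p.size != 9 or not np.all(np.isfinite(p)):
        raise ValueError("patch must be 9 finite values")
    med = np.median(p)
    rng = p.max() - p.min()
    energy = np.sum(p * p)
    mu = p.mean()
    d = p - mu
    m2 = np.mean(d ** 2)
    m3 = np.mean(d ** 3)
    m4 = np.mean(d ** 4)
    return np.array([med, rng, energy, m2, m3, m4])


def _patch_stack(arr2d: np.ndarray) -> np.ndarray:
    """(H, W, 9) of reflect-padded 3x3 patches, row-major within the patch."""
    padded = np.pad(arr2d, 1, mode="reflect")
    wins = sliding_window_view(padded, (3, 3))
    return wins.reshape(arr2d.shape + (9,))


@dataclass
class FeatureMatrix:
    """N x 33 per-pixel feature matrix plus normalisation state.

    ``mean``/``std`` hold the per-column statistics of the *training* matrix
    once :func:`normalize_features` has run in training mode; ``std`` uses
    the population (1/N) convention.  ``constant_columns`` flags columns that
    had zero variance at training time (these are centred, not scaled).
    """

    values: np.ndarray
    normalized: bool = False
    mean: Optional[np.ndarray] = None
    std: Optional[np.ndarray] = None
    constant_columns: Optional[np.ndarray] = None
    names: tuple = FEATURE_NAMES

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != N_FEATURES:
            raise ValueError(
                f"feature matrix must have {N_FEATURES} columns, "
                f"got shape {self.values.shape}"
            )

    @property
    def n_pixels(self) -> int:
        return self.values.shape[0]

    def stats(self):
        if self.mean is None:
            raise ValueError("no normalisation statistics attached")
        return self.mean, self.std, self.constant_columns

    def inverse_transform(self) -> "FeatureMatrix":
        """Undo normalisation using the attached statistics."""
        if not self.normalized:
            return self
        mean, std, const = self.stats()
        scale = np.where(const, 1.0, std)
        return FeatureMatrix(self.values * scale + mean)


def build_feature_matrix(
    image: np.ndarray,
    field: Optional[np.ndarray] = None,
    pixels: Optional[np.ndarray] = None,
    **orientation_kwargs,
) -> FeatureMatrix:
    """Map pixels of an image to 33-column feature vectors.

    Parameters
    ----------
    image : 2-D array
    field : optional (H, W, 2) orientation dominance field; computed from the
        image with default scales when omitted.
    pixels : optional (K, 2) array of (row, col) indices; default all pixels
        in row-major scan order.

    Returns
    -------
    FeatureMatrix (unnormalised).
    """
    image = np.asarray(image, dtype=float)
    if field is None:
        field = orientation_dominance(image, **orientation_kwargs)
    field = np.asarray(field, dtype=float)
    if field.shape[:2] != image.shape:
        raise ValueError("orientation field is not aligned with the image")

    ipatch = _patch_stack(image)                      # (H, W, 9)
    v1patch = _patch_stack(field[..., 0])             # (H, W, 9)
    v2patch = _patch_stack(field[..., 1])
    opatch = np.empty(image.shape + (18,))
    opatch[..., 0::2] = v1patch                       # position k: v1 then v2
    opatch[..., 1::2] = v2patch

    med = np.median(ipatch, axis=-1)
    rng = ipatch.max(axis=-1) - ipatch.min(axis=-1)
    energy = np.sum(ipatch * ipatch, axis=-1)
    mu = ipatch.mean(axis=-1, keepdims=True)
    d = ipatch - mu
    m2 = np.mean(d ** 2, axis=-1)
    m3 = np.mean(d ** 3, axis=-1)
    m4 = np.mean(d ** 4, axis=-1)
    stats = np.stack([med, rng, energy, m2, m3, m4], axis=-1)

    full = np.concatenate([ipatch, opatch, stats], axis=-1)  # (H, W, 33)
    if pixels is None:
        values = full.reshape(-1, N_FEATURES)
    else:
        pixels = np.asarray(pixels)
        r, c = pixels[:, 0], pixels[:, 1]
        if r.min() < 0 or c.min() < 0 or r.max() >= image.shape[0] or c.max() >= image.shape[1]:
            raise IndexError("pixel index out of bounds")
        values = full[r, c]
    return FeatureMatrix(values)


def normalize_features(
    matrix: FeatureMatrix,
    stats: Optional[tuple] = None,
) -> FeatureMatrix:
    """Standardise columns to zero mean, unit (population) std.

    Training mode (``stats`` omitted): compute per-column mean and 1/N std
    from this matrix, transform, and attach the statistics.  Zero-variance
    columns are flagged, centred only, and a warning is issued.

    Test mode (``stats`` given as ``(mean, std, constant_columns)``): apply
    the training statistics unchanged.
    """
    X = matrix.values
    if stats is None:
        if X.shape[0] < 2:
            raise ValueError("need at least 2 rows to estimate normalisation stats")
        mean = X.mean(axis=0)
        std = X.std(axis=0)  # population (ddof=0)
        # constant columns: allow for accumulation error in the mean
        const = std <= 1e-12 * np.maximum(1.0, np.abs(mean))
        if const.any():
            warnings.warn(
                f"{int(const.sum())} zero-variance feature column(s) centred "
                "but not scaled",
                stacklevel=2,
            )
    else:
        mean, std, const = stats
        mean = np.asarray(mean, dtype=float)
        std = np.asarray(std, dtype=float)
        const = np.asarray(const, dtype=bool)
        if mean.shape != (N_FEATURES,) or std.shape != (N_FEATURES,):
            raise ValueError("normalisation statistics must have 33 entries")
    scale = np.where(const, 1.0, std)
    return FeatureMatrix(
        (X - mean) / scale,
        normalized=True,
        mean=mean,
        std=std,
        constant_columns=const,
    )
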