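"""Synthetic endothelial-monolayer phantoms with exact ground truth.

Silver-stained monolayer images are closed mosaics of cells separated by thin
dark boundary curves, degraded by additive Gaussian noise, a slowly varying
(second-order polynomial) illumination trend, additive montage-seam offsets,
gaps where the stain failed, and isolated speckle pixels whose intensity
mimics a boundary.  The generator reproduces each of these degradations with
an independent knob so every downstream stage (feature extraction, SVM
training, baseline thresholding, evaluation) can be exercised against a known
per-pixel ground truth.

The mosaic itself is a planar nearest-site (Voronoi) tessellation of randomly
seeded cell centres; a pixel belongs to the boundary network when it lies
within ``boundary_width / 2`` of the bisector between its two nearest sites.

Coordinate convention: images are row-major 2-D arrays indexed ``(row, col)``,
0-based; for the illumination polynomial ``x = col`` and ``y = row``, both
normalised to [-1, 1] across the image.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.spatial import cKDTree


@dataclass
class PhantomConfig:
    """Parameters of a synthetic monolayer image.

    Attributes
    ----------
    width, height : int
        Image size in pixels; at least 16 each.
    n_cells : int
        Number of mosaic cells (tessellation sites); at least 2.
    boundary_width : float
        Full width of the boundary curves in pixels.
    boundary_mean, background_mean : float
        Class intensities in [0, 1].  Boundaries are darker than background
        in stained material; set ``invert=True`` for bright boundaries.
    noise_sigma : float
        Standard deviation of the additive Gaussian noise.
    gap_fraction : float
        Fraction of boundary pixels reverted to background intensity in the
        rendered image (the ground-truth mask stays complete), in [0, 1).
    speckle_density : float
        Expected isolated boundary-intensity noise pixels per pixel of area.
        Speckles are placed at least 2 px away from any true boundary so they
        have no supporting neighbours.
    illum_coeffs : tuple of 6 floats
        (c0, cx, cy, cxx, cxy, cyy) of the additive second-order illumination
        trend evaluated on coordinates normalised to [-1, 1].
    seam_offset : float
        Additive intensity step applied right of the image-centre column,
        emulating a montage seam.  0 disables it.
    invert : bool
        If True, boundaries are brighter than the background (means swapped
        in interpretation; the mask is unchanged).
    seed : int
        RNG seed.  Identical config and seed give bit-identical output.
    """

    width: int = 256
    height: int = 256
    n_cells: int = 50
    boundary_width: float = 2.0
    boundary_mean: float = 0.10
    background_mean: float = 0.50
    noise_sigma: float = 0.12
    gap_fraction: float = 0.05
    speckle_density: float = 0.002
    illum_coeffs: tuple = (0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    seam_offset: float = 0.0
    invert: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.width < 16 or self.height < 16:
            raise ValueError("width and height must be >= 16")
        if self.n_cells < 2:
            raise ValueError("n_cells must be >= 2 to form a mosaic")
        if not (0.0 <= self.gap_fraction < 1.0):
            raise ValueError("gap_fraction must lie in [0, 1)")
        for name in ("boundary_mean", "background_mean"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.boundary_mean == self.background_mean and self.noise_sigma == 0:
            raise ValueError(
                "degenerate config: boundary_mean equals background_mean with "
                "zero noise; the classes would be indistinguishable"
            )
        if self.boundary_width <= 0:
            raise ValueError("boundary_width must be positive")
        if len(self.illum_coeffs) != 6:
            raise ValueError("illum_coeffs must have 6 entries (c0,cx,cy,cxx,cxy,cyy)")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["illum_coeffs"] = list(d["illum_coeffs"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown PhantomConfig keys: {sorted(unknown)}")
        d = dict(d)
        if "illum_coeffs" in d:
            d["illum_coeffs"] = tuple(d["illum_coeffs"])
        return cls(**d)


def _normalized_grid(shape):
    """x (col) and y (row) coordinates normalised to [-1, 1] over the image."""
    h, w = shape
    y = np.linspace(-1.0, 1.0, h) if h > 1 else np.zeros(1)
    x = np.linspace(-1.0, 1.0, w) if w > 1 else np.zeros(1)
    return np.meshgrid(x, y)  # X varies along columns, Y along rows


def quadratic_surface(shape, coeffs) -> np.ndarray:
    """Evaluate c0 + cx*x + cy*y + cxx*x^2 + cxy*x*y + cyy*y^2 on the grid."""
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.shape != (6,):
        raise ValueError("coeffs must be a 6-vector (c0,cx,cy,cxx,cxy,cyy)")
    if not np.all(np.isfinite(coeffs)):
        raise ValueError("coeffs must be finite")
    X, Y = _normalized_grid(shape)
    c0, cx, cy, cxx, cxy, cyy = coeffs
    return c0 + cx * X + cy * Y + cxx * X * X + cxy * X * Y + cyy * Y * Y


def apply_illumination(image: np.ndarray, coeffs) -> np.ndarray:
    """Add a second-order polynomial illumination trend, clipped to [0, 1]."""
    image = np.asarray(image, dtype=float)
    return np.clip(image + quadratic_surface(image.shape, coeffs), 0.0, 1.0)


def apply_montage_seam(image: np.ndarray, column: int, offset: float) -> np.ndarray:
    """Shift all pixels with col >= column by ``offset`` (clipped to [0, 1])."""
    image = np.asarray(image, dtype=float)
    w = image.shape[1]
    if not (0 < column < w):
        raise ValueError(f"seam column must lie strictly inside (0, {w}), got {column}")
    out = image.copy()
    out[:, column:] += offset
    return np.clip(out, 0.0, 1.0)


def _boundary_mask(shape, sites, boundary_width):
    """Pixels within boundary_width/2 of a Voronoi edge between two sites.

    The distance from a pixel to the bisector of its two nearest sites is
    (d2 - d1) / 2, exact on the bisector line itself.
    """
    h, w = shape
    rows, cols = np.mgrid[0:h, 0:w]
    pts = np.column_stack([rows.ravel(), cols.ravel()]).astype(float)
    tree = cKDTree(sites)
    dists, _ = tree.query(pts, k=2)
    edge_dist = (dists[:, 1] - dists[:, 0]) / 2.0
    return (edge_dist <= boundary_width / 2.0).reshape(h, w).astype(np.uint8)


def generate_monolayer_phantom(config: PhantomConfig, return_info: bool = False):
    """Render a synthetic monolayer image and its ground-truth boundary mask.

    The mask is the clean boundary network (before gaps, speckle and noise).
    The image starts as a two-level rendering of the mask, then boundary gaps,
    speckles, the illumination trend, the montage seam and Gaussian noise are
    applied in that order, and the result is clipped to [0, 1].

    Parameters
    ----------
    config : PhantomConfig
    return_info : bool
        If True, also return a dict with the tessellation sites, speckle
        pixel coordinates and gap pixel coordinates (useful for constructing
        targeted test fixtures).

    Returns
    -------
    (image, mask) or (image, mask, info)
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    h, w = config.height, config.width

    sites = rng.uniform([0, 0], [h, w], size=(config.n_cells, 2))
    mask = _boundary_mask((h, w), sites, config.boundary_width)

    lo, hi = config.boundary_mean, config.background_mean
    if config.invert:
        lo, hi = hi, lo
    image = np.where(mask == 1, lo, hi).astype(float)

    # Boundary gaps: delete a fraction of boundary pixels in the image only.
    boundary_idx = np.flatnonzero(mask.ravel() == 1)
    n_gap = int(round(config.gap_fraction * boundary_idx.size))
    gap_idx = (
        rng.choice(boundary_idx, size=n_gap, replace=False)
        if n_gap > 0
        else np.empty(0, dtype=int)
    )
    image.ravel()[gap_idx] = hi

    # Speckles: isolated boundary-intensity pixels >= 2 px from any boundary.
    from scipy.ndimage import distance_transform_edt

    dist_to_boundary = distance_transform_edt(mask == 0)
    eligible = np.flatnonzero(dist_to_boundary.ravel() >= 2.0)
    n_speckle = min(int(round(config.speckle_density * h * w)), eligible.size)
    speckle_idx = (
        rng.choice(eligible, size=n_speckle, replace=False)
        if n_speckle > 0
        else np.empty(0, dtype=int)
    )
    image.ravel()[speckle_idx] = lo

    if any(c != 0 for c in config.illum_coeffs):
        image = image + quadratic_surface((h, w), config.illum_coeffs)
    if config.seam_offset != 0:
        image[:, w // 2:] += config.seam_offset
    if config.noise_sigma > 0:
        image = image + rng.normal(0.0, config.noise_sigma, size=(h, w))
    image = np.clip(image, 0.0, 1.0)

    if return_info:
        info = {
            "sites": sites,
            "speckles": np.column_stack(np.unravel_index(speckle_idx, (h, w))),
            "gaps": np.column_stack(np.unravel_index(gap_idx, (h, w))),
        }
        return image, mask, info
    return image, mask


def sample_training_patch(image, mask, size, seed=0, max_tries=1000):
    """Crop a random size x size patch containing both classes.

    Mirrors the practice of training the classifier on a small hand-labelled
    sample region (62 x 62 px in the original protocol) rather than the whole
    image.  Locations are retried until the patch mask contains at least one
    boundary and one background pixel.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask)
    h, w = image.shape
    if size > min(h, w):
        raise ValueError(f"patch size {size} exceeds image dimensions {h}x{w}")
    if size == h and size == w:
        if mask.min() == mask.max():
            raise ValueError("full image contains a single class")
        return image, mask
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        r = int(rng.integers(0, h - size + 1))
        c = int(rng.integers(0, w - size + 1))
        m = mask[r : r + size, c : c + size]
        if m.min() != m.max():
            return image[r : r + size, c : c + size].copy(), m.copy()
    raise RuntimeError(
        f"no patch of size {size} containing both classes found in {max_tries} tries"
    )
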