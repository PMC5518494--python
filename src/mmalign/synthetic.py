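"""Synthetic multimodal image pairs and matching problems with ground truth.

Real multimodal pairs (multispectral retinal images, flash/no-flash,
RGB/depth) differ in two ways this generator emulates separately: a
*photometric* change (the same structure rendered with different intensity
statistics, here an intensity remapping of a shared base image — gamma,
inversion, or a non-monotone band remap) and a *geometric* change (a known
affine or quadratic warp between the frames).  Zero-mean Gaussian noise at
variances 0 to 0.08 (on images normalised to [0, 1]) is added to both
observed images after the remapping.  The base image is a vessel-like
texture — smoothed random curves of varying width on a smooth background —
chosen so the difference-of-Gaussians detector finds plentiful landmarks,
as it does on retinal imagery.

Ground truth is exact: a point ``p`` in the first image corresponds to
``true_transform(p)`` in the second, and the linear-mapping matching
problems return the generating permutation and mapping matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d, map_coordinates

from .spatial import SpatialTransform, apply_transform, identity_transform, transform_jacobian

__all__ = [
    "SyntheticPair",
    "make_base_image",
    "make_pair",
    "make_matching_problem",
    "true_point_pairs",
    "INTENSITY_KINDS",
    "NOISE_VARIANCES",
]

NOISE_VARIANCES = (0.0, 0.01, 0.02, 0.04, 0.08)
INTENSITY_KINDS = ("identity", "gamma", "inverted", "band-remap")


@dataclass(frozen=True)
class SyntheticPair:
    """A simulated multimodal pair with known geometric truth.

    ``true_transform`` maps coordinates of ``img_I`` to ``img_J`` (pixels).
    """

    img_I: np.ndarray
    img_J: np.ndarray
    true_transform: SpatialTransform
    intensity_map: str
    noise_var: float
    seed: int


def make_base_image(size: int = 256, n_structures: int = 12, seed: int = 0) -> np.ndarray:
    """Vessel-like texture: smoothed random curves on a smooth background."""
    if size < 32:
        raise ValueError("size must be >= 32")
    rng = np.random.default_rng(seed)
    background = gaussian_filter(rng.standard_normal((size, size)), size / 10.0)
    span = background.max() - background.min()
    if span > 0:
        background = (background - background.min()) / span
    img = 0.45 + 0.25 * background

    n_steps = 3 * size
    for _ in range(int(n_structures)):
        start = rng.uniform(0.1 * size, 0.9 * size, size=2)
        heading = rng.uniform(0, 2 * np.pi)
        turn = gaussian_filter1d(rng.standard_normal(n_steps), 12.0) * 0.35
        angles = heading + np.cumsum(turn)
        path = start[None, :] + np.cumsum(
            np.column_stack([np.cos(angles), np.sin(angles)]), axis=0
        )
        rows = np.clip(np.round(path[:, 0]).astype(int), 0, size - 1)
        cols = np.clip(np.round(path[:, 1]).astype(int), 0, size - 1)
        layer = np.zeros((size, size))
        layer[rows, cols] = 1.0
        width = rng.uniform(0.8, 2.5)
        layer = gaussian_filter(layer, width)
        if layer.max() > 0:
            layer = layer / layer.max()
        contrast = rng.uniform(0.25, 0.45)
        img = img - contrast * layer  # vessels darker than background

    return np.clip(img, 0.0, 1.0)


def _remap_intensity(base: np.ndarray, kind: str, rng: np.random.Generator) -> np.ndarray:
    if kind == "identity":
        return base.copy()
    if kind == "gamma":
        gamma = np.exp(rng.uniform(np.log(0.45), np.log(2.2)))
        return base**gamma
    if kind == "inverted":
        return 1.0 - base
    if kind == "band-remap":
        # non-monotone: mid-tones bright, extremes dark (triangle map)
        return 1.0 - np.abs(2.0 * base - 1.0)
    raise ValueError(f"unknown intensity kind {kind!r}; choose from {INTENSITY_KINDS}")


def _random_transform(kind: str, size: int, rng: np.random.Generator) -> SpatialTransform:
    if kind == "identity":
        return identity_transform("affine")
    if kind not in ("affine", "quadratic12"):
        raise ValueError(f"unknown transform kind {kind!r}")
    angle = np.deg2rad(rng.uniform(-4.0, 4.0))
    scale = np.exp(rng.uniform(-0.04, 0.04))
    shear = rng.uniform(-0.02, 0.02)
    tx, ty = rng.uniform(-12.0, 12.0, size=2)
    c = size / 2.0
    rot = scale * np.array(
        [[np.cos(angle), -np.sin(angle) + shear], [np.sin(angle), np.cos(angle)]]
    )
    # rotate/scale about the image centre, then translate
    offset = np.array([tx, ty]) + c - rot @ np.array([c, c])
    affine = np.column_stack([rot, offset])
    if kind == "affine":
        return SpatialTransform("affine", affine)
    coeffs = np.zeros((2, 6))
    coeffs[:, 0] = affine[:, 2]
    coeffs[:, 1] = affine[:, 0]
    coeffs[:, 2] = affine[:, 1]
    # second-order terms sized for a few pixels of bending at the borders
    coeffs[:, 3:] = rng.uniform(-2.0, 2.0, size=(2, 3)) / size**2 * 3.0
    return SpatialTransform("quadratic12", coeffs)


def _invert_on_grid(t: SpatialTransform, shape: tuple[int, int]) -> np.ndarray:
    """Per-pixel inverse of a mild polynomial warp by Newton iteration.

    Returns ``(2, h, w)`` sampling coordinates (row, col): for each output
    pixel ``q`` the point ``p`` with ``t(p) = q``.
    """
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    q = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    p = q.copy()
    for _ in range(25):
        r = apply_transform(t, p) - q
        if np.max(np.abs(r)) < 1e-9:
            break
        jac = transform_jacobian(t, p)
        det = jac[:, 0, 0] * jac[:, 1, 1] - jac[:, 0, 1] * jac[:, 1, 0]
        det = np.where(np.abs(det) < 1e-12, 1e-12, det)
        dx = (jac[:, 1, 1] * r[:, 0] - jac[:, 0, 1] * r[:, 1]) / det
        dy = (-jac[:, 1, 0] * r[:, 0] + jac[:, 0, 0] * r[:, 1]) / det
        p[:, 0] -= dx
        p[:, 1] -= dy
    rows = p[:, 1].reshape(h, w)
    cols = p[:, 0].reshape(h, w)
    return np.stack([rows, cols])


def make_pair(
    base: np.ndarray,
    transform_kind: str = "affine",
    intensity_kind: str = "gamma",
    noise_var: float = 0.0,
    seed: int = 0,
) -> SyntheticPair:
    """Observe one base scene through two simulated modalities.

    ``img_I`` is the base plus noise; ``img_J`` is the intensity-remapped
    base warped by a random transform of the requested kind (drawn from
    ``seed``), plus independent noise.  Noise is zero-mean Gaussian with
    the given variance, added after the remapping, and both images are
    clipped to [0, 1].
    """
    base = np.asarray(base, dtype=float)
    if base.ndim != 2:
        raise ValueError("base must be a 2-D gray image")
    if noise_var < 0:
        raise ValueError("noise_var must be >= 0")
    rng = np.random.default_rng(seed)
    t = _random_transform(transform_kind, max(base.shape), rng)
    modality = _remap_intensity(base, intensity_kind, rng)

    if transform_kind == "identity":
        warped = modality
    else:
        coords = _invert_on_grid(t, base.shape)
        warped = map_coordinates(modality, coords, order=3, mode="nearest")

    sigma = float(np.sqrt(noise_var))
    img_i = base + (rng.normal(0.0, sigma, base.shape) if sigma > 0 else 0.0)
    img_j = warped + (rng.normal(0.0, sigma, base.shape) if sigma > 0 else 0.0)
    return SyntheticPair(
        img_I=np.clip(img_i, 0.0, 1.0),
        img_J=np.clip(img_j, 0.0, 1.0),
        true_transform=t,
        intensity_map=intensity_kind,
        noise_var=float(noise_var),
        seed=int(seed),
    )


def true_point_pairs(pair: SyntheticPair, n: int = 10, seed: int = 0, margin: float = 0.12) -> np.ndarray:
    """Sample ground-truth correspondences ``(p, t(p))`` as an (n, 2, 2) array.

    Points are drawn in the interior of ``img_I`` and kept only when their
    mapped position also lies inside ``img_J`` — mimicking rater-marked
    point pairs visible in both images.
    """
    h, w = pair.img_I.shape
    rng = np.random.default_rng(seed)
    src = []
    while len(src) < n:
        cand = rng.uniform([margin * w, margin * h], [(1 - margin) * w, (1 - margin) * h], (4 * n, 2))
        mapped = apply_transform(pair.true_transform, cand)
        ok = (
            (mapped[:, 0] >= 0) & (mapped[:, 0] <= w - 1) & (mapped[:, 1] >= 0) & (mapped[:, 1] <= h - 1)
        )
        src.extend(cand[ok].tolist())
    src = np.asarray(src[:n])
    dst = apply_transform(pair.true_transform, src)
    return np.stack([src, dst], axis=1)


def make_matching_problem(
    m: int = 8, k: int = 6, l: int = 6, noise_sigma: float = 0.02, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Draw a landmark-matching problem that follows the linear-mapping model.

    Features ``phi_j`` are random unit vectors, ``T0`` a random k x l
    mapping (orthogonal when k == l, so mapped features stay unit-scale),
    ``pi`` a random permutation, and ``theta_i = T0 phi_{pi(i)} + eps``
    with iid Gaussian noise of standard deviation ``noise_sigma`` (relative
    to the unit-norm features).  Returns ``(Theta, Phi, T0, pi)``; the true
    correspondence matrix is ``E[i, pi(i)] = 1``.
    """
    if m < 2 or k < 1 or l < 1:
        raise ValueError("need m >= 2 and positive feature dimensions")
    rng = np.random.default_rng(seed)
    phi = rng.standard_normal((l, m))
    phi /= np.linalg.norm(phi, axis=0, keepdims=True)
    g = rng.standard_normal((max(k, l), max(k, l)))
    q, _ = np.linalg.qr(g)
    t0 = q[:k, :l]
    pi = rng.permutation(m)
    theta = t0 @ phi[:, pi]
    if noise_sigma > 0:
        theta = theta + rng.normal(0.0, noise_sigma, theta.shape)
    return theta, phi, t0, pi
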