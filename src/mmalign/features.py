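"""Landmark detection and gradient-orientation features.

Landmarks are SIFT keypoint locations (difference-of-Gaussians extrema with
subpixel refinement, via scikit-image).  Each landmark is described by a
gradient-orientation lattice descriptor: the image gradient orientation is
sampled on a ``grid x grid`` lattice centred at the landmark (lattice step
proportional to the detection scale) and every sampled orientation ``a`` is
encoded as the doubled-angle pair ``(cos 2a, sin 2a)``.  Doubling the angle
identifies opposite gradient directions, so a contrast reversal between
modalities (bright-on-dark vs dark-on-bright structures) leaves the
descriptor unchanged; remaining appearance differences between modalities
are absorbed downstream by the learned linear feature mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates
from skimage.feature import SIFT

__all__ = [
    "LandmarkSet",
    "FeatureMatrix",
    "detect_landmarks",
    "extract_gom",
    "write_landmarks_tsv",
    "read_landmarks_tsv",
]


@dataclass(frozen=True)
class LandmarkSet:
    """Detected keypoints of one image.

    coords
        ``(count, 2)`` float array of ``(x, y)`` pixel positions.
    scales
        per-landmark detection scale in pixels.
    image_shape
        ``(height, width)`` of the source image, used to normalise
        coordinates; ``None`` when the coordinates are already in a
        normalised frame.
    """

    coords: np.ndarray
    scales: np.ndarray
    image_shape: tuple[int, int] | None = None
    responses: np.ndarray | None = None

    def __post_init__(self) -> None:
        coords = np.atleast_2d(np.asarray(self.coords, dtype=float))
        if coords.size == 0:
            coords = coords.reshape(0, 2)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValueError("coords must be an (m, 2) array of (x, y)")
        scales = np.asarray(self.scales, dtype=float).reshape(-1)
        if scales.shape[0] != coords.shape[0]:
            raise ValueError("scales length must equal number of coords")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "scales", scales)
        if self.image_shape is not None:
            h, w = self.image_shape
            object.__setattr__(self, "image_shape", (int(h), int(w)))

    @property
    def count(self) -> int:
        return self.coords.shape[0]

    def __len__(self) -> int:
        return self.count

    def normalized_coords(self) -> np.ndarray:
        """Coordinates scaled to [0, 1] by image width/height.

        Returns the raw coordinates when no image shape is attached (they
        are then assumed to already live in a common normalised frame).
        """
        if self.image_shape is None:
            return self.coords.copy()
        h, w = self.image_shape
        return self.coords / np.array([w, h], dtype=float)

    def subset(self, idx: np.ndarray) -> "LandmarkSet":
        return LandmarkSet(
            self.coords[idx],
            self.scales[idx],
            image_shape=self.image_shape,
            responses=None if self.responses is None else self.responses[idx],
        )


@dataclass(frozen=True)
class FeatureMatrix:
    """Per-landmark feature vectors stacked column-wise (``dim x count``)."""

    values: np.ndarray
    landmarks: LandmarkSet | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("feature values must be a 2-D matrix")
        if not np.all(np.isfinite(values)):
            raise ValueError("feature values must be finite")
        if self.landmarks is not None and values.shape[1] != self.landmarks.count:
            raise ValueError("one feature column per landmark required")
        object.__setattr__(self, "values", values)

    @property
    def feature_dim(self) -> int:
        return self.values.shape[0]

    @property
    def count(self) -> int:
        return self.values.shape[1]


def _as_float_image(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2-D single-channel image")
    if not np.all(np.isfinite(image)):
        raise ValueError("image contains non-finite values")
    return image


def _dog_response(image: np.ndarray, positions: np.ndarray, sigmas: np.ndarray) -> np.ndarray:
    """|difference-of-Gaussians| sampled at each keypoint's own sigma.

    scikit-image's SIFT does not expose the detector response, so it is
    recomputed here for ranking: for every distinct sigma the DoG band
    ``G(k*sigma) - G(sigma)`` (k = 2^(1/3)) is evaluated and sampled at the
    keypoints detected at that sigma.
    """
    k = 2.0 ** (1.0 / 3.0)
    resp = np.zeros(len(positions))
    for s in np.unique(sigmas):
        band = gaussian_filter(image, k * s) - gaussian_filter(image, s)
        sel = sigmas == s
        rows = positions[sel, 0]
        cols = positions[sel, 1]
        resp[sel] = np.abs(
            map_coordinates(band, np.vstack([rows, cols]), order=1, mode="nearest")
        )
    return resp


def detect_landmarks(image: np.ndarray, max_points: int = 500) -> LandmarkSet:
    """Detect up to ``max_points`` SIFT keypoints, strongest response first.

    Duplicate detections (the same location/scale reported once per
    assigned orientation) are collapsed.  Response ties are broken by
    (y, x) lexicographic order so the output is deterministic.  A constant
    or featureless image yields an empty :class:`LandmarkSet`.
    """
    image = _as_float_image(image)
    if max_points < 1:
        raise ValueError("max_points must be >= 1")

    shape = (image.shape[0], image.shape[1])
    # SIFT works on the intensity pattern; rescale for a stable detector
    # threshold irrespective of the input's numeric range.
    span = float(image.max() - image.min())
    if span == 0.0:
        return LandmarkSet(np.empty((0, 2)), np.empty(0), image_shape=shape)
    norm = (image - image.min()) / span

    det = SIFT()
    try:
        det.detect(norm)
    except RuntimeError:
        # scikit-image raises when no extremum survives its filters
        return LandmarkSet(np.empty((0, 2)), np.empty(0), image_shape=shape)

    positions = np.asarray(det.positions, dtype=float)  # (row, col)
    sigmas = np.asarray(det.sigmas, dtype=float)
    if positions.size == 0:
        return LandmarkSet(np.empty((0, 2)), np.empty(0), image_shape=shape)

    # collapse per-orientation duplicates of the same extremum
    key = np.round(np.column_stack([positions, sigmas[:, None]]), 3)
    _, keep = np.unique(key, axis=0, return_index=True)
    positions, sigmas = positions[keep], sigmas[keep]

    resp = _dog_response(norm, positions, sigmas)
    order = np.lexsort((positions[:, 1], positions[:, 0], -resp))
    order = order[:max_points]

    coords = positions[order][:, ::-1]  # (x, y)
    return LandmarkSet(coords, sigmas[order], image_shape=shape, responses=resp[order])


def _gradients(image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Central-difference gradients with replicate border padding."""
    padded = np.pad(image, 1, mode="edge")
    gx = (padded[1:-1, 2:] - padded[1:-1, :-2]) / 2.0
    gy = (padded[2:, 1:-1] - padded[:-2, 1:-1]) / 2.0
    return gx, gy


def extract_gom(
    image: np.ndarray,
    landmarks: LandmarkSet,
    grid: int = 9,
    spacing: float = 1.5,
    smooth: float = 1.0,
) -> tuple[FeatureMatrix, LandmarkSet]:
    """Gradient-orientation lattice descriptor for each landmark.

    For each landmark a ``grid x grid`` lattice centred at the keypoint is
    sampled (lattice step = ``spacing`` times the landmark scale) from the
    gradient of the image smoothed at ``smooth`` times the landmark scale
    (scale-space consistency: the descriptor sees the structure the
    detector responded to, not pixel noise).  Each sample is encoded as
    the doubled-angle pair ``(cos 2a, sin 2a)`` weighted by the gradient
    magnitude, so strong edges dominate and textureless lattice points,
    whose orientation is undefined, contribute nothing; a zero-gradient
    sample encodes ``(0, 0)``.  Columns are L2-normalised (an all-zero
    column stays zero), which also makes the descriptor invariant to
    multiplying the image by a positive constant.  Landmarks whose lattice
    leaves the image are dropped from both the feature matrix and the
    returned landmark set, so the two stay consistent.

    Returns ``(features, kept_landmarks)`` with ``features.feature_dim ==
    2 * grid**2``.
    """
    image = _as_float_image(image)
    if grid < 3 or grid % 2 == 0:
        raise ValueError("grid must be an odd integer >= 3")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if smooth < 0:
        raise ValueError("smooth must be >= 0")

    h, w = image.shape
    half = (grid - 1) / 2.0
    extent = half * spacing * np.maximum(landmarks.scales, 1e-12)
    x, y = landmarks.coords[:, 0], landmarks.coords[:, 1]
    inside = (
        (x - extent >= 0) & (x + extent <= w - 1) & (y - extent >= 0) & (y + extent <= h - 1)
    )
    kept = landmarks.subset(np.flatnonzero(inside))

    # smoothing scales quantised to half-octave bins so each distinct
    # Gaussian is computed once per image
    sigma_d = smooth * kept.scales
    bins = np.where(
        sigma_d < 0.3, 0.0, 0.3 * np.sqrt(2.0) ** np.round(np.log(np.maximum(sigma_d, 0.3) / 0.3) / np.log(np.sqrt(2.0)))
    )
    grad_cache: dict[float, tuple[np.ndarray, np.ndarray]] = {}
    for b in np.unique(bins):
        smoothed = gaussian_filter(image, b) if b > 0 else image
        grad_cache[float(b)] = _gradients(smoothed)

    offsets = (np.arange(grid) - half) * spacing  # unit-scale lattice offsets
    oy, ox = np.meshgrid(offsets, offsets, indexing="ij")

    m = kept.count
    cols = np.zeros((2 * grid * grid, m))
    for i in range(m):
        gx, gy = grad_cache[float(bins[i])]
        s = max(kept.scales[i], 1e-12)
        xs = kept.coords[i, 0] + ox.ravel() * s
        ys = kept.coords[i, 1] + oy.ravel() * s
        sample = np.vstack([ys, xs])
        sgx = map_coordinates(gx, sample, order=1, mode="nearest")
        sgy = map_coordinates(gy, sample, order=1, mode="nearest")
        mag2 = sgx**2 + sgy**2
        nz = mag2 > 1e-24
        mag = np.sqrt(mag2)
        cos2 = np.zeros_like(sgx)
        sin2 = np.zeros_like(sgy)
        # magnitude * doubled angle via the identities
        # m*cos2a = (gx^2-gy^2)/m, m*sin2a = 2 gx gy / m
        cos2[nz] = (sgx[nz] ** 2 - sgy[nz] ** 2) / mag[nz]
        sin2[nz] = 2.0 * sgx[nz] * sgy[nz] / mag[nz]
        col = np.concatenate([cos2, sin2])
        norm = np.linalg.norm(col)
        if norm > 0:
            col = col / norm
        cols[:, i] = col

    return FeatureMatrix(cols, landmarks=kept), kept


def write_landmarks_tsv(path, landmarks: LandmarkSet, features: FeatureMatrix | None = None) -> None:
    """Dump landmarks (and optionally features) as TSV: id x y scale [f0..]."""
    import pandas as pd

    data = {
        "id": np.arange(landmarks.count),
        "x": landmarks.coords[:, 0],
        "y": landmarks.coords[:, 1],
        "scale": landmarks.scales,
    }
    if features is not None:
        if features.count != landmarks.count:
            raise ValueError("feature count must match landmark count")
        for d in range(features.feature_dim):
            data[f"f{d}"] = features.values[d]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def read_landmarks_tsv(path, image_shape: tuple[int, int] | None = None):
    """Read a landmark TSV; returns (LandmarkSet, FeatureMatrix | None)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    lms = LandmarkSet(
        df[["x", "y"]].to_numpy(float), df["scale"].to_numpy(float), image_shape=image_shape
    )
    fcols = [c for c in df.columns if c.startswith("f") and c[1:].isdigit()]
    if not fcols:
        return lms, None
    fcols = sorted(fcols, key=lambda c: int(c[1:]))
    feats = FeatureMatrix(df[fcols].to_numpy(float).T, landmarks=lms)
    return lms, feats
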