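"""Coarse-to-fine orchestration of the matcher and transform fitting.

Matching proceeds over an image pyramid (defaults: 3 scales, downsampling
rate 0.8).  The pair is matched first at the coarsest scale; an affine
transform fitted to those matches (in coordinates normalised to [0, 1],
which are comparable across scales) then predicts where each landmark of
the first image should land in the second, and at every finer scale the
distance prior of the matching objective is measured from that predicted
position instead of the raw one.  Only the distance term changes, so
every scale minimises the same objective family.  The finest-scale matches
finally yield the output transform (affine or quadratic12) in pixel
coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from .errors import DegenerateFitError, TooFewLandmarksError
from .matcher import Correspondence, MatchConfig, MatchResult, match_landmarks
from .spatial import SpatialTransform, apply_transform, fit_transform

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "build_pyramid",
    "coarse_to_fine_match",
    "fit_transform_from_matches",
    "render_overlay",
]

logger = logging.getLogger(__name__)

_MIN_PAIRS = {"affine": 3, "quadratic12": 6}


@dataclass(frozen=True)
class PipelineConfig:
    """Settings for the full coarse-to-fine alignment pipeline."""

    match: MatchConfig = field(default_factory=MatchConfig)
    pyramid_levels: int = 3
    downsample_rate: float = 0.8
    max_points: int = 500
    grid: int = 9
    spacing: float = 1.5
    transform_kind: str = "affine"
    search_radius: float = 0.04
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.pyramid_levels < 1:
            raise ValueError("pyramid_levels must be >= 1")
        if not 0 < self.downsample_rate < 1:
            raise ValueError("downsample_rate must lie in (0, 1)")
        if self.transform_kind not in _MIN_PAIRS:
            raise ValueError(f"unknown transform kind {self.transform_kind!r}")
        if self.max_points < 1:
            raise ValueError("max_points must be >= 1")
        if self.search_radius <= 0:
            raise ValueError("search_radius must be > 0 (normalised units)")


@dataclass(frozen=True)
class PipelineResult:
    correspondence: Correspondence
    transform: SpatialTransform
    match: MatchResult
    levels: tuple[dict, ...] = ()


def build_pyramid(image: np.ndarray, levels: int = 3, rate: float = 0.8) -> list[np.ndarray]:
    """Image pyramid, original first, coarsest last.

    Level ``t`` is the original resampled to ``floor(size * rate^t)`` with
    anti-alias smoothing.  Raises if any level would fall below 16 px on a
    side.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2-D gray image")
    if levels < 1:
        raise ValueError("levels must be >= 1")
    if not 0 < rate < 1:
        raise ValueError("rate must lie in (0, 1)")
    h, w = image.shape
    out = [image]
    for t in range(1, levels):
        nh, nw = int(np.floor(h * rate**t)), int(np.floor(w * rate**t))
        if min(nh, nw) < 16:
            raise ValueError(
                f"pyramid level {t} would be {nh}x{nw}; levels below 16 px a side are not supported"
            )
        out.append(resize(image, (nh, nw), anti_aliasing=True))
    return out


def _match_level(img_i, img_j, cfg: PipelineConfig, predicted) -> MatchResult:
    return match_landmarks(
        img_i,
        img_j,
        cfg.match,
        max_points=cfg.max_points,
        grid=cfg.grid,
        spacing=cfg.spacing,
        predicted_transform=predicted,
        search_radius=cfg.search_radius if predicted is not None else None,
    )


def _confident_pairs(result: MatchResult, normalized: bool) -> np.ndarray:
    """Matched pairs as (n, 2, 2), best confidence first."""
    pairs = result.correspondence.pairs or ()
    a = result.lm_I.normalized_coords() if normalized else result.lm_I.coords
    b = result.lm_J.normalized_coords() if normalized else result.lm_J.coords
    return np.stack(
        [np.array([a[i] for i, _, _ in pairs]).reshape(-1, 2),
         np.array([b[j] for _, j, _ in pairs]).reshape(-1, 2)],
        axis=1,
    )


def fit_transform_from_matches(
    result: MatchResult,
    kind: str = "affine",
    normalized: bool = False,
    inlier_tol: float = 0.015,
) -> SpatialTransform:
    """Fit a transform from a match set, robust to residual false matches.

    Landmark matching is one-to-one filtered but a detector may simply
    miss a landmark's counterpart in the other image, so a fraction of
    confidently wrong matches is expected.  The fit uses deterministic
    confidence-nested consensus: candidate transforms are fitted on nested
    prefixes of the confidence-ranked matches (most trustworthy first),
    each candidate is scored by how many of all matches it brings within
    ``inlier_tol`` (relative to the coordinate span), and the best
    candidate is refitted on its own inlier set.  No random sampling is
    involved, so the result is deterministic.
    """
    pairs = _confident_pairs(result, normalized)
    need = _MIN_PAIRS[kind]
    n = pairs.shape[0]
    if n < need:
        raise TooFewLandmarksError(
            f"{n} matches cannot determine a {kind} transform (need {need})"
        )
    span = float(np.ptp(pairs[:, 1], axis=0).max())
    tol = inlier_tol * max(span, 1e-9)

    def inliers_of(t: SpatialTransform) -> np.ndarray:
        resid = np.sqrt(np.sum((apply_transform(t, pairs[:, 0]) - pairs[:, 1]) ** 2, axis=1))
        return resid <= tol

    prefixes = sorted({k for k in (need, 8, 12, 16, 24, 32, 48, 64, n) if need <= k <= n})
    best_t, best_in = None, None
    for k in prefixes:
        try:
            t = fit_transform(pairs[:k], kind)
        except DegenerateFitError:
            continue
        mask = inliers_of(t)
        if best_in is None or mask.sum() > best_in.sum():
            best_t, best_in = t, mask
    if best_t is None:
        raise DegenerateFitError(
            f"no non-degenerate {kind} fit from {n} matches (need {need} in general position)"
        )
    for _ in range(2):  # refit on consensus set until stable
        if best_in.sum() >= need:
            t = fit_transform(pairs[best_in], kind)
            mask = inliers_of(t)
            if mask.sum() >= best_in.sum():
                best_t, best_in = t, mask
    if best_in.sum() >= need:
        # reported residual reflects the final consensus fit
        best_t = fit_transform(pairs[best_in], kind)
    return best_t


def coarse_to_fine_match(img_I: np.ndarray, img_J: np.ndarray, cfg: PipelineConfig = PipelineConfig()) -> PipelineResult:
    """Match a pair over the pyramid and fit the output transform.

    Falls back to plain single-scale matching (with a warning) when the
    coarse levels cannot produce enough matches to propagate a prediction.
    Raises :class:`TooFewLandmarksError` only when the finest scale itself
    cannot be matched or fitted.
    """
    pyr_i = build_pyramid(img_I, cfg.pyramid_levels, cfg.downsample_rate)
    pyr_j = build_pyramid(img_J, cfg.pyramid_levels, cfg.downsample_rate)

    predicted: SpatialTransform | None = None
    finest: MatchResult | None = None
    level_log: list[dict] = []
    for level in range(cfg.pyramid_levels - 1, -1, -1):
        try:
            result = _match_level(pyr_i[level], pyr_j[level], cfg, predicted)
        except TooFewLandmarksError as exc:
            if level == 0:
                raise
            logger.warning("pyramid level %d failed (%s); skipping", level, exc)
            level_log.append({"level": level, "matches": 0, "skipped": True})
            continue
        n_matches = result.correspondence.n_matches
        level_log.append({"level": level, "matches": n_matches, "skipped": False})
        logger.info("pyramid level %d: %d matches", level, n_matches)
        if level == 0:
            finest = result
        elif n_matches >= _MIN_PAIRS["affine"]:
            predicted = fit_transform_from_matches(result, "affine", normalized=True)
        else:
            logger.warning(
                "pyramid level %d produced only %d matches; prediction not updated",
                level,
                n_matches,
            )

    assert finest is not None
    need = _MIN_PAIRS[cfg.transform_kind]
    if finest.correspondence.n_matches < need and predicted is not None:
        logger.warning(
            "coarse-to-fine produced %d matches (< %d); falling back to single-level matching",
            finest.correspondence.n_matches,
            need,
        )
        finest = _match_level(pyr_i[0], pyr_j[0], cfg, None)
        level_log.append({"level": 0, "matches": finest.correspondence.n_matches, "fallback": True})
    if finest.correspondence.n_matches < need:
        raise TooFewLandmarksError(
            f"only {finest.correspondence.n_matches} matches at the finest scale; "
            f"{cfg.transform_kind} fit needs {need}"
        )

    transform = fit_transform_from_matches(finest, cfg.transform_kind, normalized=False)
    return PipelineResult(finest.correspondence, transform, finest, tuple(level_log))


def render_overlay(img_I: np.ndarray, img_J: np.ndarray, transform: SpatialTransform) -> np.ndarray:
    """Magenta/green composite of ``img_I`` and ``img_J`` warped into its frame.

    The first image fills the red and blue channels, the warped second
    image the green channel, so aligned structure reads gray and residual
    misalignment shows as magenta/green fringes.  Pixels whose warped
    position falls outside ``img_J`` are set to zero in all channels.
    """
    from scipy.ndimage import map_coordinates

    img_I = np.asarray(img_I, dtype=float)
    img_J = np.asarray(img_J, dtype=float)
    h, w = img_I.shape
    yy, xx = np.mgrid[0:h, 0:w]
    pts = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    mapped = apply_transform(transform, pts)
    hj, wj = img_J.shape
    valid = (
        (mapped[:, 0] >= 0) & (mapped[:, 0] <= wj - 1) & (mapped[:, 1] >= 0) & (mapped[:, 1] <= hj - 1)
    ).reshape(h, w)
    warped = map_coordinates(img_J, np.vstack([mapped[:, 1], mapped[:, 0]]), order=1, mode="constant").reshape(h, w)
    rgb = np.zeros((h, w, 3))
    rgb[..., 0] = img_I
    rgb[..., 2] = img_I
    rgb[..., 1] = warped
    rgb[~valid] = 0.0
    return np.clip(rgb, 0.0, 1.0)
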