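"""Spatial transforms fitted from matched landmarks.

Two model classes are supported: a 6-parameter affine map and the
12-parameter quadratic map conventional for retinal registration, where
each output coordinate is a polynomial over the basis
``[1, x, y, x^2, xy, y^2]``.  The quadratic class captures the curvature
of the retinal surface that an affine map cannot; for planar scenes the
affine class is appropriate.  Alignment error is the mean Euclidean
distance between transformed source points and their marked targets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateFitError

__all__ = [
    "SpatialTransform",
    "fit_transform",
    "apply_transform",
    "transform_jacobian",
    "alignment_error",
    "identity_transform",
    "write_transform_json",
    "read_transform_json",
    "write_points_tsv",
    "read_points_tsv",
]

_BASIS = "1,x,y,x2,xy,y2"
_MIN_PAIRS = {"affine": 3, "quadratic12": 6}


@dataclass(frozen=True)
class SpatialTransform:
    """A 2-D coordinate map.

    kind
        ``"affine"`` (coeffs 2x3, acting on ``[x, y, 1]``) or
        ``"quadratic12"`` (coeffs 2x6 over ``[1, x, y, x^2, xy, y^2]``).
    residual
        RMS fitting residual in the units of the target frame, when the
        transform came from a least-squares fit.
    """

    kind: str
    coeffs: np.ndarray
    residual: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in _MIN_PAIRS:
            raise ValueError(f"unknown transform kind {self.kind!r}")
        width = 3 if self.kind == "affine" else 6
        coeffs = np.asarray(self.coeffs, dtype=float).reshape(2, width)
        if not np.all(np.isfinite(coeffs)):
            raise ValueError("transform coefficients must be finite")
        object.__setattr__(self, "coeffs", coeffs)

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return apply_transform(self, points)


def identity_transform(kind: str = "affine") -> SpatialTransform:
    if kind == "affine":
        return SpatialTransform("affine", np.array([[1.0, 0, 0], [0, 1.0, 0]]))
    coeffs = np.zeros((2, 6))
    coeffs[0, 1] = 1.0
    coeffs[1, 2] = 1.0
    return SpatialTransform("quadratic12", coeffs)


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    single = pts.ndim == 1
    pts = np.atleast_2d(pts)
    if pts.shape[1] != 2:
        raise ValueError("points must be (n, 2) arrays of (x, y)")
    return pts if not single else pts  # callers keep (n,2); single row ok


def _design(kind: str, pts: np.ndarray) -> np.ndarray:
    x, y = pts[:, 0], pts[:, 1]
    if kind == "affine":
        return np.column_stack([x, y, np.ones_like(x)])
    return np.column_stack([np.ones_like(x), x, y, x * x, x * y, y * y])


def apply_transform(t: SpatialTransform, points) -> np.ndarray:
    """Map ``(n, 2)`` points through the transform."""
    pts = _as_points(points)
    return _design(t.kind, pts) @ t.coeffs.T


def transform_jacobian(t: SpatialTransform, points) -> np.ndarray:
    """Per-point 2x2 Jacobian ``d(x', y')/d(x, y)`` — shape (n, 2, 2)."""
    pts = _as_points(points)
    n = pts.shape[0]
    jac = np.empty((n, 2, 2))
    if t.kind == "affine":
        jac[:] = t.coeffs[:, :2]
        return jac
    x, y = pts[:, 0], pts[:, 1]
    for out in range(2):
        _, cx, cy, cxx, cxy, cyy = t.coeffs[out]
        jac[:, out, 0] = cx + 2 * cxx * x + cxy * y
        jac[:, out, 1] = cy + cxy * x + 2 * cyy * y
    return jac


def _split_pairs(pairs) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim == 3 and arr.shape[1:] == (2, 2):
        return arr[:, 0, :], arr[:, 1, :]
    if arr.ndim == 2 and arr.shape[1] == 4:
        return arr[:, :2], arr[:, 2:]
    raise ValueError("pairs must be ((x,y),(x',y')) tuples or an (n, 4) array")


def fit_transform(pairs, kind: str = "affine") -> SpatialTransform:
    """Least-squares fit of the coordinate map from point pairs.

    Coordinates are rescaled to the unit square before solving (for
    conditioning) and the coefficients are mapped back exactly afterwards —
    both model classes are closed under affine changes of frame.  Raises
    :class:`DegenerateFitError` for under-determined configurations
    (fewer than 3 non-collinear pairs for affine, 6 pairs in general
    position for quadratic12).
    """
    if kind not in _MIN_PAIRS:
        raise ValueError(f"unknown transform kind {kind!r}")
    src, dst = _split_pairs(pairs)
    n, need = src.shape[0], _MIN_PAIRS[kind]
    if n < need:
        raise DegenerateFitError(
            f"{kind} fit needs at least {need} pairs, got {n}"
        )

    def unit_frame(p):
        lo = p.min(axis=0)
        span = max(float((p.max(axis=0) - lo).max()), 1e-12)
        return lo, span

    lo_s, sp_s = unit_frame(src)
    lo_d, sp_d = unit_frame(dst)
    a = _design(kind, (src - lo_s) / sp_s)
    b = (dst - lo_d) / sp_d
    coef, _, rank, _ = np.linalg.lstsq(a, b, rcond=None)
    if rank < a.shape[1]:
        raise DegenerateFitError(
            f"degenerate point configuration for {kind} fit: rank {rank} < "
            f"{a.shape[1]}; need at least {need} pairs in general position"
        )
    scaled = SpatialTransform(kind, coef.T)

    # Map back to the original frames by exact refit of the composed map
    # on a generic probe grid (the model class is closed under this).
    gx, gy = np.meshgrid(np.linspace(0.13, 0.91, 3), np.linspace(0.07, 0.83, 3))
    probe_unit = np.column_stack([gx.ravel(), gy.ravel()])
    probe_src = probe_unit * sp_s + lo_s
    probe_dst = apply_transform(scaled, probe_unit) * sp_d + lo_d
    coef_px, _, _, _ = np.linalg.lstsq(_design(kind, probe_src), probe_dst, rcond=None)
    fitted = SpatialTransform(kind, coef_px.T)
    resid = apply_transform(fitted, src) - dst
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return SpatialTransform(kind, coef_px.T, residual=rms)


def alignment_error(t: SpatialTransform, marked_pairs) -> float:
    """Mean Euclidean distance between transformed sources and targets."""
    src, dst = _split_pairs(marked_pairs)
    if src.shape[0] < 1:
        raise ValueError("alignment_error needs at least one marked pair")
    diff = apply_transform(t, src) - dst
    return float(np.mean(np.sqrt(np.sum(diff**2, axis=1))))


def write_transform_json(path, t: SpatialTransform) -> None:
    obj = {
        "kind": t.kind,
        "coeffs": t.coeffs.ravel().tolist(),
        "frame": "pixels",
        "basis": _BASIS,
        "residual": t.residual,
    }
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1)


def read_transform_json(path) -> SpatialTransform:
    with open(path) as fh:
        obj = json.load(fh)
    if obj.get("basis", _BASIS) != _BASIS:
        raise ValueError(f"unsupported basis {obj['basis']!r}")
    return SpatialTransform(obj["kind"], np.asarray(obj["coeffs"]), residual=obj.get("residual"))


def write_points_tsv(path, pairs) -> None:
    """Marked point pairs as TSV ``x1 y1 x2 y2``."""
    import pandas as pd

    src, dst = _split_pairs(pairs)
    pd.DataFrame(
        np.column_stack([src, dst]), columns=["x1", "y1", "x2", "y2"]
    ).to_csv(path, sep="\t", index=False)


def read_points_tsv(path) -> np.ndarray:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    arr = df[["x1", "y1", "x2", "y2"]].to_numpy(float)
    return arr.reshape(-1, 2, 2)
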