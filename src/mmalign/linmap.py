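"""Linear mapping between feature modalities.

Matched landmarks are assumed to satisfy ``theta_i = T phi_j`` for a single
projection matrix ``T`` shared by all pairs, i.e. ``Theta E = T Phi`` for the
correspondence matrix ``E``.  With ``E`` held fixed, solving

    min_T  ||Theta E - T Phi||_F^2 + ridge * ||T||_F^2

is ridge regression with the closed form ``T = Theta E Phi' (Phi Phi' +
ridge I)^{-1}``.  Substituting the minimiser back collapses the data term to
``O_m = Tr(Theta E Z E' Theta')`` with the reduced kernel ``Z = I - Phi'
(Phi Phi' + ridge I)^{-1} Phi`` — a convex quadratic in ``E`` that no longer
involves ``T``, which is what the matcher optimises.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.linalg import LinAlgError, cho_factor, cho_solve

from .errors import SingularSystemError
from .features import FeatureMatrix

__all__ = ["MappingMatrix", "ReducedKernel", "solve_mapping", "compute_Z", "data_objective"]


@dataclass(frozen=True)
class MappingMatrix:
    """The modality-bridging projection ``T`` (k x l)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or not np.all(np.isfinite(values)):
            raise ValueError("mapping must be a finite 2-D matrix")
        object.__setattr__(self, "values", values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_json(self) -> str:
        return json.dumps({"shape": list(self.shape), "values": self.values.tolist()})

    @classmethod
    def from_json(cls, text: str) -> "MappingMatrix":
        obj = json.loads(text)
        values = np.asarray(obj["values"], dtype=float)
        if list(values.shape) != list(obj["shape"]):
            raise ValueError("mapping JSON shape mismatch")
        return cls(values)


@dataclass(frozen=True)
class ReducedKernel:
    """``Z = I - Phi'(Phi Phi' + ridge I)^{-1} Phi``: symmetric PSD, n x n.

    Eigenvalues are ``ridge / (s_i^2 + ridge)`` on the row space of Phi
    (``s_i`` the singular values) and 1 on its null space, hence lie in
    (0, 1] for any positive ridge.
    """

    values: np.ndarray
    ridge: float

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[0] != values.shape[1]:
            raise ValueError("kernel must be square")
        if not np.allclose(values, values.T, atol=1e-8):
            raise ValueError("kernel must be symmetric")
        object.__setattr__(self, "values", (values + values.T) / 2.0)

    @property
    def n(self) -> int:
        return self.values.shape[0]


def _matrix(x, name: str) -> np.ndarray:
    if isinstance(x, FeatureMatrix):
        return x.values
    if isinstance(x, ReducedKernel) or isinstance(x, MappingMatrix):
        return x.values
    values = getattr(x, "values", x)
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"{name} must be 2-D")
    return arr


def _gram_solve(phi: np.ndarray, ridge: float, rhs: np.ndarray) -> np.ndarray:
    """Solve ``(Phi Phi' + ridge I) X = rhs`` via a Cholesky factorisation."""
    l = phi.shape[0]
    gram = phi @ phi.T + ridge * np.eye(l)
    try:
        factor = cho_factor(gram, lower=True)
    except LinAlgError as exc:
        raise SingularSystemError(
            "Phi Phi' + ridge*I is singular; use a positive ridge weight "
            "(ridge > 0) to regularise the mapping"
        ) from exc
    return cho_solve(factor, rhs)


def solve_mapping(theta, phi, corr, ridge: float = 0.6) -> MappingMatrix:
    """Closed-form ridge solution ``T = Theta E Phi'(Phi Phi' + ridge I)^{-1}``.

    ``corr`` may be binary or relaxed (continuous).  Raises
    :class:`SingularSystemError` if ``ridge`` is 0 and ``Phi Phi'`` is not
    invertible.
    """
    th = _matrix(theta, "theta")
    ph = _matrix(phi, "phi")
    e = _matrix(corr, "corr")
    if ridge < 0:
        raise ValueError("ridge must be >= 0")
    if e.shape != (th.shape[1], ph.shape[1]):
        raise ValueError(
            f"correspondence shape {e.shape} does not match features "
            f"({th.shape[1]} x {ph.shape[1]})"
        )
    # T' solves (Phi Phi' + ridge I) T' = Phi E' Theta'
    t = _gram_solve(ph, ridge, ph @ e.T @ th.T).T
    return MappingMatrix(t)


def compute_Z(phi, ridge: float = 0.6) -> ReducedKernel:
    """Reduced kernel ``Z = I - Phi'(Phi Phi' + ridge I)^{-1} Phi``."""
    ph = _matrix(phi, "phi")
    if ridge < 0:
        raise ValueError("ridge must be >= 0")
    n = ph.shape[1]
    z = np.eye(n) - ph.T @ _gram_solve(ph, ridge, ph)
    return ReducedKernel((z + z.T) / 2.0, ridge=float(ridge))


def data_objective(theta, corr, kernel) -> float:
    """``O_m = Tr(Theta E Z E' Theta')`` for binary or relaxed ``E``.

    Equals the inner-minimised ridge objective ``min_T ||Theta E - T Phi||^2
    + ridge ||T||^2`` when ``kernel`` was built from the same ``Phi`` and
    ridge weight.
    """
    th = _matrix(theta, "theta")
    e = _matrix(corr, "corr")
    z = _matrix(kernel, "kernel")
    if e.shape[0] != th.shape[1] or e.shape[1] != z.shape[0]:
        raise ValueError("non-conformable shapes for Tr(Theta E Z E' Theta')")
    m = th @ e
    val = float(np.sum((m @ z) * m))
    return max(val, 0.0)
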