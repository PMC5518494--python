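"""Landmark correspondence via a learned linear mapping between modalities.

The full matching objective is

    O(E) = O_m(E) + w_card * O_c1(E) + w_dist * O_c2(E)

with the data term ``O_m = Tr(Theta E Z E' Theta')`` (see :mod:`.linmap`),
a cardinality prior ``O_c1 = ||E 1 - mu 1||^2 + ||E' 1 - mu 1||^2`` pulling
every row and column sum towards the target degree ``mu``, and a distance
prior ``O_c2 = sum_ij E_ij d_ij`` that penalises matches between spatially
distant landmarks (``d_ij`` = squared Euclidean distance on coordinates
normalised to [0, 1]).  O is a convex quadratic; the binary constraint
``E in {0,1}^{m x n}`` is relaxed to the unit box, minimised by the
Frank-Wolfe (conditional gradient) algorithm with exact line search, and
a continuous solution is rounded to a one-to-one binary matching by
linear assignment.

A convex relaxation of a matching objective has a well-known weakness: its
unique minimiser averages over many near-optimal binary matchings, so the
relaxed matrix itself is too diffuse to round reliably (for a discussion
of this failure mode in graph matching see Lyzinski et al., IEEE TPAMI
38(1), 2016).  The relaxed solution is, however, an excellent *estimator
of the mapping* ``T``.  The matcher therefore uses the relaxation to
initialise ``T`` and then refines the pair (T, E) on the equivalent
pairwise form of the same model,

    F(E, T) = sum_ij E_ij (||theta_i - T phi_j||^2 + w_dist * d_ij)
              + ridge * ||T||^2,

by deterministic annealing: alternate a soft assignment (Sinkhorn-balanced
Gibbs weights of the pairwise costs at a decreasing temperature) with the
closed-form ridge update of ``T``, finishing with hard assignment steps.
Several restarts (the Frank-Wolfe initialisation plus random mappings)
guard against local minima; the candidate with the lowest ``F`` wins.
Confidences are ratio tests of the final pairwise costs, and
:func:`round_correspondence` turns them into the binary matching.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import NumericalError, TooFewLandmarksError
from .features import FeatureMatrix, LandmarkSet, detect_landmarks, extract_gom
from .linmap import MappingMatrix, ReducedKernel, _matrix, compute_Z, data_objective, solve_mapping

logger = logging.getLogger(__name__)

__all__ = [
    "Correspondence",
    "MatchConfig",
    "MatchResult",
    "cardinality_penalty",
    "distance_penalty",
    "squared_distance_matrix",
    "total_objective",
    "objective_gradient",
    "frank_wolfe",
    "round_correspondence",
    "match_landmarks",
    "write_matches_tsv",
]


@dataclass(frozen=True)
class Correspondence:
    """An m x n matching matrix, relaxed (entries in [0,1]) or binary.

    When binary, ``pairs`` lists the matched ``(i, j, confidence)`` triples
    sorted by descending confidence, where the confidence is the continuous
    value the binary entry was rounded from.
    """

    values: np.ndarray
    relaxed: bool = True
    pairs: tuple[tuple[int, int, float], ...] | None = None
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("correspondence must be a 2-D matrix")
        if self.relaxed:
            if values.min() < -1e-9 or values.max() > 1 + 1e-9:
                raise ValueError("relaxed correspondence entries must lie in [0, 1]")
            values = np.clip(values, 0.0, 1.0)
        else:
            if not np.all((values == 0) | (values == 1)):
                raise ValueError("binary correspondence entries must be 0 or 1")
            if values.sum(axis=1).max(initial=0) > 1 or values.sum(axis=0).max(initial=0) > 1:
                raise ValueError("binary correspondence must be at most one-to-one")
        object.__setattr__(self, "values", values)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_matches(self) -> int:
        if self.relaxed:
            raise ValueError("n_matches is defined for binary correspondences")
        return int(self.values.sum())


@dataclass(frozen=True)
class MatchConfig:
    """Weights and optimiser settings for the matching objective.

    ridge
        L2 weight of the ridge regression solving the feature mapping.
    w_card, target_degree
        weight and target of the row/column-sum (cardinality) prior.
    w_dist
        weight of the spatial-distance prior.
    """

    ridge: float = 0.6
    w_card: float = 0.8
    w_dist: float = 0.1
    target_degree: float = 1.5
    max_iter: int = 500
    tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ridge <= 0:
            raise ValueError("ridge must be > 0")
        if self.w_card < 0 or self.w_dist < 0:
            raise ValueError("prior weights must be >= 0")
        if self.target_degree <= 0:
            raise ValueError("target_degree must be > 0")
        if self.max_iter < 1 or self.tol <= 0:
            raise ValueError("max_iter >= 1 and tol > 0 required")


def cardinality_penalty(corr, target_degree: float) -> float:
    """``O_c1 = ||E 1 - mu 1||^2 + ||E' 1 - mu 1||^2``."""
    e = _matrix(corr, "corr")
    mu = float(target_degree)
    return float(np.sum((e.sum(axis=1) - mu) ** 2) + np.sum((e.sum(axis=0) - mu) ** 2))


def squared_distance_matrix(lm_I: LandmarkSet, lm_J: LandmarkSet) -> np.ndarray:
    """Pairwise squared distances ``d_ij`` on normalised coordinates."""
    a = lm_I.normalized_coords()
    b = lm_J.normalized_coords()
    diff = a[:, None, :] - b[None, :, :]
    return np.sum(diff**2, axis=2)


def distance_penalty(corr, lm_I: LandmarkSet, lm_J: LandmarkSet) -> float:
    """``O_c2 = sum_ij E_ij d_ij`` — linear in E."""
    e = _matrix(corr, "corr")
    if e.shape != (lm_I.count, lm_J.count):
        raise ValueError("correspondence shape must match landmark counts")
    return float(np.sum(e * squared_distance_matrix(lm_I, lm_J)))


def _dist_matrix(lm_I, lm_J, cfg: MatchConfig, dist=None) -> np.ndarray | None:
    if cfg.w_dist == 0:
        return None
    if dist is not None:
        return np.asarray(dist, dtype=float)
    if lm_I is None or lm_J is None:
        raise ValueError("landmark sets required when w_dist > 0")
    return squared_distance_matrix(lm_I, lm_J)


def total_objective(corr, theta, kernel, lm_I, lm_J, cfg: MatchConfig, dist=None) -> float:
    """``O = O_m + w_card * O_c1 + w_dist * O_c2``."""
    e = _matrix(corr, "corr")
    val = data_objective(theta, e, kernel)
    val += cfg.w_card * cardinality_penalty(e, cfg.target_degree)
    d = _dist_matrix(lm_I, lm_J, cfg, dist)
    if d is not None:
        val += cfg.w_dist * float(np.sum(e * d))
    return val


def objective_gradient(corr, theta, kernel, lm_I, lm_J, cfg: MatchConfig, dist=None) -> np.ndarray:
    """Analytic gradient of the total objective with respect to E."""
    e = _matrix(corr, "corr")
    th = _matrix(theta, "theta")
    z = _matrix(kernel, "kernel")
    mu = cfg.target_degree
    grad = 2.0 * (th.T @ (th @ e)) @ z
    r = e.sum(axis=1) - mu
    c = e.sum(axis=0) - mu
    grad += cfg.w_card * 2.0 * (r[:, None] + c[None, :])
    d = _dist_matrix(lm_I, lm_J, cfg, dist)
    if d is not None:
        grad += cfg.w_dist * d
    return grad


def frank_wolfe(
    theta,
    kernel,
    lm_I=None,
    lm_J=None,
    cfg: MatchConfig = MatchConfig(),
    dist=None,
) -> Correspondence:
    """Minimise the relaxed objective over the unit box [0, 1]^{m x n}.

    Each iteration solves the linear subproblem over the box (a vertex
    with 1 wherever the gradient is negative), takes the exact line-search
    step for the quadratic objective (clipped to [0, 1]; step 2/(t+2) if
    the curvature is numerically non-positive) and stops once the
    Frank-Wolfe duality gap falls below ``cfg.tol``.  The objective is
    convex, so the optimum does not depend on the random initialisation.

    The returned correspondence is relaxed; ``meta`` carries the objective
    trajectory, final duality gap and iteration count.
    """
    th = _matrix(theta, "theta")
    z = _matrix(kernel, "kernel")
    m, n = th.shape[1], z.shape[0]
    if m < 1 or n < 1:
        raise ValueError("need at least one landmark on each side")
    d = _dist_matrix(lm_I, lm_J, cfg, dist)
    if d is not None and d.shape != (m, n):
        raise ValueError("distance matrix shape must be (m, n)")

    tht = th.T @ th
    mu = cfg.target_degree
    rng = np.random.default_rng(cfg.seed)
    e = rng.random((m, n))

    def objective(mat: np.ndarray) -> float:
        val = float(np.sum(((tht @ mat) * (mat @ z))))
        r = mat.sum(axis=1) - mu
        c = mat.sum(axis=0) - mu
        val += cfg.w_card * (float(r @ r) + float(c @ c))
        if d is not None:
            val += cfg.w_dist * float(np.sum(mat * d))
        return val

    history = [objective(e)]
    if not np.isfinite(history[0]):
        raise NumericalError("matching objective is non-finite; check features")
    gap = np.inf
    it = 0
    for it in range(1, cfg.max_iter + 1):
        grad = 2.0 * (tht @ e) @ z
        r = e.sum(axis=1) - mu
        c = e.sum(axis=0) - mu
        grad += cfg.w_card * 2.0 * (r[:, None] + c[None, :])
        if d is not None:
            grad += cfg.w_dist * d
        if not np.all(np.isfinite(grad)):
            raise NumericalError("non-finite gradient during Frank-Wolfe")

        s = (grad < 0).astype(float)
        step = s - e
        gap = float(-np.sum(grad * step))
        if gap <= cfg.tol:
            break

        # exact line search: O(E + g*step) is quadratic in g with curvature
        # 2*[Tr(Theta step Z step' Theta') + w_card*(||step 1||^2 + ||step' 1||^2)]
        quad = float(np.sum((tht @ step) * (step @ z)))
        quad += cfg.w_card * (
            float(np.sum(step.sum(axis=1) ** 2)) + float(np.sum(step.sum(axis=0) ** 2))
        )
        curvature = 2.0 * quad
        if curvature > 1e-15:
            gamma = min(max(gap / curvature, 0.0), 1.0)
        else:
            gamma = 2.0 / (it + 2.0)
        e = e + gamma * step
        np.clip(e, 0.0, 1.0, out=e)
        history.append(objective(e))

    logger.debug("frank_wolfe: %d iterations, gap=%.3g, objective=%.6g", it, gap, history[-1])
    return Correspondence(
        e,
        relaxed=True,
        meta={"objective": history, "gap": gap, "n_iter": it, "converged": gap <= cfg.tol},
    )


def round_correspondence(relaxed: Correspondence) -> Correspondence:
    """Round a relaxed correspondence to the nearest one-to-one binary one.

    Minimising ``||E* - E||_F^2`` over binary matrices with at most one 1
    per row and column is the linear assignment maximising the scores
    ``2 E - 1``; assignments with non-positive score (confidence <= 0.5)
    are discarded, so weakly matched rows yield no match at all.
    """
    e = _matrix(relaxed, "relaxed")
    if e.min() < -1e-9 or e.max() > 1 + 1e-9:
        raise ValueError("relaxed entries must lie in [0, 1]")
    scores = 2.0 * e - 1.0
    rows, cols = linear_sum_assignment(scores, maximize=True)
    keep = scores[rows, cols] > 0
    rows, cols = rows[keep], cols[keep]
    binary = np.zeros_like(e)
    binary[rows, cols] = 1.0
    pairs = sorted(
        ((int(i), int(j), float(e[i, j])) for i, j in zip(rows, cols)),
        key=lambda p: (-p[2], p[0], p[1]),
    )
    return Correspondence(binary, relaxed=False, pairs=tuple(pairs))


@dataclass(frozen=True)
class MatchResult:
    """Output of :func:`match_landmarks`: the binary matches, the fitted
    feature mapping, the (border-filtered) landmark sets and the relaxed
    solution the matches were rounded from."""

    correspondence: Correspondence
    mapping: MappingMatrix
    lm_I: LandmarkSet
    lm_J: LandmarkSet
    relaxed: Correspondence

    def matched_points(self) -> tuple[np.ndarray, np.ndarray]:
        """Pixel coordinates of matched landmark pairs, confidence order."""
        pairs = self.correspondence.pairs or ()
        pi = np.array([[*self.lm_I.coords[i]] for i, _, _ in pairs]).reshape(-1, 2)
        pj = np.array([[*self.lm_J.coords[j]] for _, j, _ in pairs]).reshape(-1, 2)
        return pi, pj


def _pairwise_costs(theta: np.ndarray, phi: np.ndarray, t: np.ndarray) -> np.ndarray:
    """``C_ij = ||theta_i - T phi_j||^2`` for all landmark pairs."""
    mapped = t @ phi
    sq_t = np.sum(theta**2, axis=0)[:, None]
    sq_m = np.sum(mapped**2, axis=0)[None, :]
    return np.maximum(sq_t + sq_m - 2.0 * theta.T @ mapped, 0.0)


def _sinkhorn(w: np.ndarray, iters: int = 30) -> np.ndarray:
    for _ in range(iters):
        w = w / np.maximum(w.sum(axis=1, keepdims=True), 1e-300)
        w = w / np.maximum(w.sum(axis=0, keepdims=True), 1e-300)
    return w


def _anneal(
    theta: np.ndarray,
    phi: np.ndarray,
    t: np.ndarray,
    ridge: float,
    dist_term: np.ndarray | None,
    n_temp: int = 20,
    factor: float = 0.85,
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic-annealing descent on F(E, T) from one starting mapping.

    Returns ``(F, row_idx, col_idx, T)`` for the final hard assignment.
    """
    m, n = theta.shape[1], phi.shape[1]

    def costs(tm):
        c = _pairwise_costs(theta, phi, tm)
        return c if dist_term is None else c + dist_term

    def confident_refit(c):
        # refit T on assigned pairs that pass the ratio test; forcing every
        # row into the update would drag T towards unmatchable landmarks
        rows, cols = linear_sum_assignment(c)
        conf = _ratio_confidence(c)[rows, cols]
        keep = conf > 0.5
        if keep.sum() < max(2, min(m, n) // 10):
            keep = np.argsort(-conf)[: max(2, min(m, n) // 4)]
        e = np.zeros((m, n))
        e[rows[keep], cols[keep]] = 1.0
        return rows, cols, solve_mapping(theta, phi, e, ridge).values

    c = costs(t)
    tau = float(np.median(c))
    for _ in range(n_temp):
        w = np.exp(-(c - c.min(axis=1, keepdims=True)) / max(tau, 1e-12))
        w = _sinkhorn(w)
        t = solve_mapping(theta, phi, w, ridge).values
        c = costs(t)
        tau *= factor
    prev = None
    for _ in range(6):
        rows, cols, t = confident_refit(c)
        c = costs(t)
        if tuple(cols) == prev:
            break
        prev = tuple(cols)
    rows, cols = linear_sum_assignment(c)
    f = float(c[rows, cols].sum()) + ridge * float(np.sum(t**2))
    return f, rows, cols, t


def _ratio_confidence(c: np.ndarray) -> np.ndarray:
    """Per-cell confidence from the cost's margin over the runner-up.

    ``conf_ij = s / (C_ij + s)`` with ``s`` the best cost in the same row
    excluding column j (and symmetrically for columns; the smaller of the
    two is kept).  The row/column minimum exceeds 0.5 exactly when it beats
    the runner-up — a Lowe-style ratio test — and every other cell falls
    below 0.5.
    """

    def one_axis(cm: np.ndarray) -> np.ndarray:
        n = cm.shape[1]
        if n == 1:
            return 1.0 / (1.0 + cm)
        part = np.partition(cm, 1, axis=1)
        m1, m2 = part[:, :1], part[:, 1:2]
        s = np.where(cm <= m1, m2, m1)
        denom = cm + s
        return np.where(denom > 0, s / np.where(denom > 0, denom, 1.0), 0.5)

    conf = np.minimum(one_axis(c), one_axis(c.T).T)
    return np.clip(conf, 0.0, 1.0)


def match_features(
    theta: FeatureMatrix,
    phi: FeatureMatrix,
    lm_I: LandmarkSet | None,
    lm_J: LandmarkSet | None,
    cfg: MatchConfig = MatchConfig(),
    dist=None,
    n_restarts: int = 3,
    gate=None,
) -> MatchResult:
    """Core matcher on precomputed features.

    Runs the Frank-Wolfe relaxation of the full objective, extracts the
    mapping it implies, refines (T, E) by annealed alternation on the
    pairwise objective (with ``n_restarts`` extra random-mapping starts),
    converts the final pairwise costs to ratio-test confidences discounted
    by the distance prior, and rounds to the one-to-one matching.

    ``gate``, when given, is a boolean (m, n) matrix of admissible pairs
    (used by the coarse-to-fine pyramid to restrict candidates to the
    neighbourhood of a predicted position); pairs outside it are excluded
    from the refinement and receive zero confidence.
    """
    th = _matrix(theta, "theta")
    ph = _matrix(phi, "phi")
    kernel = compute_Z(phi, cfg.ridge)
    d = _dist_matrix(lm_I, lm_J, cfg, dist)
    relaxed = frank_wolfe(theta, kernel, lm_I, lm_J, cfg, dist=d)

    dist_term = None if d is None else cfg.w_dist * d
    if gate is not None:
        gate = np.asarray(gate, dtype=bool)
        blocked = np.where(gate, 0.0, 1e6)
        dist_term = blocked if dist_term is None else dist_term + blocked
    starts = [solve_mapping(theta, phi, relaxed, cfg.ridge).values]
    k, l = th.shape[0], ph.shape[0]
    if k == l:
        # same descriptor family on both sides: the identity mapping is the
        # natural null hypothesis for the modality bridge
        starts.append(np.eye(k))
    rng = np.random.default_rng(cfg.seed + 77)
    for _ in range(n_restarts):
        q, _ = np.linalg.qr(rng.standard_normal((max(k, l), max(k, l))))
        starts.append(q[:k, :l])
    # each start competes twice: annealed (escapes local minima on hard
    # problems) and hard-only (annealing can wash out an already-good
    # start); the joint objective F picks the winner
    candidates = []
    for t0 in starts:
        candidates.append(_anneal(th, ph, t0, cfg.ridge, dist_term))
        candidates.append(_anneal(th, ph, t0, cfg.ridge, dist_term, n_temp=0))
    best = min(candidates, key=lambda r: r[0])
    _, _, _, t_final = best

    costs = _pairwise_costs(th, ph, t_final)
    if dist_term is not None:
        costs = costs + dist_term
    conf = _ratio_confidence(costs)
    if d is not None:
        # soft spatial gate mirroring the linear distance penalty
        conf = conf * np.exp(-cfg.w_dist * d)
    if gate is not None:
        conf = np.where(gate, conf, 0.0)
    rounded = round_correspondence(Correspondence(conf, relaxed=True))
    mapping = solve_mapping(theta, phi, rounded, cfg.ridge)
    if lm_I is None:
        lm_I = LandmarkSet(np.zeros((th.shape[1], 2)), np.ones(th.shape[1]))
    if lm_J is None:
        lm_J = LandmarkSet(np.zeros((ph.shape[1], 2)), np.ones(ph.shape[1]))
    return MatchResult(rounded, mapping, lm_I, lm_J, relaxed)


def match_landmarks(
    img_I: np.ndarray,
    img_J: np.ndarray,
    cfg: MatchConfig = MatchConfig(),
    max_points: int = 500,
    grid: int = 9,
    spacing: float = 1.5,
    predicted_transform=None,
    search_radius: float | None = None,
) -> MatchResult:
    """Full single-scale pipeline: detect, describe, relax, round, refit.

    ``predicted_transform``, when given, is a spatial transform in the
    normalised coordinate frame; the distance prior is then measured from
    the predicted position of each landmark rather than its raw position,
    and ``search_radius`` (normalised units) restricts candidate pairs to
    that neighbourhood of the prediction (used by the coarse-to-fine
    pyramid).
    """
    lm_I = detect_landmarks(img_I, max_points=max_points)
    lm_J = detect_landmarks(img_J, max_points=max_points)
    theta, lm_I = extract_gom(img_I, lm_I, grid=grid, spacing=spacing)
    phi, lm_J = extract_gom(img_J, lm_J, grid=grid, spacing=spacing)
    for name, lms in (("first", lm_I), ("second", lm_J)):
        if lms.count < 3:
            raise TooFewLandmarksError(
                f"only {lms.count} usable landmarks detected in the {name} image "
                "(need at least 3); try a larger or more structured image"
            )
    dist = None
    gate = None
    if cfg.w_dist > 0:
        a = lm_I.normalized_coords()
        if predicted_transform is not None:
            from .spatial import apply_transform

            a = apply_transform(predicted_transform, a)
        b = lm_J.normalized_coords()
        diff = a[:, None, :] - b[None, :, :]
        dist = np.sum(diff**2, axis=2)
        if predicted_transform is not None and search_radius is not None:
            gate = dist <= search_radius**2
    return match_features(theta, phi, lm_I, lm_J, cfg, dist=dist, gate=gate)


def write_matches_tsv(path, result: MatchResult) -> None:
    """Write matches as TSV ``i j x_i y_i x_j y_j confidence`` (best first)."""
    import pandas as pd

    rows = []
    for i, j, conf in result.correspondence.pairs or ():
        xi, yi = result.lm_I.coords[i]
        xj, yj = result.lm_J.coords[j]
        rows.append((i, j, xi, yi, xj, yj, conf))
    pd.DataFrame(
        rows, columns=["i", "j", "x_i", "y_i", "x_j", "y_j", "confidence"]
    ).to_csv(path, sep="\t", index=False)
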