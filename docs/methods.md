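# Methods

## Model

Two images I and J of the same scene, taken through different modalities,
share geometry but not intensity statistics.  The package assumes that the
modality difference acts *linearly in feature space*: if landmark i of I
(descriptor θᵢ ∈ ℝᵏ) corresponds to landmark j of J (descriptor φⱼ ∈ ℝˡ),
then θᵢ ≈ T φⱼ for one projection matrix T ∈ ℝ^{k×l} shared by all pairs —
in matrix form Θ E = T Φ with E the binary correspondence matrix.  T and E
are estimated jointly by minimising

    O(E) = O_m(E) + λ₁ O_c1(E) + λ₂ O_c2(E)

- **Data term.**  O_m(E) = min_T ‖ΘE − TΦ‖²_F + λ‖T‖²_F.  The inner
  problem is ridge regression, T* = ΘEΦ′(ΦΦ′+λI)⁻¹, and back-substitution
  gives the closed form O_m = Tr(ΘEZE′Θ′) with the reduced kernel
  Z = I − Φ′(ΦΦ′+λI)⁻¹Φ.  Z is symmetric PSD with eigenvalues
  λ/(σᵢ²+λ) on the row space of Φ (σᵢ its singular values) and 1 on the
  null space, so O_m is a convex quadratic in E.
- **Cardinality prior.**  O_c1 = ‖E1−μ1‖² + ‖E′1−μ1‖² pulls every row and
  column sum toward the target degree μ, discouraging the degenerate E = 0
  and many-to-one pile-ups.
- **Distance prior.**  O_c2 = Σᵢⱼ Eᵢⱼ dᵢⱼ, with dᵢⱼ the squared Euclidean
  distance between landmark positions on coordinates normalised by image
  width/height to [0, 1]; linear in E.

Weights λ = 0.6, λ₁ = 0.8, λ₂ = 0.1 and μ = 1.5 by default.  λ must be
positive (it also guarantees ΦΦ′+λI is invertible); the solver raises a
dedicated error suggesting λ > 0 when called with λ = 0 on rank-deficient
features.

## Optimisation: relax, refine, round

The binary constraint E ∈ {0,1}^{m×n} is relaxed to the unit box and the
convex objective minimised by Frank–Wolfe: each iteration solves the
linear subproblem over the box (place 1 wherever the gradient is
negative), takes the exact line-search step for the quadratic objective
(clipped to [0, 1]; 2/(t+2) fallback when the curvature is numerically
non-positive) and stops when the duality gap falls below `tol` (1e−6) or
after `max_iter` (500) iterations.  Convexity makes the optimum
independent of the random initialisation.

A convex relaxation of a matching objective cannot be rounded naively: its
unique minimiser is an *average* over many near-optimal matchings, because
spreading mass always lowers a convex quadratic.  On small instances one
can verify exhaustively that the true matching is the best *binary*
solution while the relaxed optimum is diffuse.  The relaxed solution is,
however, an excellent estimator of the mapping: T read off the relaxation
via the ridge closed form retains the modality bridge.  The matcher
therefore refines the pair (T, E) on the pairwise form of the same model,

    F(E, T) = Σᵢⱼ Eᵢⱼ (‖θᵢ − Tφⱼ‖² + λ₂ dᵢⱼ) + λ‖T‖²,

by deterministic annealing: alternate a Sinkhorn-balanced soft assignment
of the pairwise costs at temperature τ (initial τ = median cost, ×0.85
per step, 20 steps) with the closed-form ridge update of T, then switch to
hard assignment steps in which T is refitted only on pairs passing a
ratio test (forcing unmatchable landmarks into the update would drag T
off).  Each run starts from several mappings — the Frank–Wolfe estimate,
the identity (when k = l; the natural null hypothesis when both sides use
the same descriptor family) and three random orthogonal draws — and each
start is run both annealed and hard-only, because annealing can wash out
an already-good start.  The candidate with the lowest F wins.

Confidences are Lowe-style ratio tests of the final pairwise costs
(runner-up cost over the sum, row- and column-wise; the minimum of the
two), multiplied by the soft spatial gate exp(−λ₂ dᵢⱼ).  Rounding solves
the linear assignment maximising 2E−1 — the binary one-to-one matrix
nearest to the confidence matrix in Euclidean distance — and keeps only
assignments with confidence above 0.5, so ambiguous landmarks end up
unmatched rather than forced.

## Landmarks and descriptors

Keypoints are SIFT difference-of-Gaussians extrema (scikit-image
implementation).  Since that implementation does not expose the detector
response, keypoints are ranked by the |DoG| value recomputed at each
keypoint's detected scale; ties break by (y, x) order so detection is
deterministic.  Duplicate detections of one extremum (one per assigned
orientation) are collapsed.  `max_points` defaults to 500 — the intended
regime is hundreds of keypoints per image.

The descriptor samples the image gradient on a grid×grid lattice centred
on the keypoint (grid 9, step 1.5 × the detection scale), from the image
smoothed at the keypoint's scale (half-octave-quantised so each Gaussian
is computed once per image).  Each sample is encoded as the doubled-angle
pair (cos 2α, sin 2α) *weighted by the gradient magnitude* and the column
is L2-normalised.  Doubling the angle identifies opposite gradient
directions, so a contrast reversal between modalities leaves the
descriptor unchanged; magnitude weighting makes textureless lattice
points, whose orientation is undefined noise, contribute nothing —
without it the descriptor is unusable at realistic noise levels.
Landmarks whose lattice leaves the image are dropped together with their
columns.  Gradients are central differences with replicate padding.

## Spatial transforms

Affine (2×3, acting on [x, y, 1]) and the 12-parameter quadratic model
standard for the curved retinal surface (2×6 over [1, x, y, x², xy, y²]).
Fits are linear least squares on coordinates pre-scaled to the unit square
for conditioning; the coefficients are mapped back exactly by refitting
the composed map on a generic probe grid (both classes are closed under
affine changes of frame).  Rank-deficient configurations raise an error
naming the minimum pair count (3 for affine, 6 for quadratic).  Alignment
error is the mean Euclidean distance between transformed source points
and marked targets, in pixels.

Transforms fitted *from matches* use deterministic confidence-nested
consensus: candidate fits on nested prefixes of the confidence-ranked
matches, each scored by how many matches fall within 1.5 % of the
coordinate span, and the winner refitted on its inlier set.  This guards
against the confidently-wrong minority that detector dropout produces
(a landmark whose counterpart was never detected can still collect a
plausible-looking match).  No random sampling is involved; results are
reproducible bit-for-bit.

## Coarse-to-fine pyramid

Matching runs over an image pyramid (3 levels, downsampling rate 0.8,
anti-aliased resampling; a level below 16 px per side is refused).  The
coarsest level is matched first; an affine transform fitted to its
matches (in normalised coordinates, comparable across levels) predicts
each landmark's position at the next finer level, where the distance
prior is measured *from the prediction* and candidate pairs outside
`search_radius` (0.04 in normalised units, ≈10 px on a 256 px image) of
it are excluded.  Only the distance term changes, so every level
minimises the same objective family.  Each level's Frank–Wolfe starts
fresh (no warm start across levels — simpler and the per-level cost is
small).  If a coarse level cannot produce enough matches the prediction
simply is not updated; if the finest level underperforms with a
prediction in force, the pipeline falls back to single-level matching
with a warning.

## Synthetic data

The generator stands in for multimodal pairs with known ground truth.  A
base scene is a vessel-like texture — smoothed random-walk curves of
width 0.8–2.5 px and contrast 0.25–0.45 on a smooth background — chosen
because the flagship modality for this method is retinal multispectral
imaging and because curves give the DoG detector plentiful, localisable
structure.  One observed image is the base plus noise; the other is the
base intensity-remapped (gamma with γ ∈ [0.45, 2.2], inversion, or a
non-monotone triangular band remap), warped by a known affine or
quadratic transform (rotation ±4°, log-scale ±0.04, shear ±0.02,
translation ±12 px; quadratic terms sized for a few pixels of bending at
the borders), plus independent noise.  Noise is zero-mean Gaussian at
variances {0, 0.01, 0.02, 0.04, 0.08} on the [0, 1] intensity scale,
added after the remapping, and images are clipped to [0, 1] (variance
checks are restricted to pixels that cannot clip).  Warps are rendered by
per-pixel Newton inversion of the polynomial map (vectorised; exact for
affine, converges in a few iterations for the mild quadratics used).
Ground truth is exact: point p in the first frame corresponds to
true_transform(p) in the second.

`make_matching_problem` generates feature-space problems following the
linear-mapping model exactly: unit-norm random features φ, a random
orthogonal T₀ (so mapped features keep unit scale), a random permutation
π and θᵢ = T₀φ_{π(i)} + ε with ε ~ N(0, σ²), σ defaulting to 0.02
relative to the unit-norm features.

What the generator does *not* emulate: anatomically realistic vessel
trees and backgrounds, spatially varying illumination, occlusion and
partial overlap, sensor-specific noise (depth shadows, speckle), and
resolution differences between the two images.  Passing tests therefore
demonstrate the mechanics of the method under controlled modality change,
warp and noise — not clinical-grade performance on real retinal data.

## Numerical choices

- (ΦΦ′+λI) systems are solved by Cholesky factorisation, never explicit
  inversion; Z is symmetrised after assembly.
- Frank–Wolfe line search uses the closed-form quadratic step, clipped to
  [0, 1]; duality gap ≤ 1e−6 stops iteration.
- Annealing: 20 temperature steps ×0.85, 30 Sinkhorn sweeps per step;
  hard phase stops when the assignment repeats (≤ 6 iterations).
- Degenerate inputs: constant images yield an empty landmark set (not an
  error); an all-zero descriptor column stays zero rather than being
  normalised; fewer than 3 usable landmarks raise a too-few-landmarks
  error naming the count.
- Problem sizes in the test and acceptance protocols — 256 px images,
  `max_points` 150, 10 (tests) or 5 (acceptance script) replicates per
  noise variance — keep full runs to a few minutes while leaving the
  detector in its intended hundreds-of-keypoints regime.

## Known limitations

- A single global linear mapping cannot capture spatially varying
  modality relations (e.g. vignetting interacting with a nonlinear sensor
  response); the refinement inherits this model bias.
- The annealed refinement is a heuristic for a non-convex joint problem;
  with very low inlier fractions (heavy noise, variance ≥ 0.04 on the
  synthetic protocol) it can settle on a self-consistent wrong mapping,
  and alignment degrades accordingly — mirroring the rising error curves
  of the underlying evaluation protocol.
- One-to-one matching only; many-to-many correspondence and non-rigid
  dense warps are out of scope.
- The quadratic transform extrapolates poorly outside the convex hull of
  its fitting points, as any polynomial model does.
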