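# mmalign

Landmark-based alignment of **multimodal images** — pairs of images of the
same scene or organ captured by different sensors or spectral bands
(multispectral retinal imaging, flash/no-flash photography, RGB/depth),
whose intensities relate in complex, unknown ways even though the
underlying geometry is shared.  It is aimed at researchers in biological
and medical image analysis who need point correspondences and a spatial
transform between such pairs without hand-crafting a modality-specific
similarity measure.

## Method

Landmarks are detected in both images (difference-of-Gaussians / SIFT
keypoints) and each is described by a contrast-invariant
gradient-orientation descriptor, giving feature matrices
Θ = [θ₁ … θ_m] ∈ ℝ^{k×m} and Φ = [φ₁ … φ_n] ∈ ℝ^{l×n}.  The key modelling
assumption is that a single **linear mapping** T ∈ ℝ^{k×l} bridges the two
feature modalities: matched landmarks satisfy θᵢ ≈ T φⱼ, i.e. **Θ E = T Φ**
for the binary correspondence matrix E ∈ 𝔹^{m×n}.  T and E are solved
jointly from

```
min_E min_T ‖ΘE − TΦ‖² + λ‖T‖²  +  λ₁·O_c1(E)  +  λ₂·O_c2(E)
```

where the inner problem is ridge regression with the closed form
T = ΘEΦ′(ΦΦ′+λI)⁻¹; substituting it back reduces the data term to the
convex quadratic O_m = Tr(ΘEZE′Θ′) with Z = I − Φ′(ΦΦ′+λI)⁻¹Φ.  The prior
O_c1 = ‖E1−μ1‖² + ‖E′1−μ1‖² pulls row/column sums toward a target degree μ
and O_c2 = Σ E_ij·d_ij penalises spatially distant matches.  The binary
constraint is relaxed, the relaxation minimised by the Frank–Wolfe
(conditional-gradient) algorithm, and the continuous solution rounded to a
one-to-one matching by linear assignment.  Because the relaxed optimum of
a convex matching objective is an average over many near-optimal matchings,
the relaxation is used as an *estimator of T*, and (T, E) are then refined
by deterministic-annealing alternation on the pairwise form
Σ E_ij‖θᵢ−Tφⱼ‖² + λ‖T‖² before rounding (see `docs/methods.md`).

From the matched landmarks the package fits either an affine transform or
the 12-parameter quadratic model standard in retinal registration
(basis 1, x, y, x², xy, y² per coordinate), using a coarse-to-fine image
pyramid (3 scales, rate 0.8).  Defaults: λ = 0.6, λ₁ = 0.8, λ₂ = 0.1,
μ = 1.5.

## Worked example

```sh
# simulate a multimodal pair: gamma-remapped, affine-warped, noisy copy
mmalign simulate -o demo --size 256 --noise-var 0.01 --seed 1

# align the pair and write matches, transform and an overlay image
mmalign match demo/img_I.png demo/img_J.png -o demo/run --max-points 150

# evaluate against the simulated ground-truth points
mmalign eval demo/run/transform.json demo/truth_points.tsv
```

printed:

```
matches: 64
fit residual (px): 2.230
mean error (px): 1.8427
```

meaning 64 one-to-one landmark matches survived rounding, the affine
fit's RMS residual on its consensus matches was about two pixels (the
simulated noise jitters each detected keypoint), and the fitted transform
lands the ten held-out ground-truth points within 1.8 px of their true
positions on average.  `demo/run/overlay.png`
composites the warped second image (green) over the first (magenta):
aligned structure reads gray.

`mmalign noise-sweep -o sweep` repeats match + eval across Gaussian-noise
variances {0, 0.01, 0.02, 0.04, 0.08} and writes a CSV of mean errors.

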