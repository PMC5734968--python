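# Methods

This note documents the models, the numerical choices and the synthetic
test regime behind `meshffd`, and states where the design was genuinely
open and which reading we chose.

## Conventions

Images are 2-D arrays of intensities in [0, 1], indexed `img[y, x]` with
0-based pixel-center coordinates; points are `(x, y)`, homogeneous points
column vectors `(x, y, 1)ᵀ`. A homography `H` always maps reference
coordinates to float coordinates; matrices are stored with `H[2,2] = 1`
when that entry is nonzero, otherwise with unit Frobenius norm. All image
resampling is backward warping with bilinear intensity interpolation: the
output pixel takes the sample at its mapped position, so no holes appear.
Partial volume interpolation (PVI) is implemented as a joint-histogram
update rule (mass distributed over the four neighboring pixels' intensity
bins with bilinear weights), never as an intensity interpolator.

## Global stage

SIFT keypoints (scikit-image) are matched with a 0.8 nearest-neighbor
ratio test and cross-checking. A seeded RANSAC draws 4-point samples,
fits the exact homography by normalized DLT (Hartley pre-conditioning:
centroid at the origin, mean radius √2) and scores candidates by the
symmetric transfer residual; pairs with residual ≤ ε₁ are inliers, the
largest consensus wins with ties broken by the smaller mean residual, and
the winner is refit by least-squares DLT on its inliers followed by one
re-classification. Iterations stop early once an all-inlier sample is
99.9% likely under the current inlier ratio (the sampling sequence is a
pure function of the seed, so results stay reproducible). The reference
domain is then split into 4×4 equal sub-images; any sub-image holding at
least 8 inliers re-runs the same estimator at the tighter threshold ε₂ and
keeps only its survivors — 4-point fits on fewer pairs would overfit, so
sparser sub-images pass through unchanged. Defaults ε₁ = 3 px,
ε₂ = 1.5 px, 2000 iterations; all exposed in `RobustConfig`.

An apparent contradiction had to be resolved: the global model is defined
by `x' = H_g x`, yet the mesh stage is motivated by the pre-aligned float
point being *close to the reference point*, which requires the inverse
map. We fix `H_g` as reference→float and pre-align float points by
`x̃' = H_g⁻¹ x'`; the per-cell map is then composed as `H_g · H_cell`.
Correctness of the composition order is certified by a test that the
composed map reproduces matched corner positions on exact synthetic data,
not by symbol order.

## Mesh stage

The reference is tiled into β×β cells (β = 16), vertices at multiples of β
with clipped boundary cells when the image size is not a multiple. The
unknowns are the warped vertex positions; the energy has two quadratic
terms plus a tiny anchor:

* **Data term.** For each inlier pair, the reference point's bilinear
  weights over its cell's corners (TL, TR, BR, BL order) are applied to
  the *warped* corners, and the squared distance to the pre-aligned float
  point is penalized. (Written with the reference corners the term would
  not involve the unknowns; the warped corners are the only reading
  consistent with estimating them.)
* **Shape constraint.** For each cell, four corner triangles
  `(v̂, v₁, v₀)` — a corner and its two cyclic successors — must satisfy
  `v̂ = v₁ + s·R₉₀(v₀ − v₁)`, `s = ‖v − v₁‖/‖v₀ − v₁‖` from the reference
  triangle. This squared residual vanishes exactly for every similarity
  transform (rotation·scale commutes with R₉₀), which is verified as the
  similarity-null property. With our TL,TR,BR,BL enumeration the
  orientation that nulls the reference mesh is `R₉₀ = [[0,−1],[1,0]]`;
  triangle orientation is a free convention. Both energy terms are used
  squared — the stated sparse linear solve requires a quadratic form.
* **Anchor.** `1e-8·‖Ĉ − C_ref‖²` makes the system positive definite
  (cells without correspondences are otherwise only coupled through the
  constraint term); it is far below every test tolerance.

The normal equations are solved sparsely once per λ. The grid of
constraint weights is 10 equally spaced values on [0.3, 3.0]. For each
cell and each λ, the weighted NCC between the reference window at the cell
center and the float window at the composed map's image of that center is
evaluated; the per-cell winner (ties to the smaller λ, i.e. less
constraint) supplies that cell's homography. The plural phrasing of the
model-selection rule reads most naturally as per-cell selection, which is
the default; a `global` mode picking one λ by mean similarity is provided.
Mixing winners from different λ solutions can create sub-pixel seams at
shared vertices; each winning cell's homography is re-derived from its own
solution's vertices, and within one solution adjacent maps agree exactly
at shared corners (tested).

## Weighted NCC

Plain NCC weights every pixel equally; the weighted form multiplies each
pixel's contribution (in numerator and denominator alike) by
`w = w_r·w_s` with `w_r = exp(−Δψ/δ_r)` and `w_s = exp(−‖i‖/δ_s)`.
`Δψ` is the absolute difference of dominant gradient orientations wrapped
to [0, 180] — orientations, not vectors, are compared, and the original
formulation does not state wrapping. The dominant orientation at a pixel is the
peak (ties to the lowest bin, ψ = bin center) of a 36-bin histogram over
360° accumulated from an 8×8 region, each contribution weighted by
gradient magnitude times a Gaussian (σ = 2.5) of the offset; gradients are
central differences of the σ-smoothed image with replicated borders.
Per-pixel orientation maps are computed once per image (one correlation
per bin) and cached across the λ sweep. δ_s = β/2; δ_r has no
established value and defaults to 40° (≈ 4 histogram bins), exposed in
`WnccConfig`. Window means are unweighted; only the deviations are weighted. In the
δ_r, δ_s → ∞ limit all weights are 1 and the measure reduces exactly to
NCC (tested to 1e-12); the center pixel needs no special-casing because
both exponentials equal 1 at zero offset.

## Fine stage

The FFD is the standard uniform cubic B-spline lattice: spacing δ
(default 4 px), one ring of padding so every in-image pixel has a full 4×4
support, identity initialization at `φ_{i,j} = (iδ, jδ)`. Linear precision
of the cubic basis makes the identity lattice reproduce the identity map;
affine lattices reproduce affine maps to 1e-9 and have bending energy
below 1e-10 (both tested). The cost is

```
C(φ) = −(1/K)·Σ_k NMI_k + μ·(1/S)·∬ T_xx² + 2T_xy² + T_yy²
```

with μ = 0.01, the sum over the K in-image control points, NMI_k over the
4δ×4δ neighborhood of control k, and analytic spline second derivatives
sampled at every pixel center for the bending term. The per-neighborhood
NMI values are aggregated by mean — the original formulation leaves the
aggregation open, and the mean makes the objective's scale independent of the lattice size.

**Histogramming choice (a measured deviation).** Building the local joint
histograms by PVI makes the *start* of the optimization a local optimum:
at the identity lattice every mapped site lies on the pixel grid, its mass
lands in a single column bin, and any movement spreads it over four bins,
raising the joint entropy — the well-known grid-alignment artifact of
partial-volume estimators. Measured on a single-control recovery fixture,
the cost at the true lattice was *worse* than at identity for every bin
count tried and no descent step was ever accepted. Hard-binning the
bilinear-interpolated moving intensity removes that bias but leaves the
objective piecewise-constant, so finite-difference gradients are dominated
by bin-crossing noise (measured cosine between the FD gradient and the
true correction direction: 0.003). The implementation therefore bins the
interpolated intensity with *linear soft assignment* to its two nearest
bins, on both axes. This keeps the histogram continuous in the transform
and leaves neither a grid-alignment nor a sharpness bias; on the same
fixture the cost then decreases monotonically from identity toward the
true lattice. `local_nmi` retains an explicit `method="pvi"` option, and
PVI remains the first-class histogram primitive of the imaging core.

**Optimization.** Central finite differences (step 0.5 px — small enough
to stay inside a control's basin, large enough to average residual
histogram kinks) over every control coordinate give ∇C; the update steps
along −∇C with length ρ (the original update rule as written ascends C;
minimizing the cost is unambiguous, so we descend). With backtracking (default)
ρ is halved, up to 9 times, until the cost decreases, warm-starting each
iteration from twice the last accepted length capped at ρ; the cost trace
is then non-increasing by construction, and the run stops when ‖∇C‖ < ξ
(= 1e-4), when no backtracked step decreases the cost, or at the
iteration cap. Moving one control only changes the cost inside its 4δ×4δ
support, which the evaluator exploits: per-pixel basis weights, soft-bin
entries and per-window histograms with their entropy sums are cached, a
perturbation updates only the affected entries (entropy deltas evaluate
logarithms only at changed histogram cells), and the bending delta is
closed-form because the energy is quadratic in the controls. The gradient
is exact to machine precision against brute-force full recomputation
(tested).

## Synthetic test regime

The fixtures emulate the full evaluation regime with known ground truth:

* `make_texture` — band-limited Gaussian noise (periodic smoothing,
  default σ = 2 px) rescaled to [0, 1]; it has dense gradients everywhere,
  so SIFT keypoints and HOG orientations are well defined. It does not
  reproduce anatomical structure, intensity inhomogeneity or multi-modal
  contrast, so passing tests demonstrate geometric correctness of the
  machinery, not clinical performance.
* `random_homography` — the four image corners perturbed uniformly by up
  to a bound and fit exactly.
* `make_bspline_warp` — uniform random control displacements rescaled so
  the realized dense field's peak norm equals the request exactly
  (linearity of the spline); `max_disp ≤ spacing/2` keeps it invertible
  (positive Jacobian, tested at spacing/4).
* `make_correspondences` — inlier reference points uniform over the
  domain, float points warped plus isotropic Gaussian noise; outliers
  uniform over the float domain (a clean contamination model for matching
  errors); planted labels retained. Note the warped member of an image
  pair is the *reference* (`ref(p) = tex(warp(p))` via backward warping),
  which is exactly the geometry under which `x' = warp(x)` holds for the
  correspondences.

Study conditions frozen in the acceptance fixtures: robust stage — 300
matches, 0.3 px noise, outlier fractions up to 50%, ε₁ = 3; fine-stage
recovery — displacements ≤ δ/2 at δ = 4 on 128×128 (single control) and
64×64 (several controls); end-to-end — 256×256, corner shift 6 px,
B-spline field 8 px at 32 px spacing, intensity noise σ = 0.01, 1200
inliers + 25% outliers. For the end-to-end run the inlier threshold is
raised to ε₁ = 10 (the 8 px local deformation rides on top of the
homography and must not be rejected), the fine lattice uses δ = 8 with
step ρ = 8 and 8 iterations — at this scale the residual after the coarse
stage is a smooth field of 1–2 px, which the coarser, larger-stepped
descent removes in a handful of iterations; these sizes keep the full
suite comfortably reproducible on a single CPU.

## Known limitations

* The shape constraint biases the mesh against locally anisotropic
  deformation; on strongly non-similarity fields the coarse stage
  plateaus at ~1–2 px vertex error even at λ = 0.3, by design — the FFD
  stage exists to remove that residual.
* The normalized-gradient update moves the whole lattice by a fixed step
  length, so convergence measured in iterations degrades with lattice
  size; ρ should scale with the expected total correction.
* NMI estimated from 16×16 neighborhoods carries small-sample bias
  (≈ +0.1–0.2 at 32 bins); it cancels in comparisons but the absolute
  values are optimistic.
* Grayscale, single-resolution, 2-D only; no occlusion model; intensity
  relations between the images are assumed stationary within each local
  window.
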