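# meshffd

Coarse-to-fine **non-rigid registration of 2-D grayscale images** (e.g.
brain MRI slices or other medical imagery): given a fixed *reference* image
R and a *float* image F, estimate a smooth deformation that aligns F to R.
The deformation is built in three levels of increasing freedom:

1. **Global homography** `H_g` — SIFT correspondences `{x_i, x'_i}` are
   cleaned by a seeded RANSAC scored by the symmetric transfer residual
   `r_i = ½( d(x_i, H⁻¹x'_i) + d(x'_i, H x_i) )`, with a second rejection
   pass run per 4×4 sub-image at a tighter threshold.
2. **Mesh of local homographies** — the reference is tiled into β×β cells
   (β = 16); warped cell vertices `Ĉ` minimize the quadratic energy
   `E(Ĉ) = E_d(Ĉ) + λ E_c(Ĉ)`, where `E_d` fits the (pre-aligned) inlier
   correspondences through bilinear vertex interpolation and `E_c` is a
   shape-preserving term that vanishes exactly on similarity transforms.
   The constraint weight λ is chosen **per cell** from 10 values in
   [0.3, 3.0] by maximizing a *weighted NCC*: every window pixel is
   weighted by `exp(-Δψ/δ_r)·exp(-‖i‖/δ_s)`, combining the agreement of
   HOG dominant orientations ψ with distance to the window center.
3. **B-spline free-form deformation (FFD)** — a control lattice with
   spacing δ (default 4 px) refines the coarse result by minimizing
   `C(φ) = −C_NMI + μ·C_bend` (μ = 0.01): localized normalized mutual
   information over each control point's 4δ×4δ neighborhood, penalized by
   the bending energy (zero for affine maps), via backtracked steepest
   descent on finite-difference gradients.

## Worked example

Generate a synthetic pair with a known deformation (homography ∘ 8-px
B-spline field + intensity noise) and register it:

```bash
meshffd synth --out pair --seed 1 --size 256
meshffd register --ref pair/ref.png --float pair/float.png \
    --out run --seed 1 --eps1 10 --eps2 5 --delta 8 --rho 8 --max-iters 8
```

The library API gives the same pipeline with planted correspondences, so
stage accuracy can be measured against ground truth:

```python
import numpy as np, meshffd as m

size = (256, 256); seed = 1
tex  = m.make_texture(seed, *size)
warp = m.compose_warps(m.homography_warp(m.random_homography(seed+1, 6.0, size), size),
                       m.make_bspline_warp(seed+2, 32, 8.0, size), size)
ref, _ = m.warp_backward(tex, warp.mapping)
flt  = np.clip(tex + np.random.default_rng(seed+3).normal(0, 0.01, tex.shape), 0, 1)
cs   = m.make_correspondences(warp, 1200, 0.3, 300, seed+4, size)

cfg = m.PipelineConfig(seed=seed)
cfg.robust.eps1, cfg.robust.eps2 = 10.0, 5.0
cfg.ffd.delta, cfg.ffd.rho, cfg.ffd.max_iters = 8, 8.0, 8
res = m.register(ref, flt, cfg, correspondences=cs)
for stage in ("initial", "coarse", "fine"):
    print(stage, res.metrics[stage].as_dict())
```

prints (seed 1):

```
initial {'ssd': 0.024606, 'sad': 0.119007, 'ncc': 0.302526, 'nmi': 1.012790}
coarse  {'ssd': 0.004110, 'sad': 0.039074, 'ncc': 0.881890, 'nmi': 1.206748}
fine    {'ssd': 0.001987, 'sad': 0.013970, 'ncc': 0.943295, 'nmi': 1.501098}
```

SSD/SAD are per-pixel means on the [0, 1] intensity scale and should fall
toward 0 as alignment improves; NCC rises toward 1 and NMI toward 2. Here
the coarse mesh removes ~83% of the initial SSD and the FFD stage halves
the remainder (92% total reduction).

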