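"""Coarse registration: shape-preserving mesh warp and per-cell homographies.

The reference image is covered by a regular grid of beta x beta cells.  The
warped vertex positions C-hat minimize a quadratic energy

    E = E_d + lambda * E_c,

where E_d penalizes, for every inlier pair, the squared distance between the
bilinear combination of the warped cell corners (weights taken from the
reference point) and the pre-aligned float point Hg^-1 x', and E_c makes
each cell's four corner triangles follow a similarity transform (it vanishes
exactly on rotation+scale+translation maps, hence "shape preserving").  A
tiny anchor toward the reference vertices makes the system positive
definite.  Per cell, the exact 4-point homography between reference and
warped corners, composed with Hg, is the coarse map; the constraint weight
lambda is chosen per cell by maximizing the weighted NCC between the cell
center's support windows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from .errors import DegeneracyError, ValidationError
from .homography import apply_homography, fit_homography_dlt, normalize_homography
from .image import bilinear_sample
from .synthetic import CorrespondenceSet
from .wncc import WnccConfig, main_direction_map, wncc

__all__ = [
    "MeshGrid",
    "MeshEnergyConfig",
    "LocalHomographySet",
    "lambda_grid",
    "build_mesh",
    "bilinear_weights",
    "solve_mesh",
    "energy_terms",
    "cell_homography",
    "compose_final",
    "select_lambda",
    "coarse_warp",
]

# Rotation giving a zero constraint residual on the (identity) reference mesh
# with the TL,TR,BR,BL cyclic corner enumeration.
_R90 = np.array([[0.0, -1.0], [1.0, 0.0]])


def lambda_grid(lo: float = 0.3, hi: float = 3.0, n: int = 10) -> np.ndarray:
    """The constraint-weight grid: n equally spaced values on [lo, hi]."""
    if n < 1 or hi < lo or lo <= 0:
        raise ValidationError("invalid lambda grid specification")
    return np.linspace(lo, hi, n)


@dataclass
class MeshEnergyConfig:
    lambda_grid: np.ndarray = field(default_factory=lambda_grid)
    anchor_weight: float = 1e-8

    def __post_init__(self):
        lg = np.asarray(self.lambda_grid, dtype=float)
        if lg.size == 0 or np.any(lg <= 0) or np.any(np.diff(lg) <= 0) and lg.size > 1:
            raise ValidationError("lambda_grid must be non-empty, positive, increasing")
        self.lambda_grid = lg


class MeshGrid:
    """Regular beta-spaced cell grid over a width x height reference image.

    Vertex columns sit at 0, beta, 2*beta, ..., width (and likewise rows up
    to height), so boundary cells are clipped when the dimensions are not
    multiples of beta.  Cell (j, k) owns corners in the fixed order
    top-left, top-right, bottom-right, bottom-left.
    """

    def __init__(self, width: int, height: int, beta: int):
        if beta < 4:
            raise ValidationError("beta must be >= 4")
        if width < beta or height < beta:
            raise ValidationError("image must fit at least one full cell")
        self.width, self.height, self.beta = int(width), int(height), int(beta)
        self.xs = np.append(np.arange(0, width, beta, dtype=float), float(width))
        self.ys = np.append(np.arange(0, height, beta, dtype=float), float(height))
        if self.xs[-1] == self.xs[-2]:
            self.xs = self.xs[:-1]
        if self.ys[-1] == self.ys[-2]:
            self.ys = self.ys[:-1]
        self.n_cols = len(self.xs) - 1
        self.n_rows = len(self.ys) - 1
        gx, gy = np.meshgrid(self.xs, self.ys, indexing="ij")
        self.vertices = np.stack([gx, gy], axis=-1)  # (n_cols+1, n_rows+1, 2)

    def cell_of(self, x: float, y: float) -> tuple[int, int]:
        j = min(int(x // self.beta), self.n_cols - 1)
        k = min(int(y // self.beta), self.n_rows - 1)
        return j, k

    def corner_indices(self, j: int, k: int):
        """Vertex (ix, iy) indices of cell (j, k) in TL, TR, BR, BL order."""
        return [(j, k), (j + 1, k), (j + 1, k + 1), (j, k + 1)]

    def cell_bounds(self, j: int, k: int):
        return self.xs[j], self.xs[j + 1], self.ys[k], self.ys[k + 1]

    def cell_center(self, j: int, k: int):
        x0, x1, y0, y1 = self.cell_bounds(j, k)
        return np.array([(x0 + x1) / 2.0, (y0 + y1) / 2.0])


def build_mesh(width: int, height: int, beta: int = 16) -> MeshGrid:
    return MeshGrid(width, height, beta)


def bilinear_weights(p, cell_bounds) -> np.ndarray:
    """Corner weights (TL, TR, BR, BL) of a point inside a cell; sum to 1."""
    x0, x1, y0, y1 = cell_bounds
    x, y = float(p[0]), float(p[1])
    if not (x0 - 1e-9 <= x <= x1 + 1e-9 and y0 - 1e-9 <= y <= y1 + 1e-9):
        raise ValidationError("point outside cell")
    a = np.clip((x - x0) / (x1 - x0), 0.0, 1.0)
    b = np.clip((y - y0) / (y1 - y0), 0.0, 1.0)
    return np.array([(1 - a) * (1 - b), a * (1 - b), a * b, (1 - a) * b])


def _vertex_id(mesh: MeshGrid, ix: int, iy: int) -> int:
    return iy * (mesh.n_cols + 1) + ix


def _constraint_triangles(mesh: MeshGrid, j: int, k: int):
    """Per cell: 4 triangles (v_hat, v1, v0) with the reference scale ratio s.

    Corners are taken cyclically (c_t, c_{t+1}, c_{t+2}); the reference
    triangle is right-angled at v1, so v_hat - v1 = s * R90 (v0 - v1) holds
    exactly on the reference mesh.
    """
    ids = mesh.corner_indices(j, k)
    ref = np.array([mesh.vertices[ix, iy] for ix, iy in ids])
    out = []
    for t in range(4):
        vh, v1, v0 = t, (t + 1) % 4, (t + 2) % 4
        s = (np.linalg.norm(ref[vh] - ref[v1])
             / np.linalg.norm(ref[v0] - ref[v1]))
        out.append((ids[vh], ids[v1], ids[v0], s))
    return out


def solve_mesh(pairs: CorrespondenceSet, H_g: np.ndarray, mesh: MeshGrid,
               lam: float, cfg: MeshEnergyConfig | None = None) -> np.ndarray:
    """Minimize E_d + lam*E_c (+ anchor) over the warped vertex positions.

    Float points are pre-aligned by Hg^-1 so the mesh is estimated in a
    frame already close to the reference.  Returns the warped vertices as
    an array with the same (n_cols+1, n_rows+1, 2) layout as the mesh.
    """
    cfg = cfg or MeshEnergyConfig()
    if lam <= 0:
        raise ValidationError("lambda must be > 0")
    nvx, nvy = mesh.n_cols + 1, mesh.n_rows + 1
    nunk = 2 * nvx * nvy
    rows, cols, vals, b = [], [], [], []

    def add(ri, entries, rhs):
        for cj, v in entries:
            rows.append(ri)
            cols.append(cj)
            vals.append(v)
        b.append(rhs)

    ri = 0
    if len(pairs) > 0:
        pre = apply_homography(np.linalg.inv(H_g), pairs.flt_pts)
        for p, q in zip(pairs.ref_pts, pre):
            if not np.all(np.isfinite(q)):
                continue
            j, k = mesh.cell_of(min(max(p[0], 0), mesh.width - 1e-9),
                                min(max(p[1], 0), mesh.height - 1e-9))
            wts = bilinear_weights(np.clip(p, 0, [mesh.width, mesh.height]),
                                   mesh.cell_bounds(j, k))
            vids = [_vertex_id(mesh, ix, iy) for ix, iy in mesh.corner_indices(j, k)]
            add(ri, [(2 * v, w) for v, w in zip(vids, wts)], q[0]); ri += 1
            add(ri, [(2 * v + 1, w) for v, w in zip(vids, wts)], q[1]); ri += 1

    sl = np.sqrt(lam)
    for j in range(mesh.n_cols):
        for k in range(mesh.n_rows):
            for (vh, v1, v0, s) in _constraint_triangles(mesh, j, k):
                ih, i1, i0 = (_vertex_id(mesh, *vh), _vertex_id(mesh, *v1),
                              _vertex_id(mesh, *v0))
                # residual_x = xh - x1 + s*y0 - s*y1
                add(ri, [(2 * ih, sl), (2 * i1, -sl),
                         (2 * i0 + 1, s * sl), (2 * i1 + 1, -s * sl)], 0.0)
                ri += 1
                # residual_y = yh - y1 - s*x0 + s*x1
                add(ri, [(2 * ih + 1, sl), (2 * i1 + 1, -sl),
                         (2 * i0, -s * sl), (2 * i1, s * sl)], 0.0)
                ri += 1

    sa = np.sqrt(cfg.anchor_weight)
    ref_flat = np.zeros(nunk)
    for ix in range(nvx):
        for iy in range(nvy):
            v = _vertex_id(mesh, ix, iy)
            ref_flat[2 * v:2 * v + 2] = mesh.vertices[ix, iy]
    for u in range(nunk):
        add(ri, [(u, sa)], sa * ref_flat[u])
        ri += 1

    A = sp.csr_matrix((vals, (rows, cols)), shape=(ri, nunk))
    AtA = (A.T @ A).tocsc()
    Atb = A.T @ np.asarray(b)
    try:
        x = spsolve(AtA, Atb)
    except Exception as exc:  # pragma: no cover - singular despite anchor
        raise ValidationError(f"mesh system could not be solved: {exc}") from exc
    if not np.all(np.isfinite(x)):
        raise ValidationError("mesh solution contains non-finite vertices")

    warped = np.zeros_like(mesh.vertices)
    for ix in range(nvx):
        for iy in range(nvy):
            v = _vertex_id(mesh, ix, iy)
            warped[ix, iy] = x[2 * v:2 * v + 2]
    return warped


def energy_terms(mesh: MeshGrid, warped: np.ndarray, pairs: CorrespondenceSet,
                 H_g: np.ndarray) -> tuple[float, float]:
    """(E_d, E_c) of a warped-vertex configuration (squared-residual sums)."""
    e_d = 0.0
    if len(pairs) > 0:
        pre = apply_homography(np.linalg.inv(H_g), pairs.flt_pts)
        for p, q in zip(pairs.ref_pts, pre):
            j, k = mesh.cell_of(min(max(p[0], 0), mesh.width - 1e-9),
                                min(max(p[1], 0), mesh.height - 1e-9))
            wts = bilinear_weights(np.clip(p, 0, [mesh.width, mesh.height]),
                                   mesh.cell_bounds(j, k))
            pos = sum(w * warped[ix, iy] for w, (ix, iy)
                      in zip(wts, mesh.corner_indices(j, k)))
            e_d += float(((pos - q) ** 2).sum())
    e_c = 0.0
    for j in range(mesh.n_cols):
        for k in range(mesh.n_rows):
            for (vh, v1, v0, s) in _constraint_triangles(mesh, j, k):
                r = (warped[vh] - warped[v1]
                     - s * (_R90 @ (warped[v0] - warped[v1])))
                e_c += float((r ** 2).sum())
    return e_d, e_c


def cell_homography(ref_corners: np.ndarray, warped_corners: np.ndarray) -> np.ndarray:
    """Exact 4-point homography mapping reference corners to warped corners."""
    return fit_homography_dlt(np.asarray(ref_corners, dtype=float),
                              np.asarray(warped_corners, dtype=float))


def compose_final(H_cell: np.ndarray, H_g: np.ndarray) -> np.ndarray:
    """The single reference -> float map of a cell.

    H_cell maps reference coordinates into the pre-aligned frame and Hg maps
    that frame into the float image, so the composition is Hg . H_cell.
    """
    return normalize_homography(np.asarray(H_g) @ np.asarray(H_cell))


@dataclass
class LocalHomographySet:
    """Per-cell composed reference -> float homographies (+ diagnostics)."""

    mesh: MeshGrid
    maps: np.ndarray           # (n_cols, n_rows, 3, 3)
    chosen_lambda: np.ndarray  # (n_cols, n_rows)
    score: np.ndarray          # winning WNCC per cell

    def cell_map(self, j: int, k: int) -> np.ndarray:
        return self.maps[j, k]


def _cell_homographies(mesh: MeshGrid, warped: np.ndarray, H_g: np.ndarray,
                       j: int, k: int) -> np.ndarray:
    ids = mesh.corner_indices(j, k)
    ref_c = np.array([mesh.vertices[ix, iy] for ix, iy in ids])
    war_c = np.array([warped[ix, iy] for ix, iy in ids])
    try:
        Hc = cell_homography(ref_c, war_c)
    except DegeneracyError as exc:
        raise DegeneracyError(f"degenerate warped cell ({j}, {k})") from exc
    return compose_final(Hc, H_g)


def select_lambda(solutions, ref: np.ndarray, flt: np.ndarray,
                  H_g: np.ndarray, mesh: MeshGrid,
                  wncc_cfg: WnccConfig | None = None,
                  mode: str = "per-cell") -> LocalHomographySet:
    """Constraint-weight selection by maximum weighted NCC.

    ``solutions`` is a sequence of (lam, warped_vertices).  For every cell
    and every lam, the similarity between the reference window at the cell
    center and the float window at the composed map's image of that center
    is evaluated.  In ``per-cell`` mode each cell's winner (ties -> smaller
    lam) supplies that cell's homography; in ``global`` mode a single lam
    maximizing the mean similarity is chosen for the whole mesh.  Cells
    whose center maps outside the float image for every lam fall back to
    the smallest lam.
    """
    if mode not in ("per-cell", "global"):
        raise ValidationError(f"unknown lambda-selection mode: {mode}")
    wncc_cfg = wncc_cfg or WnccConfig(beta=mesh.beta)
    solutions = sorted(solutions, key=lambda t: t[0])
    ref_psi, _ = main_direction_map(ref, wncc_cfg)
    flt_psi, _ = main_direction_map(flt, wncc_cfg)
    hf, wf = flt.shape

    nc, nr = mesh.n_cols, mesh.n_rows
    nl = len(solutions)
    scores = np.full((nl, nc, nr), np.nan)
    all_maps = np.zeros((nl, nc, nr, 3, 3))
    for li, (lam, warped) in enumerate(solutions):
        for j in range(nc):
            for k in range(nr):
                Hjk = _cell_homographies(mesh, warped, H_g, j, k)
                all_maps[li, j, k] = Hjk
                center = mesh.cell_center(j, k)
                c_prime = apply_homography(Hjk, center)[0]
                if not (np.all(np.isfinite(c_prime))
                        and 0 <= c_prime[0] <= wf - 1 and 0 <= c_prime[1] <= hf - 1):
                    continue
                try:
                    scores[li, j, k] = wncc(ref, flt, center, c_prime, wncc_cfg,
                                            ref_psi=ref_psi, flt_psi=flt_psi)
                except ValidationError:
                    continue

    maps = np.zeros((nc, nr, 3, 3))
    lam_out = np.zeros((nc, nr))
    score = np.full((nc, nr), np.nan)
    lams = np.array([lam for lam, _ in solutions])
    if mode == "global":
        means = np.array([np.nanmean(scores[li]) if np.any(np.isfinite(scores[li]))
                          else -np.inf for li in range(nl)])
        li = int(np.argmax(means))  # argmax takes the first (smallest lam) on ties
        maps[:] = all_maps[li]
        lam_out[:] = lams[li]
        score[:] = scores[li]
        return LocalHomographySet(mesh=mesh, maps=maps,
                                  chosen_lambda=lam_out, score=score)

    for j in range(nc):
        for k in range(nr):
            col = scores[:, j, k]
            if np.all(np.isnan(col)):
                warnings.warn(f"cell ({j},{k}) center maps outside the float "
                              "image for every lambda; falling back to the "
                              "smallest lambda")
                li = 0
            else:
                li = int(np.nanargmax(col))  # first max -> smaller lam on ties
            maps[j, k] = all_maps[li, j, k]
            lam_out[j, k] = lams[li]
            score[j, k] = scores[li, j, k]
    return LocalHomographySet(mesh=mesh, maps=maps, chosen_lambda=lam_out,
                              score=score)


def coarse_warp(flt: np.ndarray, local_maps: LocalHomographySet,
                ref_size=None):
    """Backward-warp the float image through the per-cell homographies.

    Each reference pixel is sampled from the float image at its cell's
    composed map; out-of-bounds samples become 0 and are masked False.
    """
    mesh = local_maps.mesh
    if ref_size is None:
        ref_size = (mesh.width, mesh.height)
    w, h = ref_size
    out = np.zeros((h, w))
    valid = np.zeros((h, w), dtype=bool)
    hf, wf = flt.shape
    for j in range(mesh.n_cols):
        for k in range(mesh.n_rows):
            x0, x1, y0, y1 = mesh.cell_bounds(j, k)
            xa, xb = int(x0), min(int(x1), w)
            ya, yb = int(y0), min(int(y1), h)
            if xb <= xa or yb <= ya:
                continue
            yy, xx = np.mgrid[ya:yb, xa:xb]
            pts = np.column_stack([xx.ravel().astype(float),
                                   yy.ravel().astype(float)])
            mapped = apply_homography(local_maps.maps[j, k], pts)
            # snap float-precision residue so identity maps resample exactly
            r = np.round(mapped)
            mapped = np.where(np.abs(mapped - r) < 1e-9, r, mapped)
            ok = ((mapped[:, 0] >= 0) & (mapped[:, 0] <= wf - 1)
                  & (mapped[:, 1] >= 0) & (mapped[:, 1] <= hf - 1)
                  & np.all(np.isfinite(mapped), axis=1))
            block = np.zeros(len(pts))
            if np.any(ok):
                block[ok] = bilinear_sample(flt, mapped[ok])
            out[ya:yb, xa:xb] = block.reshape(yb - ya, xb - xa)
            valid[ya:yb, xa:xb] = ok.reshape(yb - ya, xb - xa)
    return out, valid
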