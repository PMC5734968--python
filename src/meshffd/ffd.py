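"""Fine registration: cubic B-spline free-form deformation (FFD).

The deformation T(x, y) = sum_{l,m} B_l(u) B_m(v) phi_{i+l, j+m} is driven by
a lattice of control points with uniform spacing delta, padded by one ring so
every in-image pixel has full 4x4 support.  The objective is

    C(phi) = -mean_k NMI_k + mu * bending_energy,

where NMI_k is the normalized mutual information between the 4delta x 4delta
pixel neighborhood of control k in the reference image and the same sites of
the moving image sampled through T (joint histograms from soft-binned
intensities, continuous in T; partial volume accumulation is available as an
option), and the bending energy integrates squared second derivatives of T
over the image (zero exactly for affine maps).  Optimization is steepest
descent on central finite differences with an optional backtracking step
control; moving one control point only changes cost terms inside its 4delta
support, which the evaluator exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .image import JointHistogram, intensity_bin, nmi_from_hist, pvi_accumulate, warp_backward

__all__ = [
    "bspline_basis",
    "ControlLattice",
    "FFDConfig",
    "FFDResult",
    "ffd_transform",
    "bending_energy",
    "local_nmi",
    "cost",
    "optimize",
    "fine_warp",
]


def _basis(u: np.ndarray) -> np.ndarray:
    """Vectorized cubic uniform B-spline basis values, shape (..., 4)."""
    u = np.asarray(u, dtype=float)
    return np.stack([
        (1 - u) ** 3 / 6.0,
        (3 * u ** 3 - 6 * u ** 2 + 4) / 6.0,
        (-3 * u ** 3 + 3 * u ** 2 + 3 * u + 1) / 6.0,
        u ** 3 / 6.0,
    ], axis=-1)


def _basis_d1(u: np.ndarray) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    return np.stack([
        -((1 - u) ** 2) / 2.0,
        (3 * u ** 2 - 4 * u) / 2.0,
        (-3 * u ** 2 + 2 * u + 1) / 2.0,
        u ** 2 / 2.0,
    ], axis=-1)


def _basis_d2(u: np.ndarray) -> np.ndarray:
    u = np.asarray(u, dtype=float)
    return np.stack([1 - u, 3 * u - 2, 1 - 3 * u, u], axis=-1)


def bspline_basis(u: float) -> np.ndarray:
    """The four cubic B-spline basis values (B0..B3) at local coordinate u."""
    if not (0.0 <= u < 1.0):
        raise ValidationError(f"u must be in [0, 1), got {u}")
    return _basis(float(u))


@dataclass
class ControlLattice:
    """Uniform B-spline control lattice over a width x height image.

    ``points[a, b]`` is the position of control index (i, j) = (a-1, b-1);
    the one-ring padding (indices -1 and n+1, n+2) keeps the 4x4 support of
    index arithmetic i = floor(x/delta)-1 valid everywhere in the image.
    At identity, control (i, j) sits at (i*delta, j*delta).
    """

    delta: int
    width: int
    height: int
    points: np.ndarray  # (na, nb, 2): axis 0 indexes x-controls, axis 1 y-controls

    @classmethod
    def identity(cls, width: int, height: int, delta: int) -> "ControlLattice":
        if delta < 2:
            raise ValidationError("control spacing delta must be >= 2")
        na = (width - 1) // delta + 4
        nb = (height - 1) // delta + 4
        ii, jj = np.meshgrid(np.arange(na) - 1, np.arange(nb) - 1, indexing="ij")
        pts = np.stack([ii * float(delta), jj * float(delta)], axis=-1)
        return cls(delta=int(delta), width=int(width), height=int(height), points=pts)

    def copy(self) -> "ControlLattice":
        return ControlLattice(self.delta, self.width, self.height, self.points.copy())

    def identity_points(self) -> np.ndarray:
        return ControlLattice.identity(self.width, self.height, self.delta).points

    def inimage_control_indices(self):
        """(a, b) array indices of controls whose lattice position is in-image."""
        na, nb = self.points.shape[:2]
        out = []
        for a in range(na):
            for b in range(nb):
                x, y = (a - 1) * self.delta, (b - 1) * self.delta
                if 0 <= x <= self.width - 1 and 0 <= y <= self.height - 1:
                    out.append((a, b))
        return out

    def to_csv(self, path) -> None:
        na, nb = self.points.shape[:2]
        with open(path, "w") as fh:
            fh.write(f"# delta={self.delta} width={self.width} height={self.height} "
                     f"na={na} nb={nb}\n")
            fh.write("a,b,x,y\n")
            for a in range(na):
                for b in range(nb):
                    fh.write(f"{a},{b},{float(self.points[a, b, 0])!r},"
                             f"{float(self.points[a, b, 1])!r}\n")

    @classmethod
    def from_csv(cls, path) -> "ControlLattice":
        with open(path) as fh:
            header = fh.readline().lstrip("# ").split()
            meta = dict(kv.split("=") for kv in header)
            fh.readline()
            rows = np.loadtxt(fh, delimiter=",")
        na, nb = int(meta["na"]), int(meta["nb"])
        pts = np.zeros((na, nb, 2))
        pts[rows[:, 0].astype(int), rows[:, 1].astype(int)] = rows[:, 2:4]
        return cls(delta=int(meta["delta"]), width=int(meta["width"]),
                   height=int(meta["height"]), points=pts)


@dataclass
class FFDConfig:
    """Tunables of the fine stage (the method's standard defaults)."""

    delta: int = 4          # control spacing, px
    mu: float = 0.01        # bending-energy weight
    rho: float = 1.0        # descent step length, px
    xi: float = 1e-4        # gradient-norm stopping threshold
    max_iters: int = 200
    bins: int = 32          # joint-histogram bins
    fd_step: float = 0.5    # finite-difference step, px
    backtracking: bool = True

    def __post_init__(self):
        if self.mu < 0 or self.rho <= 0 or self.xi <= 0:
            raise ValidationError("require mu >= 0, rho > 0, xi > 0")


def ffd_transform(lattice: ControlLattice, pts: np.ndarray) -> np.ndarray:
    """Evaluate T at (n, 2) point(s) inside the image domain."""
    p = np.atleast_2d(np.asarray(pts, dtype=float))
    w, h, d = lattice.width, lattice.height, lattice.delta
    if np.any((p[:, 0] < 0) | (p[:, 0] > w - 1) | (p[:, 1] < 0) | (p[:, 1] > h - 1)):
        raise ValidationError("point outside image domain")
    fx, fy = p[:, 0] / d, p[:, 1] / d
    ix, iy = np.floor(fx).astype(int), np.floor(fy).astype(int)
    Bu, Bv = _basis(fx - ix), _basis(fy - iy)
    out = np.zeros_like(p)
    for l in range(4):
        for m in range(4):
            out += (Bu[:, l] * Bv[:, m])[:, None] * lattice.points[ix + l, iy + m]
    # snap float-precision residue so the identity lattice maps exactly
    r = np.round(out)
    out = np.where(np.abs(out - r) < 1e-9, r, out)
    if np.asarray(pts).ndim == 1:
        return out[0]
    return out


def _second_derivative_maps(lattice: ControlLattice, ys, xs):
    """Txx, Txy, Tyy over a pixel grid, each (ny, nx, 2)."""
    d = float(lattice.delta)
    fx, fy = xs / d, ys / d
    ix, iy = np.floor(fx).astype(int), np.floor(fy).astype(int)
    u, v = fx - ix, fy - iy
    B0u, B1u, B2u = _basis(u), _basis_d1(u), _basis_d2(u)
    B0v, B1v, B2v = _basis(v), _basis_d1(v), _basis_d2(v)
    shape = (len(ys), len(xs), 2)
    txx = np.zeros(shape)
    txy = np.zeros(shape)
    tyy = np.zeros(shape)
    for l in range(4):
        for m in range(4):
            P = lattice.points[ix[None, :] + l, iy[:, None] + m]
            txx += (B2u[None, :, l, None] * B0v[:, None, m, None]) * P
            txy += (B1u[None, :, l, None] * B1v[:, None, m, None]) * P
            tyy += (B0u[None, :, l, None] * B2v[:, None, m, None]) * P
    return txx / d ** 2, txy / d ** 2, tyy / d ** 2


def bending_energy(lattice: ControlLattice) -> float:
    """Mean over pixel centers of Txx^2 + 2 Txy^2 + Tyy^2, both components."""
    xs = np.arange(lattice.width, dtype=float)
    ys = np.arange(lattice.height, dtype=float)
    txx, txy, tyy = _second_derivative_maps(lattice, ys, xs)
    integrand = (txx ** 2 + 2.0 * txy ** 2 + tyy ** 2).sum(axis=2)
    return float(integrand.mean())


def _soft_bins(v: np.ndarray, bins: int, valid: np.ndarray):
    """Linear soft assignment of intensities to their two nearest bins.

    Mass (1-t, t) goes to the bins bracketing the intensity's continuous
    bin coordinate; at the scale edges both entries collapse to the
    boundary bin.  Returns (cols, wgts) with a trailing axis of length 2.
    """
    c = np.asarray(v, dtype=float) * bins - 0.5
    f = np.floor(c)
    t = c - f
    b0 = np.clip(f.astype(int), 0, bins - 1)
    b1 = np.clip(f.astype(int) + 1, 0, bins - 1)
    cols = np.stack([b0, b1], axis=-1)
    wgts = np.stack([(1.0 - t) * valid, t * valid], axis=-1)
    return cols, wgts


def _control_window(lattice: ControlLattice, a: int, b: int):
    """Half-open pixel slices of the 4delta x 4delta support of control (a, b)."""
    d = lattice.delta
    i, j = a - 1, b - 1
    x0, x1 = max(0, (i - 2) * d), min(lattice.width, (i + 2) * d)
    y0, y1 = max(0, (j - 2) * d), min(lattice.height, (j + 2) * d)
    return slice(y0, y1), slice(x0, x1)


def local_nmi(ref: np.ndarray, moving: np.ndarray, lattice: ControlLattice,
              control_index, cfg: FFDConfig, method: str = "soft") -> float | None:
    """NMI over the 4delta x 4delta neighborhood of one control point.

    Reference intensities at the neighborhood's integer sites form the rows;
    the moving image sampled through T forms the columns.  The default
    ``method="soft"`` bins the bilinear-interpolated moving intensity with
    linear soft assignment to its two nearest bins, which keeps the
    objective continuous in the transform and free of the integer-grid
    sharpness bias that partial-volume accumulation exhibits;
    ``method="pvi"`` builds the histogram by partial volume interpolation
    instead.  Returns None when the neighborhood misses the image; an empty
    overlap scores 1 (the no-information floor).
    """
    i, j = control_index
    ysl, xsl = _control_window(lattice, i + 1, j + 1)
    if ysl.stop <= ysl.start or xsl.stop <= xsl.start:
        return None
    yy, xx = np.mgrid[ysl, xsl]
    sites = np.column_stack([xx.ravel().astype(float), yy.ravel().astype(float)])
    if method == "pvi":
        hist = pvi_accumulate(ref, moving, lambda p: ffd_transform(lattice, p),
                              sites, bins=cfg.bins)
    elif method == "soft":
        h, w = moving.shape
        q = ffd_transform(lattice, sites)
        ok = ((q[:, 0] >= 0) & (q[:, 0] <= w - 1)
              & (q[:, 1] >= 0) & (q[:, 1] <= h - 1))
        counts = np.zeros((cfg.bins, cfg.bins))
        if np.any(ok):
            rv = ref[sites[ok, 1].astype(int), sites[ok, 0].astype(int)]
            from .image import bilinear_sample
            iv = np.asarray(bilinear_sample(moving, q[ok]))
            rc, rw = _soft_bins(rv, cfg.bins, np.ones_like(rv))
            cc, cw = _soft_bins(iv, cfg.bins, np.ones_like(iv))
            for i in range(2):
                for j in range(2):
                    np.add.at(counts, (rc[:, i], cc[:, j]), rw[:, i] * cw[:, j])
        hist = JointHistogram(counts)
    else:
        raise ValidationError(f"unknown local_nmi method: {method}")
    if hist.total_mass <= 0:
        return 1.0
    return nmi_from_hist(hist)


class _CostEvaluator:
    """Incremental evaluator of C(phi) and its finite-difference gradient.

    Basis weights, reference row bins and per-control support windows depend
    only on geometry and are precomputed once; lattice-dependent state (T,
    PVI bin/weight tables, per-control NMI, bending integrand) is cached and
    patched locally when a single control is perturbed.
    """

    def __init__(self, ref: np.ndarray, moving: np.ndarray, cfg: FFDConfig):
        self.ref = np.asarray(ref, dtype=float)
        self.moving = np.asarray(moving, dtype=float)
        self.cfg = cfg
        self.h, self.w = self.ref.shape
        self.lattice = ControlLattice.identity(self.w, self.h, cfg.delta)
        d = float(cfg.delta)

        xs = np.arange(self.w, dtype=float)
        ys = np.arange(self.h, dtype=float)
        self.ix = np.floor(xs / d).astype(int)   # (w,)
        self.iy = np.floor(ys / d).astype(int)   # (h,)
        self.Bu = _basis(xs / d - self.ix)       # (w, 4)
        self.Bv = _basis(ys / d - self.iy)       # (h, 4)

        B = cfg.bins
        # reference (row) intensities soft-binned once; the moving (column)
        # side is soft-binned per transform in _sample_region
        self.rowc, self.roww = _soft_bins(self.ref, B, np.ones_like(self.ref))

        # basis derivative tables for the bending quadratic form
        ux = xs / d - self.ix
        vy = ys / d - self.iy
        self.B1u, self.B2u = _basis_d1(ux), _basis_d2(ux)
        self.B1v, self.B2v = _basis_d1(vy), _basis_d2(vy)

        na, nb = self.lattice.points.shape[:2]
        self.na, self.nb = na, nb
        # controls with a nonempty support window are the free variables
        self.var_controls = []
        self.windows = {}
        self.wpatch = {}
        self.bendpatch = {}
        for a in range(na):
            for b in range(nb):
                ysl, xsl = _control_window(self.lattice, a, b)
                if ysl.stop <= ysl.start or xsl.stop <= xsl.start:
                    continue
                self.var_controls.append((a, b))
                self.windows[(a, b)] = (ysl, xsl)
                xr = np.arange(xsl.start, xsl.stop)
                yr = np.arange(ysl.start, ysl.stop)
                lx = a - self.ix[xr]             # in 0..3 within the window
                my = b - self.iy[yr]
                self.wpatch[(a, b)] = (self.Bv[yr, my][:, None]
                                       * self.Bu[xr, lx][None, :])
                # second-derivative coefficient patches (bending is quadratic
                # in the controls, so its perturbation delta is closed-form)
                cxx = (self.B0v_at(yr, my)[:, None] * self.B2u[xr, lx][None, :]) / d ** 2
                cxy = (self.B1v[yr, my][:, None] * self.B1u[xr, lx][None, :]) / d ** 2
                cyy = (self.B2v[yr, my][:, None] * self.B0u_at(xr, lx)[None, :]) / d ** 2
                q2 = float((cxx ** 2 + 2 * cxy ** 2 + cyy ** 2).sum())
                self.bendpatch[(a, b)] = (cxx, cxy, cyy, q2)
        inimg = set(self.lattice.inimage_control_indices())
        self.nmi_controls = [c for c in self.var_controls if c in inimg]
        self.n_nmi = len(self.nmi_controls)
        self.nmi_pos = {c: k for k, c in enumerate(self.nmi_controls)}
        # windows intersecting each control's support (Chebyshev distance <= 3)
        self.affected = {
            c: np.array([self.nmi_pos[c2] for c2 in self.nmi_controls
                         if abs(c2[0] - c[0]) <= 3 and abs(c2[1] - c[1]) <= 3],
                        dtype=int)
            for c in self.var_controls}

        # lattice-dependent caches, filled by set_points
        self.T = None         # (h, w, 2)
        self.joint4 = None    # (h, w, 4) int joint-bin index row*B + col
        self.wgt4 = None      # (h, w, 4) PVI weights (0 where invalid)
        self.hist_all = None  # (n_nmi, B, B) per-control joint histograms
        self.nmi_vals = None  # (n_nmi,)
        self.bend_map = None  # (h, w)
        self.Txx = self.Txy = self.Tyy = None  # (h, w, 2) each
        self.cost = None
        self.set_points(self.lattice.points)

    def B0v_at(self, yr, my):
        return self.Bv[yr, my]

    def B0u_at(self, xr, lx):
        return self.Bu[xr, lx]

    # ---- region computations -------------------------------------------

    def _transform_region(self, points, ysl, xsl):
        P_acc = 0.0
        ixr, iyr = self.ix[xsl], self.iy[ysl]
        for l in range(4):
            for m in range(4):
                coef = self.Bv[ysl, m][:, None, None] * self.Bu[xsl, l][None, :, None]
                P_acc = P_acc + coef * points[ixr[None, :] + l, iyr[:, None] + m]
        return P_acc  # (ny, nx, 2)

    def _sample_region(self, Treg):
        """Column-bin soft assignment of the interpolated moving intensity.

        Each mapped site's bilinear intensity is distributed linearly over
        its two nearest bins, making the histogram (hence the cost)
        continuous in the transform; hard binning would leave the
        finite-difference gradient dominated by bin-crossing noise.
        Returns (cols, wgts) of shape region + (2,).
        """
        B = self.cfg.bins
        hf, wf = self.moving.shape
        qx, qy = Treg[..., 0], Treg[..., 1]
        valid = ((qx >= 0) & (qx <= wf - 1) & (qy >= 0) & (qy <= hf - 1)
                 & np.isfinite(qx) & np.isfinite(qy))
        qxc = np.clip(np.nan_to_num(qx), 0, wf - 1)
        qyc = np.clip(np.nan_to_num(qy), 0, hf - 1)
        x0 = np.minimum(np.floor(qxc).astype(int), wf - 1)
        y0 = np.minimum(np.floor(qyc).astype(int), hf - 1)
        x1 = np.minimum(x0 + 1, wf - 1)
        y1 = np.minimum(y0 + 1, hf - 1)
        fx, fy = qxc - x0, qyc - y0
        iv = (self.moving[y0, x0] * (1 - fx) * (1 - fy)
              + self.moving[y0, x1] * fx * (1 - fy)
              + self.moving[y1, x0] * (1 - fx) * fy
              + self.moving[y1, x1] * fx * fy)
        return _soft_bins(iv, B, valid.astype(float))

    def _joint_from(self, ysl, xsl, cols, colw):
        """Combine soft row and column assignments into 4 joint entries."""
        B = self.cfg.bins
        rc = self.rowc[ysl, xsl]
        rw = self.roww[ysl, xsl]
        joint = rc[..., :, None] * B + cols[..., None, :]
        wgt = rw[..., :, None] * colw[..., None, :]
        return (joint.reshape(joint.shape[:-2] + (4,)),
                wgt.reshape(wgt.shape[:-2] + (4,)))

    def _bend_region(self, lattice, ysl, xsl):
        xs = np.arange(xsl.start, xsl.stop, dtype=float)
        ys = np.arange(ysl.start, ysl.stop, dtype=float)
        txx, txy, tyy = _second_derivative_maps(lattice, ys, xs)
        return (txx ** 2 + 2.0 * txy ** 2 + tyy ** 2).sum(axis=2)

    def _window_hists(self, controls):
        """Joint histograms of the given controls from current joint4/wgt4."""
        B = self.cfg.bins
        nw = len(controls)
        if nw == 0:
            return np.zeros((0, B, B))
        idx_parts, w_parts = [], []
        for k, c in enumerate(controls):
            ysl, xsl = self.windows[c]
            idx_parts.append(self.joint1[ysl, xsl].ravel() + k * B * B)
            w_parts.append(self.wgt1[ysl, xsl].ravel())
        return np.bincount(np.concatenate(idx_parts),
                           weights=np.concatenate(w_parts),
                           minlength=nw * B * B).reshape(nw, B, B)

    @staticmethod
    def _nmi_from_hists(hists):
        """NMI per histogram; empty mass -> 1 (no information), H12=0 -> 2.

        Entropies come from unnormalized counts via
        H = log(M) - sum(h log h)/M, avoiding per-window normalization.
        """
        mass = hists.sum(axis=(1, 2))
        out = np.ones(len(hists))
        ok = mass > 0
        if not np.any(ok):
            return out
        h = hists[ok]
        M = mass[ok]
        logM = np.log(M)
        # 0*log(tiny) == -0.0, so empty cells contribute exactly zero
        sj = (h * np.log(np.maximum(h, 1e-300))).sum(axis=(1, 2))
        r = h.sum(axis=2)
        c = h.sum(axis=1)
        sr = (r * np.log(np.maximum(r, 1e-300))).sum(axis=1)
        sc = (c * np.log(np.maximum(c, 1e-300))).sum(axis=1)
        h12 = logM - sj / M
        h1 = logM - sr / M
        h2 = logM - sc / M
        out[ok] = np.where(h12 > 1e-12, (h1 + h2) / np.maximum(h12, 1e-300), 2.0)
        return out

    # ---- full state ----------------------------------------------------

    def set_points(self, points):
        self.lattice.points = np.asarray(points, dtype=float)
        full = (slice(0, self.h), slice(0, self.w))
        self.T = self._transform_region(self.lattice.points, *full)
        cols, colw = self._sample_region(self.T)
        self.joint1, self.wgt1 = self._joint_from(*full, cols, colw)
        self.hist_all = self._window_hists(self.nmi_controls)
        self.nmi_vals = self._nmi_from_hists(self.hist_all)
        # per-window base statistics for sparse entropy updates
        h = self.hist_all
        self.mass_all = h.sum(axis=(1, 2))
        self.r_all = h.sum(axis=2)
        self.c_all = h.sum(axis=1)
        self.sj_all = (h * np.log(np.maximum(h, 1e-300))).sum(axis=(1, 2))
        self.sr_all = (self.r_all * np.log(np.maximum(self.r_all, 1e-300))).sum(axis=1)
        self.sc_all = (self.c_all * np.log(np.maximum(self.c_all, 1e-300))).sum(axis=1)
        xs = np.arange(self.w, dtype=float)
        ys = np.arange(self.h, dtype=float)
        self.Txx, self.Txy, self.Tyy = _second_derivative_maps(self.lattice, ys, xs)
        self.bend_map = (self.Txx ** 2 + 2.0 * self.Txy ** 2
                         + self.Tyy ** 2).sum(axis=2)
        self.cost = self._cost_from_state()
        return self.cost

    def _cost_from_state(self):
        mean_nmi = float(self.nmi_vals.mean()) if self.n_nmi else 0.0
        return -mean_nmi + self.cfg.mu * float(self.bend_map.mean())

    _STATE = ("T", "joint1", "wgt1", "hist_all", "nmi_vals", "mass_all",
              "r_all", "c_all", "sj_all", "sr_all", "sc_all", "bend_map",
              "Txx", "Txy", "Tyy", "cost")

    def peek_cost(self, points):
        """Cost of a candidate lattice without touching the cached state."""
        saved = (self.lattice.points,
                 tuple(getattr(self, n) for n in self._STATE))
        c = self.set_points(points)
        self.lattice.points = saved[0]
        for n, v in zip(self._STATE, saved[1]):
            setattr(self, n, v)
        return c

    # ---- gradient ------------------------------------------------------

    def _nmi_delta_sums(self, aff, nw, idx_new, w_new, idx_old, w_old_neg):
        """Sum of perturbed NMI values over the affected windows, for the
        four perturbations encoded in the flat indices (pert, window, joint
        bin).  Entropy sums are updated sparsely: log terms are evaluated
        only at the histogram entries that actually change.
        """
        B = self.cfg.bins
        B2 = B * B
        tiny = 1e-300
        idx_cat = np.concatenate([idx_new, idx_old])
        w_cat = np.concatenate([w_new, w_old_neg])
        dh = np.bincount(idx_cat, weights=w_cat, minlength=4 * nw * B2)
        uq = np.nonzero(dh)[0]
        dv = dh[uq]

        grp = uq // B2                      # perturbation*nw + window
        win_joint = uq % (nw * B2)          # window-local joint-bin address
        # gather base joint counts of the affected windows
        hb = self.hist_all[aff].reshape(nw * B2)[win_joint]
        hn = np.maximum(hb + dv, 0.0)
        dsj = np.bincount(grp, weights=hn * np.log(np.maximum(hn, tiny))
                          - hb * np.log(np.maximum(hb, tiny)),
                          minlength=4 * nw)
        dM = np.bincount(grp, weights=dv, minlength=4 * nw)

        # row marginals: collapse the column bin
        drow = np.bincount(uq // B, weights=dv, minlength=4 * nw * B)
        ur = np.nonzero(drow)[0]
        drv = drow[ur]
        rb = self.r_all[aff].reshape(nw * B)[ur % (nw * B)]
        rn = np.maximum(rb + drv, 0.0)
        dsr = np.bincount(ur // B, weights=rn * np.log(np.maximum(rn, tiny))
                          - rb * np.log(np.maximum(rb, tiny)),
                          minlength=4 * nw)

        # column marginals: collapse the row bin
        dcol = np.bincount(grp * B + uq % B, weights=dv, minlength=4 * nw * B)
        uc = np.nonzero(dcol)[0]
        dcv = dcol[uc]
        wlocal = (uc // B) % nw
        cb = self.c_all[aff].reshape(nw * B)[wlocal * B + uc % B]
        cn = np.maximum(cb + dcv, 0.0)
        dsc = np.bincount(uc // B, weights=cn * np.log(np.maximum(cn, tiny))
                          - cb * np.log(np.maximum(cb, tiny)),
                          minlength=4 * nw)

        M = np.tile(self.mass_all[aff], 4) + dM
        sj = np.tile(self.sj_all[aff], 4) + dsj
        sr = np.tile(self.sr_all[aff], 4) + dsr
        sc = np.tile(self.sc_all[aff], 4) + dsc
        nmi = np.ones(4 * nw)
        ok = M > 0
        logM = np.log(np.maximum(M, tiny))
        h12 = logM - sj / np.maximum(M, tiny)
        h1 = logM - sr / np.maximum(M, tiny)
        h2 = logM - sc / np.maximum(M, tiny)
        good = ok & (h12 > 1e-12)
        nmi[good] = ((h1 + h2) / h12)[good]
        nmi[ok & ~good] = 2.0
        return nmi.reshape(4, nw).sum(axis=1)

    def gradient(self):
        """Central finite-difference gradient of C w.r.t. all free controls.

        Only the perturbed control's 4delta support changes, so each
        affected window's histogram is updated by the entries of the
        support/window intersection; the bending delta is closed-form
        (the energy is quadratic in the control positions).
        """
        fd = self.cfg.fd_step
        B = self.cfg.bins
        S = self.w * self.h
        mu = self.cfg.mu
        n_nmi = max(self.n_nmi, 1)
        g = np.zeros((self.na, self.nb, 2))
        for (a, b) in self.var_controls:
            ysl, xsl = self.windows[(a, b)]
            ny, nx = ysl.stop - ysl.start, xsl.stop - xsl.start
            npix = ny * nx
            aff = self.affected[(a, b)]
            nw = len(aff)
            # membership: which support pixels feed which affected window
            grid = np.arange(npix).reshape(ny, nx)
            pix_parts, widx_parts = [], []
            for k, pos in enumerate(aff):
                c2 = self.nmi_controls[pos]
                ysl2, xsl2 = self.windows[c2]
                r0 = max(ysl.start, ysl2.start) - ysl.start
                r1 = min(ysl.stop, ysl2.stop) - ysl.start
                c0 = max(xsl.start, xsl2.start) - xsl.start
                c1 = min(xsl.stop, xsl2.stop) - xsl.start
                if r1 <= r0 or c1 <= c0:
                    continue
                sub = grid[r0:r1, c0:c1].ravel()
                pix_parts.append(sub)
                widx_parts.append(np.full(len(sub), k))
            pix_e = np.concatenate(pix_parts)
            widx_e = np.concatenate(widx_parts)
            woff = widx_e * (B * B)

            jt_old = self.joint1[ysl, xsl].reshape(npix, 4)
            wg_old = self.wgt1[ysl, xsl].reshape(npix, 4)
            idx_old = (woff[:, None] + jt_old[pix_e]).ravel()
            w_old_neg = -wg_old[pix_e].ravel()

            base_sum = float(self.nmi_vals[aff].sum())
            Tbase = self.T[ysl, xsl]
            wp = self.wpatch[(a, b)]
            cxx, cxy, cyy, q2 = self.bendpatch[(a, b)]
            rcf = self.rowc[ysl, xsl].reshape(npix, 2)
            rwf = self.roww[ysl, xsl].reshape(npix, 2)

            # all four perturbations (+x, -x, +y, -y) in one batch
            Tregs = np.broadcast_to(Tbase, (4,) + Tbase.shape).copy()
            Tregs[0, ..., 0] += fd * wp
            Tregs[1, ..., 0] -= fd * wp
            Tregs[2, ..., 1] += fd * wp
            Tregs[3, ..., 1] -= fd * wp
            cols, colw = self._sample_region(Tregs)
            cols = cols.reshape(4, npix, 1, 2)
            colw = colw.reshape(4, npix, 1, 2)
            jt_new = (rcf[None, :, :, None] * B + cols).reshape(4, npix, 4)
            wn = (rwf[None, :, :, None] * colw).reshape(4, npix, 4)
            poff = (np.arange(4) * nw * B * B)[:, None, None]
            idx_new = (poff + woff[None, :, None] + jt_new[:, pix_e]).ravel()
            w_new = wn[:, pix_e].ravel()
            idx_o = (poff + woff[None, :, None]
                     + np.broadcast_to(jt_old[pix_e], (4, len(pix_e), 4))).ravel()
            w_o = np.broadcast_to(w_old_neg, (4, w_old_neg.size)).ravel()
            d_nmi = self._nmi_delta_sums(aff, nw, idx_new, w_new, idx_o, w_o) \
                - base_sum

            for coord in range(2):
                # bending delta is closed-form (quadratic in the controls)
                L = float((cxx * self.Txx[ysl, xsl, coord]
                           + 2.0 * cxy * self.Txy[ysl, xsl, coord]
                           + cyy * self.Tyy[ysl, xsl, coord]).sum())
                dC = []
                for k, sgn in ((0, +1.0), (1, -1.0)):
                    step = sgn * fd
                    d_bend = (2.0 * step * L + step * step * q2) / S
                    dC.append(-d_nmi[2 * coord + k] / n_nmi + mu * d_bend)
                g[a, b, coord] = (dC[0] - dC[1]) / (2.0 * fd)
        return g


def cost(ref: np.ndarray, moving: np.ndarray, lattice: ControlLattice,
         cfg: FFDConfig) -> float:
    """C(phi) = -mean local NMI + mu * bending energy."""
    ev = _CostEvaluator(ref, moving, FFDConfig(**{**cfg.__dict__, "delta": lattice.delta}))
    return ev.peek_cost(lattice.points)


@dataclass
class FFDResult:
    lattice: ControlLattice
    cost_trace: list = field(default_factory=list)
    grad_norms: list = field(default_factory=list)
    n_iters: int = 0
    converged: bool = False


def optimize(ref: np.ndarray, moving: np.ndarray, cfg: FFDConfig | None = None) -> FFDResult:
    """Gradient descent on C(phi) from the identity lattice.

    Steps of length rho along -grad C / |grad C|; stops when the gradient
    norm falls below xi, when no backtracked step (rho halved up to 6 times)
    decreases the cost, or at max_iters.  With backtracking enabled the cost
    trace is non-increasing.
    """
    cfg = cfg or FFDConfig()
    ref = np.asarray(ref, dtype=float)
    moving = np.asarray(moving, dtype=float)
    if ref.shape != moving.shape:
        raise ValidationError("reference and moving images must share a shape")
    ev = _CostEvaluator(ref, moving, cfg)
    trace = [ev.cost]
    gnorms = []
    converged = False
    it = 0
    r_start = cfg.rho
    for it in range(1, cfg.max_iters + 1):
        g = ev.gradient()
        gn = float(np.sqrt((g ** 2).sum()))
        gnorms.append(gn)
        if not np.isfinite(gn):
            raise ValidationError("non-finite cost gradient; aborting")
        if gn < cfg.xi:
            converged = True
            break
        direction = -g / gn
        accepted = False
        # warm-start from the last accepted step length (capped at rho)
        r = min(cfg.rho, 2.0 * r_start) if cfg.backtracking else cfg.rho
        for _ in range(9 if cfg.backtracking else 1):
            cand = ev.lattice.points + r * direction
            c = ev.peek_cost(cand)
            if (not cfg.backtracking) or c < ev.cost - 1e-15:
                ev.set_points(cand)
                trace.append(ev.cost)
                accepted = True
                r_start = r
                break
            r *= 0.5
        if not accepted:
            converged = True
            break
    return FFDResult(lattice=ev.lattice, cost_trace=trace, grad_norms=gnorms,
                     n_iters=it, converged=converged)


def fine_warp(moving: np.ndarray, lattice: ControlLattice):
    """Backward warp of the coarse result through T (bilinear resampling)."""
    return warp_backward(moving, lambda p: ffd_transform(lattice, p),
                         out_shape=(lattice.height, lattice.width))
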