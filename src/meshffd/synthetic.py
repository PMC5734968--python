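"""Synthetic images, ground-truth warps and correspondence sets.

These generators emulate the method's test regime end to end: band-limited
random textures stand in for anatomical images, known homographies and
smooth B-spline displacement fields supply ground-truth deformations, and
correspondence sets carry Gaussian localization noise plus planted uniform
outliers mimicking feature-matching errors.  Everything is a pure function
of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import DegeneracyError, ValidationError
from .ffd import ControlLattice, ffd_transform
from .homography import apply_homography, fit_homography_dlt

__all__ = [
    "GroundTruthWarp",
    "make_texture",
    "random_homography",
    "make_bspline_warp",
    "homography_warp",
    "compose_warps",
    "CorrespondenceSet",
    "make_correspondences",
]


@dataclass
class GroundTruthWarp:
    """An invertible-on-domain map reference frame -> float frame."""

    kind: str                 # homography | bspline_field | composed | ...
    mapping: Callable         # (n, 2) -> (n, 2)
    max_displacement: float   # realized max |warp(p) - p| over the domain
    params: object = None     # the defining map (matrix, lattice, tuple, ...)

    def __call__(self, pts: np.ndarray) -> np.ndarray:
        return self.mapping(pts)


def make_texture(seed: int, width: int = 128, height: int = 128,
                 smoothness: float = 2.0) -> np.ndarray:
    """Band-limited random texture in [0, 1] with dense local gradients."""
    if width < 32 or height < 32:
        raise ValidationError("texture must be at least 32x32")
    if smoothness <= 0:
        raise ValidationError("smoothness must be > 0")
    rng = np.random.default_rng(seed)
    img = gaussian_filter(rng.standard_normal((height, width)), smoothness,
                          mode="wrap")
    img -= img.min()
    img /= img.max()
    return img


def homography_warp(H: np.ndarray, size) -> GroundTruthWarp:
    """Wrap a homography matrix as a ground-truth warp on a (w, h) domain."""
    w, h = size
    corners = np.array([[0, 0], [w - 1, 0], [w - 1, h - 1], [0, h - 1]], float)
    grid = np.column_stack([g.ravel() for g in
                            np.meshgrid(np.linspace(0, w - 1, 24),
                                        np.linspace(0, h - 1, 24))])
    disp = np.linalg.norm(apply_homography(H, grid) - grid, axis=1).max()
    return GroundTruthWarp(kind="homography",
                           mapping=lambda p: apply_homography(H, p),
                           max_displacement=float(disp), params=H)


def random_homography(seed: int, max_corner_shift: float, size) -> np.ndarray:
    """Homography from uniform perturbations of the four image corners."""
    w, h = size
    if max_corner_shift >= min(w, h) / 4:
        raise ValidationError("max_corner_shift must be < min(width, height)/4")
    corners = np.array([[0, 0], [w - 1, 0], [w - 1, h - 1], [0, h - 1]], float)
    if max_corner_shift == 0:
        return np.eye(3)
    rng = np.random.default_rng(seed)
    for _ in range(100):
        shifted = corners + rng.uniform(-max_corner_shift, max_corner_shift,
                                        size=(4, 2))
        try:
            H = fit_homography_dlt(corners, shifted)
        except DegeneracyError:
            continue
        # reject maps that push part of the domain toward infinity
        grid = np.column_stack([g.ravel() for g in
                                np.meshgrid(np.linspace(0, w - 1, 8),
                                            np.linspace(0, h - 1, 8))])
        if np.all(np.isfinite(apply_homography(H, grid))):
            return H
    raise DegeneracyError("no valid random homography after 100 attempts")


def make_bspline_warp(seed: int, spacing: int, max_disp: float,
                      size) -> GroundTruthWarp:
    """Smooth random B-spline displacement field with exact peak amplitude.

    Control displacements are drawn uniformly in [-max_disp, max_disp]^2 and
    rescaled so the realized dense field's maximum norm equals max_disp
    (exactly, by linearity of the spline in its control displacements).
    max_disp <= spacing/2 keeps the field invertible.
    """
    w, h = size
    if spacing < 4:
        raise ValidationError("spacing must be >= 4")
    if max_disp > spacing / 2:
        raise ValidationError("max_disp must be <= spacing/2 for invertibility")
    lattice = ControlLattice.identity(w, h, spacing)
    if max_disp > 0:
        rng = np.random.default_rng(seed)
        disp = rng.uniform(-max_disp, max_disp, size=lattice.points.shape)
        lattice.points = lattice.points + disp
        ys, xs = np.mgrid[0:h, 0:w]
        grid = np.column_stack([xs.ravel().astype(float), ys.ravel().astype(float)])
        field = ffd_transform(lattice, grid) - grid
        peak = np.linalg.norm(field, axis=1).max()
        lattice.points = lattice.points - disp + disp * (max_disp / peak)
    return GroundTruthWarp(kind="bspline_field",
                           mapping=lambda p: ffd_transform(lattice, p),
                           max_displacement=float(max_disp), params=lattice)


def compose_warps(outer: GroundTruthWarp, inner: GroundTruthWarp,
                  size) -> GroundTruthWarp:
    """outer after inner, with the realized displacement measured densely."""
    w, h = size

    def mapping(p):
        return outer.mapping(inner.mapping(np.atleast_2d(p)))

    ys, xs = np.mgrid[0:h:4, 0:w:4]
    grid = np.column_stack([xs.ravel().astype(float), ys.ravel().astype(float)])
    disp = np.linalg.norm(mapping(grid) - grid, axis=1).max()
    return GroundTruthWarp(kind="composed", mapping=mapping,
                           max_displacement=float(disp),
                           params=(outer, inner))


@dataclass
class CorrespondenceSet:
    """Matched point pairs (reference, float) with optional labels."""

    ref_pts: np.ndarray                 # (n, 2)
    flt_pts: np.ndarray                 # (n, 2)
    inlier: np.ndarray | None = None    # estimated labels
    truth: np.ndarray | None = None     # planted ground-truth labels

    def __len__(self) -> int:
        return len(self.ref_pts)

    def subset(self, mask: np.ndarray) -> "CorrespondenceSet":
        return CorrespondenceSet(
            self.ref_pts[mask], self.flt_pts[mask],
            None if self.inlier is None else self.inlier[mask],
            None if self.truth is None else self.truth[mask])

    def to_csv(self, path) -> None:
        cols = [self.ref_pts, self.flt_pts]
        header = "ref_x,ref_y,flt_x,flt_y"
        if self.inlier is not None:
            cols.append(self.inlier.astype(float)[:, None])
            header += ",is_inlier"
        if self.truth is not None:
            cols.append(self.truth.astype(float)[:, None])
            header += ",is_inlier_truth"
        np.savetxt(path, np.column_stack(cols), delimiter=",",
                   header=header, comments="")

    @classmethod
    def from_csv(cls, path) -> "CorrespondenceSet":
        with open(path) as fh:
            names = fh.readline().strip().split(",")
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        cols = {n: data[:, k] for k, n in enumerate(names)}
        return cls(
            ref_pts=np.column_stack([cols["ref_x"], cols["ref_y"]]),
            flt_pts=np.column_stack([cols["flt_x"], cols["flt_y"]]),
            inlier=cols["is_inlier"].astype(bool) if "is_inlier" in cols else None,
            truth=(cols["is_inlier_truth"].astype(bool)
                   if "is_inlier_truth" in cols else None))


def make_correspondences(warp: GroundTruthWarp, n_inliers: int,
                         noise_sigma: float, n_outliers: int, seed: int,
                         size) -> CorrespondenceSet:
    """Planted-truth correspondence set.

    Inlier reference points are uniform over the domain and map through the
    warp plus isotropic Gaussian noise; outlier float points are uniform
    over the float domain (the contamination model for matching errors).
    """
    w, h = size
    if n_inliers < 4:
        raise ValidationError("need at least 4 inliers")
    if w < 4 or h < 4:
        raise ValidationError("domain too small")
    rng = np.random.default_rng(seed)
    n = n_inliers + n_outliers
    ref = np.column_stack([rng.uniform(0, w - 1, n), rng.uniform(0, h - 1, n)])
    flt = np.asarray(warp(ref), dtype=float)
    if noise_sigma > 0:
        flt[:n_inliers] += rng.normal(0.0, noise_sigma, size=(n_inliers, 2))
    if n_outliers > 0:
        flt[n_inliers:] = np.column_stack([rng.uniform(0, w - 1, n_outliers),
                                           rng.uniform(0, h - 1, n_outliers)])
    truth = np.zeros(n, dtype=bool)
    truth[:n_inliers] = True
    return CorrespondenceSet(ref_pts=ref, flt_pts=flt, truth=truth)
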