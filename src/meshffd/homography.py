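"""3x3 projective maps of the plane and their estimation.

Conventions used package-wide: points are 0-based pixel-center coordinates
(x=column, y=row), homogeneous points are column vectors (x, y, 1)^T, and a
homography ``H`` maps reference coordinates into float-image coordinates.
Matrices are stored normalized: bottom-right entry 1 when it is nonzero,
otherwise unit Frobenius norm.
"""

from __future__ import annotations

import numpy as np

from .errors import DegeneracyError, ValidationError

__all__ = [
    "normalize_homography",
    "apply_homography",
    "fit_homography_dlt",
    "translation_homography",
    "similarity_homography",
]

_W_EPS = 1e-12


def normalize_homography(H: np.ndarray) -> np.ndarray:
    """Return ``H`` scaled to the canonical representative of its ray."""
    H = np.asarray(H, dtype=float)
    if H.shape != (3, 3):
        raise ValidationError(f"homography must be 3x3, got {H.shape}")
    if not np.all(np.isfinite(H)):
        raise ValidationError("homography contains non-finite entries")
    if abs(H[2, 2]) > _W_EPS:
        return H / H[2, 2]
    return H / np.linalg.norm(H)


def apply_homography(H: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Map an (n, 2) array of points through ``H``.

    Points that land on the plane at infinity (homogeneous w ~ 0) come back
    as +inf coordinates; callers decide whether that is an error.
    """
    pts = np.atleast_2d(np.asarray(pts, dtype=float))
    ph = np.column_stack([pts, np.ones(len(pts))])
    q = ph @ np.asarray(H, dtype=float).T
    w = q[:, 2]
    out = np.full((len(pts), 2), np.inf)
    ok = np.abs(w) > _W_EPS
    out[ok] = q[ok, :2] / w[ok, None]
    return out


def _hartley_normalization(pts: np.ndarray) -> np.ndarray:
    """Similarity sending the centroid to the origin, mean radius to sqrt(2)."""
    c = pts.mean(axis=0)
    d = np.sqrt(((pts - c) ** 2).sum(axis=1)).mean()
    s = np.sqrt(2.0) / d if d > 1e-12 else 1.0
    return np.array([[s, 0.0, -s * c[0]], [0.0, s, -s * c[1]], [0.0, 0.0, 1.0]])


def fit_homography_dlt(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Direct linear transform with Hartley pre-normalization.

    With exactly 4 pairs this is the interpolating homography; with more it
    is the algebraic least-squares solution.

    Raises
    ------
    DegeneracyError
        If the design matrix is (numerically) rank deficient, e.g. three of
        four points collinear.
    """
    src = np.asarray(src, dtype=float).reshape(-1, 2)
    dst = np.asarray(dst, dtype=float).reshape(-1, 2)
    if len(src) != len(dst) or len(src) < 4:
        raise ValidationError("need >= 4 point pairs of equal count")

    Ts, Td = _hartley_normalization(src), _hartley_normalization(dst)
    s = apply_homography(Ts, src)
    d = apply_homography(Td, dst)

    n = len(s)
    A = np.zeros((2 * n, 9))
    A[0::2, 0:2] = s
    A[0::2, 2] = 1.0
    A[0::2, 6:8] = -d[:, [0]] * s
    A[0::2, 8] = -d[:, 0]
    A[1::2, 3:5] = s
    A[1::2, 5] = 1.0
    A[1::2, 6:8] = -d[:, [1]] * s
    A[1::2, 8] = -d[:, 1]

    _, sv, vt = np.linalg.svd(A)
    # For 4 exact pairs the null space must be 1-dimensional.
    if sv[7] < 1e-9 * max(sv[0], 1.0):
        raise DegeneracyError("degenerate point configuration for homography fit")
    Hn = vt[-1].reshape(3, 3)
    H = np.linalg.inv(Td) @ Hn @ Ts
    if abs(np.linalg.det(H)) < 1e-12 * np.linalg.norm(H, "fro") ** 3:
        raise DegeneracyError("estimated homography is singular")
    return normalize_homography(H)


def translation_homography(tx: float, ty: float) -> np.ndarray:
    return np.array([[1.0, 0.0, tx], [0.0, 1.0, ty], [0.0, 0.0, 1.0]])


def similarity_homography(angle_deg: float, scale: float, tx: float = 0.0,
                          ty: float = 0.0, center: tuple = (0.0, 0.0)) -> np.ndarray:
    """Rotation (about ``center``) + isotropic scale + translation."""
    a = np.deg2rad(angle_deg)
    c, s = scale * np.cos(a), scale * np.sin(a)
    cx, cy = center
    M = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    M[0, 2] = tx + cx - (c * cx - s * cy)
    M[1, 2] = ty + cy - (s * cx + c * cy)
    return M
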