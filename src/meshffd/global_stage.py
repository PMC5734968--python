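"""Global homography estimation with two-stage robust outlier rejection.

SIFT keypoints are matched by descriptor distance with a ratio test; a
seeded RANSAC scored by the symmetric transfer residual

    r_i = 1/2 ( d(x_i, H^-1 x'_i) + d(x'_i, H x_i) )

estimates the global homography H_g with inlier threshold eps1, after which
each of the 4x4 sub-images of the reference re-runs the robust estimation
with a tighter threshold eps2 to weed out locally inconsistent matches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.feature import SIFT, match_descriptors

from .errors import (DegeneracyError, EstimationFailureError,
                     InsufficientFeaturesError, ValidationError)
from .homography import apply_homography, fit_homography_dlt, normalize_homography
from .synthetic import CorrespondenceSet

__all__ = [
    "RobustConfig",
    "detect_and_match",
    "symmetric_residual",
    "robust_estimate",
    "subimage_refine",
]


@dataclass
class RobustConfig:
    """Thresholds of the two-stage robust estimation."""

    eps1: float = 3.0          # global inlier threshold, px
    eps2: float = 1.5          # sub-image inlier threshold, px
    max_iterations: int = 2000
    seed: int = 0
    min_subimage_pairs: int = 8  # occupancy below which a sub-image is kept as-is
    ratio: float = 0.8           # nearest-neighbor descriptor ratio test

    def __post_init__(self):
        if not (0 < self.eps2 <= self.eps1):
            raise ValidationError("require 0 < eps2 <= eps1")


def detect_and_match(ref: np.ndarray, flt: np.ndarray,
                     ratio: float = 0.8) -> CorrespondenceSet:
    """SIFT keypoint detection + ratio-test descriptor matching.

    Thin adapter over scikit-image's detector; returns matched pairs only
    and raises :class:`InsufficientFeaturesError` below 4 matches.
    """
    pairs = []
    try:
        det_r, det_f = SIFT(), SIFT()
        det_r.detect_and_extract(np.asarray(ref, dtype=float))
        det_f.detect_and_extract(np.asarray(flt, dtype=float))
        matches = match_descriptors(det_r.descriptors, det_f.descriptors,
                                    max_ratio=ratio, cross_check=True)
    except RuntimeError as exc:  # skimage raises when no keypoints survive
        raise InsufficientFeaturesError(f"feature detection failed: {exc}") from exc
    if len(matches) < 4:
        raise InsufficientFeaturesError(
            f"only {len(matches)} matches; need at least 4")
    # skimage keypoints are (row, col); package convention is (x, y)
    ref_pts = det_r.keypoints[matches[:, 0]][:, ::-1].astype(float)
    flt_pts = det_f.keypoints[matches[:, 1]][:, ::-1].astype(float)
    return CorrespondenceSet(ref_pts=ref_pts, flt_pts=flt_pts)


def symmetric_residual(H: np.ndarray, pairs: CorrespondenceSet):
    """Per-pair symmetric transfer residuals and their mean.

    Points mapping to the plane at infinity get residual +inf (warned).
    """
    H = np.asarray(H, dtype=float)
    Hinv = np.linalg.inv(H)
    fwd = apply_homography(H, pairs.ref_pts)
    bwd = apply_homography(Hinv, pairs.flt_pts)
    d_fwd = np.linalg.norm(fwd - pairs.flt_pts, axis=1)
    d_bwd = np.linalg.norm(bwd - pairs.ref_pts, axis=1)
    r = 0.5 * (d_fwd + d_bwd)
    if np.any(~np.isfinite(r)):
        warnings.warn("some pairs map to the plane at infinity; residual +inf")
        r = np.where(np.isfinite(r), r, np.inf)
    return r, float(r.mean())


def robust_estimate(pairs: CorrespondenceSet, cfg: RobustConfig):
    """Seeded RANSAC homography with symmetric-residual scoring.

    Candidates are exact 4-point fits; inliers are pairs with residual
    <= eps1; the largest consensus wins (ties broken by smaller mean
    residual) and the final model is refit by DLT on the winning inliers.

    Returns
    -------
    (H_g, inliers) : (3x3 ndarray, CorrespondenceSet with ``inlier`` set)
    """
    n = len(pairs)
    if n < 4:
        raise ValidationError("robust estimation needs >= 4 pairs")
    rng = np.random.default_rng(cfg.seed)
    best_count = -1
    best_eps = np.inf
    best_mask = None
    needed = cfg.max_iterations

    it = 0
    while it < min(needed, cfg.max_iterations):
        it += 1
        idx = rng.choice(n, size=4, replace=False)
        try:
            H = fit_homography_dlt(pairs.ref_pts[idx], pairs.flt_pts[idx])
        except DegeneracyError:
            continue
        r, _ = symmetric_residual(H, pairs)
        mask = r <= cfg.eps1
        count = int(mask.sum())
        if count < 4:
            continue
        eps_in = float(r[mask].mean())
        if count > best_count or (count == best_count and eps_in < best_eps):
            best_count, best_eps, best_mask = count, eps_in, mask
            # adaptive stopping at 99.9% confidence of an all-inlier sample
            w4 = (count / n) ** 4
            if w4 >= 1.0 - 1e-12:
                needed = it
            else:
                needed = int(np.ceil(np.log(1e-3) / np.log(1.0 - w4)))

    if best_mask is None:
        raise EstimationFailureError("no candidate reached 4 inliers")

    H = fit_homography_dlt(pairs.ref_pts[best_mask], pairs.flt_pts[best_mask])
    # one re-classification with the refit model for a consistent inlier set
    r, _ = symmetric_residual(H, pairs)
    mask = r <= cfg.eps1
    if mask.sum() >= 4:
        H = fit_homography_dlt(pairs.ref_pts[mask], pairs.flt_pts[mask])
    else:
        mask = best_mask
    inliers = pairs.subset(mask)
    inliers.inlier = np.ones(len(inliers), dtype=bool)
    full = CorrespondenceSet(pairs.ref_pts, pairs.flt_pts,
                             inlier=mask, truth=pairs.truth)
    return normalize_homography(H), full


def subimage_refine(ref_size, inliers: CorrespondenceSet,
                    cfg: RobustConfig) -> CorrespondenceSet:
    """Second-stage rejection on the 4x4 sub-images of the reference.

    Sub-images holding at least ``min_subimage_pairs`` inliers re-run the
    robust estimation with the tighter threshold eps2 and keep only its
    surviving pairs; sparsely populated sub-images pass through unchanged.
    """
    w, h = ref_size
    pts = inliers.ref_pts
    keep = np.zeros(len(inliers), dtype=bool)
    gx = np.clip((pts[:, 0] / (w / 4.0)).astype(int), 0, 3)
    gy = np.clip((pts[:, 1] / (h / 4.0)).astype(int), 0, 3)
    sub_cfg = RobustConfig(eps1=cfg.eps2, eps2=cfg.eps2,
                           max_iterations=cfg.max_iterations, seed=cfg.seed,
                           min_subimage_pairs=cfg.min_subimage_pairs)
    for jy in range(4):
        for jx in range(4):
            sel = np.flatnonzero((gx == jx) & (gy == jy))
            if len(sel) == 0:
                continue
            if len(sel) < cfg.min_subimage_pairs:
                keep[sel] = True
                continue
            try:
                _, refined = robust_estimate(inliers.subset(sel), sub_cfg)
                keep[sel[refined.inlier]] = True
            except (EstimationFailureError, DegeneracyError):
                keep[sel] = True  # cannot refine; keep conservatively
    return inliers.subset(keep)
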