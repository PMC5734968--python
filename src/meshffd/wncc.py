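"""Weighted normalized cross-correlation with HOG-direction and distance weights.

Plain NCC compares window intensities only; this measure additionally
weights every pixel of the support window by (i) how well its dominant
local gradient orientation agrees with the window center's
(w_r = exp(-dpsi/delta_r), dpsi the angular difference wrapped to [0, 180])
and (ii) its distance to the center (w_s = exp(-|i|/delta_s)).  Dominant
orientations come from a 36-bin histogram of Gaussian-weighted gradient
magnitudes over an 8x8 region.  With both scale factors at infinity all
weights are 1 and the measure reduces exactly to NCC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import correlate, gaussian_filter

from .errors import ValidationError
from .image import bilinear_sample

__all__ = [
    "WnccConfig",
    "GradientField",
    "gradient_field",
    "main_direction",
    "main_direction_map",
    "direction_weight",
    "distance_weight",
    "wncc",
]


@dataclass
class WnccConfig:
    """Support-window and weighting parameters.

    delta_s defaults to beta/2 (half the support window); sigma is the
    Gaussian scale of both the gradient smoothing and the HOG emphasis.
    """

    beta: int = 16           # support window side, px
    delta_r: float = 40.0    # direction scale factor, degrees
    delta_s: float | None = None  # distance scale factor, px (None -> beta/2)
    hog_window: int = 8
    hog_bins: int = 36
    sigma: float = 2.5

    def __post_init__(self):
        if self.beta < 8 or self.beta % 2:
            raise ValidationError("beta must be even and >= 8")
        if self.delta_r <= 0:
            raise ValidationError("delta_r must be > 0")
        if self.delta_s is None:
            self.delta_s = self.beta / 2.0
        if self.delta_s <= 0:
            raise ValidationError("delta_s must be > 0")
        if 360 % self.hog_bins:
            raise ValidationError("hog_bins must divide 360")


@dataclass
class GradientField:
    """Per-pixel gradient magnitude and orientation (degrees in [0, 360))."""

    magnitude: np.ndarray
    orientation: np.ndarray


def gradient_field(img: np.ndarray, sigma: float = 2.5) -> GradientField:
    """Central-difference gradient of the Gaussian-smoothed image.

    Borders use replicated edges; zero-magnitude pixels carry orientation 0
    by convention.
    """
    img = np.asarray(img, dtype=float)
    if img.shape[0] < 3 or img.shape[1] < 3:
        raise ValidationError("image must be at least 3x3")
    L = gaussian_filter(img, sigma, mode="nearest")
    Lp = np.pad(L, 1, mode="edge")
    dx = Lp[1:-1, 2:] - Lp[1:-1, :-2]
    dy = Lp[2:, 1:-1] - Lp[:-2, 1:-1]
    m = np.hypot(dx, dy)
    theta = np.degrees(np.arctan2(dy, dx)) % 360.0
    theta[m == 0] = 0.0
    return GradientField(magnitude=m, orientation=theta)


def _hog_kernel(window: int, sigma: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gaussian emphasis kernel and its offset grids (window even: -w/2..w/2-1)."""
    half = window // 2
    offs = np.arange(-half, window - half)
    oy, ox = np.meshgrid(offs, offs, indexing="ij")
    K = np.exp(-(ox ** 2 + oy ** 2) / (2.0 * sigma ** 2))
    return K, ox, oy


def main_direction(field: GradientField, center, cfg: WnccConfig | None = None):
    """Dominant orientation around ``center`` = (x, y).

    Builds the magnitude-weighted, Gaussian-emphasized orientation histogram
    over the hog_window region (clipped at borders; at least 4 contributing
    pixels required) and returns ``(psi_degrees, degenerate)`` where psi is
    the center angle of the peak bin, ties going to the lowest bin index.
    """
    cfg = cfg or WnccConfig()
    h, w = field.magnitude.shape
    cx, cy = int(round(center[0])), int(round(center[1]))
    K, ox, oy = _hog_kernel(cfg.hog_window, cfg.sigma)
    xs, ys = cx + ox, cy + oy
    ok = (xs >= 0) & (xs < w) & (ys >= 0) & (ys < h)
    if ok.sum() < 4:
        raise ValidationError("fewer than 4 contributing pixels around center")
    mag = field.magnitude[ys[ok], xs[ok]] * K[ok]
    ang = field.orientation[ys[ok], xs[ok]]
    binw = 360.0 / cfg.hog_bins
    hist = np.bincount(np.minimum((ang / binw).astype(int), cfg.hog_bins - 1),
                       weights=mag, minlength=cfg.hog_bins)
    if hist.sum() <= 0:
        return 0.0, True
    peak = int(np.argmax(hist))
    return (peak + 0.5) * binw, False


def main_direction_map(img: np.ndarray, cfg: WnccConfig | None = None):
    """Per-pixel dominant orientation for a whole image (cached lookups).

    Equivalent to calling :func:`main_direction` at every pixel, realized as
    one correlation per orientation bin.  Returns ``(psi_map, degenerate)``.
    """
    cfg = cfg or WnccConfig()
    field = gradient_field(img, cfg.sigma)
    K, _, _ = _hog_kernel(cfg.hog_window, cfg.sigma)
    binw = 360.0 / cfg.hog_bins
    bins = np.minimum((field.orientation / binw).astype(int), cfg.hog_bins - 1)
    hists = np.empty(img.shape + (cfg.hog_bins,))
    for b in range(cfg.hog_bins):
        hists[:, :, b] = correlate(field.magnitude * (bins == b), K,
                                   mode="constant", cval=0.0)
    total = hists.sum(axis=2)
    peak = hists.argmax(axis=2)
    psi = (peak + 0.5) * binw
    degenerate = total <= 0
    psi[degenerate] = 0.0
    return psi, degenerate


def direction_weight(psi_pixel, psi_center, delta_r: float):
    """exp(-dpsi/delta_r) with dpsi the angular difference wrapped to [0, 180]."""
    d = np.abs(np.asarray(psi_pixel, dtype=float) - np.asarray(psi_center, dtype=float)) % 360.0
    d = np.minimum(d, 360.0 - d)
    return np.exp(-d / delta_r)


def distance_weight(offset, delta_s: float):
    """exp(-|offset|/delta_s), Euclidean norm of the pixel offset."""
    off = np.asarray(offset, dtype=float)
    return np.exp(-np.linalg.norm(off, axis=-1) / delta_s)


def wncc(ref: np.ndarray, flt: np.ndarray, x, x_prime,
         cfg: WnccConfig | None = None,
         ref_psi: np.ndarray | None = None,
         flt_psi: np.ndarray | None = None) -> float:
    """Weighted NCC between beta x beta windows centered at x and x'.

    Weights are computed independently per image from that image's own
    dominant-orientation map (pass ``ref_psi``/``flt_psi`` to reuse cached
    maps); the float window is sampled at integer offsets from x' with
    bilinear intensities and nearest-pixel orientations.  The result is
    clamped to [-1, 1]; a zero-weighted-variance window yields 0 (or 1 when
    the two windows are identical).
    """
    cfg = cfg or WnccConfig()
    ref = np.asarray(ref, dtype=float)
    flt = np.asarray(flt, dtype=float)
    if ref_psi is None:
        ref_psi, _ = main_direction_map(ref, cfg)
    if flt_psi is None:
        flt_psi, _ = main_direction_map(flt, cfg)

    half = cfg.beta // 2
    offs = np.arange(-half, half)
    oy, ox = np.meshgrid(offs, offs, indexing="ij")
    off = np.stack([ox.ravel(), oy.ravel()], axis=-1).astype(float)

    pr = np.asarray(x, dtype=float) + off
    pf = np.asarray(x_prime, dtype=float) + off
    h, w = ref.shape
    hf, wf = flt.shape
    ok = ((pr[:, 0] >= 0) & (pr[:, 0] <= w - 1) & (pr[:, 1] >= 0) & (pr[:, 1] <= h - 1)
          & (pf[:, 0] >= 0) & (pf[:, 0] <= wf - 1) & (pf[:, 1] >= 0) & (pf[:, 1] <= hf - 1))
    if ok.sum() < 16:
        raise ValidationError("fewer than 16 valid window pixels")
    pr, pf, off = pr[ok], pf[ok], off[ok]

    Ir = bilinear_sample(ref, pr)
    If = bilinear_sample(flt, pf)

    ri = np.round(pr).astype(int)
    fi = np.round(pf).astype(int)
    ci = np.clip(np.round(np.asarray(x, dtype=float)).astype(int), 0, [w - 1, h - 1])
    cf = np.clip(np.round(np.asarray(x_prime, dtype=float)).astype(int), 0, [wf - 1, hf - 1])
    ri[:, 0] = np.clip(ri[:, 0], 0, w - 1)
    ri[:, 1] = np.clip(ri[:, 1], 0, h - 1)
    fi[:, 0] = np.clip(fi[:, 0], 0, wf - 1)
    fi[:, 1] = np.clip(fi[:, 1], 0, hf - 1)

    ws = distance_weight(off, cfg.delta_s)
    wref = direction_weight(ref_psi[ri[:, 1], ri[:, 0]],
                            ref_psi[ci[1], ci[0]], cfg.delta_r) * ws
    wflt = direction_weight(flt_psi[fi[:, 1], fi[:, 0]],
                            flt_psi[cf[1], cf[0]], cfg.delta_r) * ws

    dr = Ir - Ir.mean()
    df = If - If.mean()
    num = float((wref * wflt * dr * df).sum())
    den = float(np.sqrt((wref ** 2 * dr ** 2).sum()) * np.sqrt((wflt ** 2 * df ** 2).sum()))
    if den == 0.0:
        return 1.0 if np.allclose(Ir, If) else 0.0
    return float(np.clip(num / den, -1.0, 1.0))
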