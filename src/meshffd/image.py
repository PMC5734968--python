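"""Image I/O, interpolation, PVI joint histograms, entropy/NMI and metrics.

A grayscale image is a 2-D ``float64`` array with intensities in [0, 1],
indexed ``img[y, x]`` (row, column) with 0-based pixel-center coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import imageio.v3 as iio

from .errors import OutOfBoundsError, ValidationError

__all__ = [
    "as_gray",
    "load_gray",
    "save_gray",
    "bilinear_sample",
    "JointHistogram",
    "pvi_accumulate",
    "nmi_from_hist",
    "intensity_bin",
    "MetricsReport",
    "compute_metrics",
    "warp_backward",
]


def as_gray(arr: np.ndarray) -> np.ndarray:
    """Validate/coerce an array into the [0, 1] float grayscale contract."""
    a = np.asarray(arr, dtype=float)
    if a.ndim != 2 or a.size == 0:
        raise ValidationError(f"expected a non-empty 2-D array, got shape {a.shape}")
    if a.min() < -1e-12 or a.max() > 1.0 + 1e-12:
        raise ValidationError("intensities must lie in [0, 1]")
    return np.clip(a, 0.0, 1.0)


def load_gray(path) -> np.ndarray:
    """Read a PNG/TIFF image as grayscale in [0, 1].

    3-channel input is collapsed by the channel average; integer images are
    scaled by their bit-depth maximum.
    """
    raw = iio.imread(path)
    if raw.size == 0:
        raise ValidationError(f"zero-sized image: {path}")
    dtype = raw.dtype
    if raw.ndim == 3:
        if raw.shape[2] == 4:  # drop alpha
            raw = raw[:, :, :3]
        raw = raw.mean(axis=2)
    elif raw.ndim != 2:
        raise ValidationError(f"unsupported image dimensionality {raw.ndim}: {path}")
    img = raw.astype(float)
    if np.issubdtype(dtype, np.integer):
        img /= float(np.iinfo(dtype).max)
    return as_gray(img)


def save_gray(path, img: np.ndarray) -> None:
    """Write a [0, 1] grayscale image as 8-bit PNG/TIFF."""
    img = as_gray(img)
    iio.imwrite(path, np.round(img * 255.0).astype(np.uint8))


def _bilinear_parts(img: np.ndarray, x: np.ndarray, y: np.ndarray):
    h, w = img.shape
    x0 = np.clip(np.floor(x).astype(int), 0, w - 1)
    y0 = np.clip(np.floor(y).astype(int), 0, h - 1)
    x1 = np.minimum(x0 + 1, w - 1)
    y1 = np.minimum(y0 + 1, h - 1)
    fx = x - x0
    fy = y - y0
    return x0, y0, x1, y1, fx, fy


def bilinear_sample(img: np.ndarray, p) -> float | np.ndarray:
    """Bilinear interpolation at point(s) ``p`` = (x, y).

    Accepts a single (x, y) pair or an (n, 2) array; exact at integer
    coordinates. Raises :class:`OutOfBoundsError` for points outside
    [0, w-1] x [0, h-1].
    """
    img = np.asarray(img, dtype=float)
    pts = np.atleast_2d(np.asarray(p, dtype=float))
    h, w = img.shape
    x, y = pts[:, 0], pts[:, 1]
    if np.any((x < 0) | (x > w - 1) | (y < 0) | (y > h - 1)):
        raise OutOfBoundsError("sample point outside image domain")
    x0, y0, x1, y1, fx, fy = _bilinear_parts(img, x, y)
    v = (img[y0, x0] * (1 - fx) * (1 - fy) + img[y0, x1] * fx * (1 - fy)
         + img[y1, x0] * (1 - fx) * fy + img[y1, x1] * fx * fy)
    return float(v[0]) if np.asarray(p).ndim == 1 else v


def intensity_bin(v: np.ndarray, bins: int) -> np.ndarray:
    """Uniform bin index on [0, 1] with a closed right edge."""
    return np.minimum((np.asarray(v) * bins).astype(int), bins - 1)


@dataclass
class JointHistogram:
    """B x B joint intensity histogram (rows: reference, cols: float)."""

    counts: np.ndarray

    @property
    def bins(self) -> int:
        return self.counts.shape[0]

    @property
    def total_mass(self) -> float:
        return float(self.counts.sum())


def pvi_accumulate(ref: np.ndarray, flt: np.ndarray, mapping, sites,
                   bins: int = 32) -> JointHistogram:
    """Joint histogram by partial volume interpolation.

    Each reference site selects its row bin exactly; its unit mass is
    distributed over the column bins of the up to four float pixels
    surrounding the mapped point, with bilinear weights.  Sites whose mapped
    point falls outside the float domain are skipped, so
    ``total_mass == number of contributing sites`` exactly.

    ``mapping`` is a callable taking an (n, 2) array of reference points and
    returning the (n, 2) mapped float-frame points.
    """
    if bins < 2:
        raise ValidationError("bins must be >= 2")
    ref = np.asarray(ref, dtype=float)
    flt = np.asarray(flt, dtype=float)
    sites = np.atleast_2d(np.asarray(sites, dtype=float))
    h, w = ref.shape
    if np.any((sites[:, 0] < 0) | (sites[:, 0] > w - 1)
              | (sites[:, 1] < 0) | (sites[:, 1] > h - 1)):
        raise ValidationError("all sites must lie in the reference domain")

    mapped = np.atleast_2d(np.asarray(mapping(sites), dtype=float))
    hf, wf = flt.shape
    ok = ((mapped[:, 0] >= 0) & (mapped[:, 0] <= wf - 1)
          & (mapped[:, 1] >= 0) & (mapped[:, 1] <= hf - 1)
          & np.all(np.isfinite(mapped), axis=1))

    counts = np.zeros((bins, bins))
    if not np.any(ok):
        return JointHistogram(counts)

    s, q = sites[ok], mapped[ok]
    rows = intensity_bin(bilinear_sample(ref, s) if np.any(s != np.round(s))
                         else ref[s[:, 1].astype(int), s[:, 0].astype(int)], bins)
    x0, y0, x1, y1, fx, fy = _bilinear_parts(flt, q[:, 0], q[:, 1])
    for yy, xx, wgt in (
        (y0, x0, (1 - fx) * (1 - fy)),
        (y0, x1, fx * (1 - fy)),
        (y1, x0, (1 - fx) * fy),
        (y1, x1, fx * fy),
    ):
        cols = intensity_bin(flt[yy, xx], bins)
        np.add.at(counts, (rows, cols), wgt)
    return JointHistogram(counts)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def nmi_from_hist(hist: JointHistogram) -> float:
    """Normalized mutual information (H1 + H2) / H12 of a joint histogram.

    Ranges over [1, 2]; a single occupied cell (zero joint entropy, i.e. a
    deterministic intensity pair) returns 2 by convention.
    """
    counts = np.asarray(hist.counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValidationError("empty joint histogram")
    p = counts / total
    h12 = _entropy(p.ravel())
    if h12 == 0.0:
        return 2.0
    return (_entropy(p.sum(axis=1)) + _entropy(p.sum(axis=0))) / h12


@dataclass
class MetricsReport:
    """The four evaluation metrics between two aligned images."""

    ssd: float  # mean squared intensity difference
    sad: float  # mean absolute intensity difference
    ncc: float  # Pearson correlation, in [-1, 1]
    nmi: float  # normalized mutual information, in [1, 2]

    def as_dict(self) -> dict:
        return {"ssd": self.ssd, "sad": self.sad, "ncc": self.ncc, "nmi": self.nmi}


def compute_metrics(a: np.ndarray, b: np.ndarray, bins: int = 32,
                    mask: np.ndarray | None = None) -> MetricsReport:
    """SSD/SAD/NCC/NMI between two same-size images.

    SSD and SAD are per-pixel means on the [0, 1] intensity scale; NMI uses
    an integer-binned joint histogram (no PVI needed on aligned grids).
    An optional boolean ``mask`` restricts the evaluation domain.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError(f"size mismatch: {a.shape} vs {b.shape}")
    if mask is not None:
        av, bv = a[mask], b[mask]
        if av.size == 0:
            raise ValidationError("empty evaluation mask")
    else:
        av, bv = a.ravel(), b.ravel()

    diff = av - bv
    ssd = float((diff ** 2).mean())
    sad = float(np.abs(diff).mean())

    sa, sb = av.std(), bv.std()
    if sa < 1e-15 or sb < 1e-15:
        identical = bool(np.array_equal(av, bv))
        warnings.warn("zero-variance image in NCC; reporting degenerate value")
        ncc = 1.0 if identical else 0.0
    else:
        ncc = float(np.corrcoef(av, bv)[0, 1])

    counts = np.zeros((bins, bins))
    np.add.at(counts, (intensity_bin(av, bins), intensity_bin(bv, bins)), 1.0)
    nmi = nmi_from_hist(JointHistogram(counts))
    return MetricsReport(ssd=ssd, sad=sad, ncc=ncc, nmi=nmi)


def warp_backward(flt: np.ndarray, mapping, out_shape=None):
    """Backward-warp ``flt`` through ``mapping`` (output frame -> float frame).

    Every output pixel takes the bilinear sample of ``flt`` at its mapped
    position; out-of-bounds samples become 0 and are flagged False in the
    returned validity mask.

    Returns
    -------
    (out, valid) : (ndarray, ndarray of bool)
    """
    flt = np.asarray(flt, dtype=float)
    if out_shape is None:
        out_shape = flt.shape
    h, w = out_shape
    ys, xs = np.mgrid[0:h, 0:w]
    pts = np.column_stack([xs.ravel().astype(float), ys.ravel().astype(float)])
    mapped = np.atleast_2d(np.asarray(mapping(pts), dtype=float))
    hf, wf = flt.shape
    valid = ((mapped[:, 0] >= 0) & (mapped[:, 0] <= wf - 1)
             & (mapped[:, 1] >= 0) & (mapped[:, 1] <= hf - 1)
             & np.all(np.isfinite(mapped), axis=1))
    out = np.zeros(h * w)
    if np.any(valid):
        out[valid] = bilinear_sample(flt, mapped[valid])
    return out.reshape(h, w), valid.reshape(h, w)
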