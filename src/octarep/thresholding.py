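"""The eleven binarization thresholding algorithms.

Five global methods compute one threshold from the 256-bin image
histogram; six local methods compute a per-pixel threshold from a
circular neighborhood of configurable radius (default 15 px, the radius
used across devices in prior OCTA quantification work).  One tie rule is
used everywhere: a pixel is white (flow) iff its value is strictly
greater than the threshold.

Method constants default to the conventions of the ImageJ
Auto Threshold / Auto Local Threshold plugin family, which is where
these algorithms entered the OCTA literature; all are overridable via
``ThresholdSpec.params``.

Border handling for local neighborhoods is edge replication by default.
A second mode, ``border="ignore"``, restricts each neighborhood to
in-image pixels; with a radius at least the image diagonal that mode
makes every local method degenerate to its global counterpart, which is
how the local implementations are cross-checked.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .images import BinaryImage, GrayImage

__all__ = [
    "GLOBAL_METHODS",
    "LOCAL_METHODS",
    "ALL_METHODS",
    "DEFAULT_METHOD_PARAMS",
    "ThresholdSpec",
    "Histogram256",
    "disk_footprint",
    "global_threshold",
    "binarize_global",
    "binarize_local",
    "binarize",
]

GLOBAL_METHODS = (
    "global_default",
    "global_huang",
    "global_isodata",
    "global_mean",
    "global_otsu",
)
LOCAL_METHODS = (
    "local_bernsen",
    "local_mean",
    "local_median",
    "local_niblack",
    "local_otsu",
    "local_phansalkar",
)
ALL_METHODS = GLOBAL_METHODS + LOCAL_METHODS

DEFAULT_METHOD_PARAMS: dict[str, float] = {
    "bernsen_contrast": 15.0,
    "niblack_k": 0.2,
    "niblack_c": 0.0,
    "mean_c": 0.0,
    "median_c": 0.0,
    "phansalkar_k": 0.25,
    "phansalkar_r": 0.5,
    "phansalkar_p": 2.0,
    "phansalkar_q": 10.0,
}


@dataclass(frozen=True)
class ThresholdSpec:
    """A binarization method plus its radius (local only) and constants."""

    method: str
    radius_px: int = 15
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.method not in ALL_METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if self.is_local and self.radius_px < 1:
            raise ValueError("radius_px must be >= 1 for local methods")
        unknown = set(self.params) - set(DEFAULT_METHOD_PARAMS)
        if unknown:
            raise ValueError(f"unknown method params: {sorted(unknown)}")

    @property
    def is_local(self) -> bool:
        return self.method in LOCAL_METHODS

    def param(self, name: str) -> float:
        return float(self.params.get(name, DEFAULT_METHOD_PARAMS[name]))


@dataclass(frozen=True)
class Histogram256:
    """256-bin gray-level histogram of an 8-bit image."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (256,) or (counts < 0).any():
            raise ValueError("counts must be 256 non-negative integers")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def from_image(cls, image: GrayImage) -> "Histogram256":
        return cls(np.bincount(image.pixels.ravel(), minlength=256))


def disk_footprint(radius: int) -> np.ndarray:
    """Boolean circular disc: offsets with dx^2 + dy^2 <= radius^2."""
    yy, xx = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    return (yy * yy + xx * xx) <= radius * radius


# ---------------------------------------------------------------------------
# global methods
# ---------------------------------------------------------------------------

def _occupied_range(counts: np.ndarray) -> tuple[int, int]:
    occ = np.nonzero(counts)[0]
    return int(occ[0]), int(occ[-1])


def _intermeans_fixpoint(counts: np.ndarray) -> int:
    """Smallest t with t == floor((mean below + mean above) / 2).

    The intermeans map is non-decreasing in t and maps the occupied range
    into itself, so a fixed point always exists; the scan returns the
    smallest one.
    """
    lo, hi = _occupied_range(counts)
    vals = np.arange(256, dtype=float)
    c = counts.astype(float)
    for t in range(lo, hi):
        below = c[: t + 1]
        above = c[t + 1:]
        nb, na = below.sum(), above.sum()
        if nb == 0 or na == 0:
            continue
        mb = (vals[: t + 1] * below).sum() / nb
        ma = (vals[t + 1:] * above).sum() / na
        if t == int((mb + ma) / 2.0):
            return t
    return (lo + hi) // 2


def _threshold_isodata(counts: np.ndarray) -> int:
    return _intermeans_fixpoint(counts)


def _threshold_default(counts: np.ndarray) -> int:
    """Legacy intermeans variant: the extreme occupied bins are ignored.

    This is what distinguishes the "default" method from plain isodata
    on histograms with heavy mass at the darkest or brightest occupied
    gray level; on other histograms the two coincide.
    """
    lo, hi = _occupied_range(counts)
    trimmed = counts.copy()
    trimmed[lo] = 0
    trimmed[hi] = 0
    if trimmed.sum() == 0 or len(np.nonzero(trimmed)[0]) == 1:
        return (lo + hi) // 2
    return _intermeans_fixpoint(trimmed)


def _threshold_mean(counts: np.ndarray) -> int:
    vals = np.arange(256, dtype=float)
    return int(np.floor((vals * counts).sum() / counts.sum()))


def _otsu_from_counts(counts2d: np.ndarray) -> np.ndarray:
    """Vectorized Otsu over rows of histograms; smallest maximizer per row.

    Maximizes the between-class variance of the split {<= t} / {> t};
    rows with a single occupied bin return that bin.
    """
    counts2d = np.atleast_2d(np.asarray(counts2d, dtype=np.float64))
    vals = np.arange(256, dtype=np.float64)
    c = np.cumsum(counts2d, axis=1)
    s = np.cumsum(counts2d * vals, axis=1)
    n = c[:, -1:]
    stot = s[:, -1:]
    valid = (c > 0) & (c < n)
    with np.errstate(divide="ignore", invalid="ignore"):
        # proportional to w0*w1*(mu0-mu1)^2
        crit = (stot * c - s * n) ** 2 / (c * (n - c))
    crit = np.where(valid, crit, -np.inf)
    t = np.argmax(crit, axis=1)  # first (smallest) maximizer
    degenerate = ~valid.any(axis=1)
    if degenerate.any():
        t = t.copy()
        t[degenerate] = np.argmax(counts2d[degenerate], axis=1)
    return t


def _threshold_otsu(counts: np.ndarray) -> int:
    return int(_otsu_from_counts(counts[None, :])[0])


def _huang_entropy(counts: np.ndarray, t: int, lo: int, hi: int) -> float:
    """Fuzzy-membership entropy of the split at t (Huang & Wang)."""
    vals = np.arange(256, dtype=float)
    c = counts.astype(float)
    nb = c[: t + 1].sum()
    na = c[t + 1:].sum()
    mu0 = (vals[: t + 1] * c[: t + 1]).sum() / nb if nb > 0 else 0.0
    mu1 = (vals[t + 1:] * c[t + 1:]).sum() / na if na > 0 else 0.0
    mu = np.where(vals <= t, mu0, mu1)
    u = 1.0 / (1.0 + np.abs(vals - mu) / (hi - lo))
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -u * np.log(u) - (1 - u) * np.log(1 - u)
    h = np.where((u <= 0) | (u >= 1), 0.0, h)
    return float((c * h).sum())


def _threshold_huang(counts: np.ndarray) -> int:
    lo, hi = _occupied_range(counts)
    if lo == hi:
        return lo
    best_t, best_s = lo, np.inf
    for t in range(lo, hi):
        s = _huang_entropy(counts, t, lo, hi)
        if s < best_s - 1e-12:
            best_t, best_s = t, s
    return best_t


_GLOBAL_DISPATCH = {
    "global_default": _threshold_default,
    "global_huang": _threshold_huang,
    "global_isodata": _threshold_isodata,
    "global_mean": _threshold_mean,
    "global_otsu": _threshold_otsu,
}


def global_threshold(hist: Histogram256, method: str) -> int:
    """Method-specific threshold t in [0, 255] from a 256-bin histogram."""
    if method not in GLOBAL_METHODS:
        raise ValueError(f"not a global method: {method!r}")
    counts = hist.counts
    if counts.sum() == 0:
        raise ValueError("empty histogram")
    occ = np.nonzero(counts)[0]
    if len(occ) == 1:
        warnings.warn("single-valued image: degenerate threshold")
        return int(occ[0])
    return int(_GLOBAL_DISPATCH[method](counts))


def binarize_global(image: GrayImage, spec: ThresholdSpec) -> BinaryImage:
    """White iff pixel > t, with t from the image-wide histogram."""
    if spec.is_local:
        raise ValueError("spec.method is not global")
    t = global_threshold(Histogram256.from_image(image), spec.method)
    return BinaryImage((image.pixels > t).astype(np.uint8), image.pitch_um)


# ---------------------------------------------------------------------------
# local methods
# ---------------------------------------------------------------------------

def _check_local(image: GrayImage, spec: ThresholdSpec, border: str) -> None:
    if not spec.is_local:
        raise ValueError("spec.method is not local")
    if border not in ("replicate", "ignore"):
        raise ValueError("border must be 'replicate' or 'ignore'")
    # with replicate padding a radius at the image scale is meaningless;
    # ignore mode simply clips the neighborhood to the image
    if border == "replicate" and spec.radius_px >= min(image.shape):
        raise ValueError("radius must be smaller than the image size")


def _local_mean_std(
    img: np.ndarray, radius: int, border: str
) -> tuple[np.ndarray, np.ndarray]:
    fp = disk_footprint(radius).astype(float)
    f = img.astype(float)
    if border == "replicate":
        # unit kernel keeps the sums exact (integers below 2^53), so the
        # strict p > mean tie rule is bit-reproducible
        n = fp.sum()
        m = ndimage.correlate(f, fp, mode="nearest") / n
        m2 = ndimage.correlate(f * f, fp, mode="nearest") / n
    else:
        cnt = ndimage.correlate(np.ones_like(f), fp, mode="constant", cval=0.0)
        m = ndimage.correlate(f, fp, mode="constant", cval=0.0) / cnt
        m2 = ndimage.correlate(f * f, fp, mode="constant", cval=0.0) / cnt
    var = np.maximum(m2 - m * m, 0.0)
    return m, np.sqrt(var)


def _iter_neighborhood_chunks(img: np.ndarray, radius: int, border: str,
                              max_elems: int = 40_000_000):
    """Yield (row-slice, values (npix, K) uint8, valid (npix, K) bool|None)."""
    h_px, w_px = img.shape
    if border == "replicate":
        pad = np.pad(img, radius, mode="edge")
        vpad = None
    else:
        pad = np.pad(img, radius, mode="constant", constant_values=0)
        vpad = np.pad(np.ones_like(img, dtype=bool), radius,
                      mode="constant", constant_values=False)
    offsets = np.argwhere(disk_footprint(radius))  # offsets into padded array
    k = len(offsets)
    chunk = max(1, min(h_px, max_elems // max(1, w_px * k)))
    for y0 in range(0, h_px, chunk):
        rows = min(chunk, h_px - y0)
        vals = np.empty((rows * w_px, k), dtype=np.uint8)
        valid = np.empty((rows * w_px, k), dtype=bool) if vpad is not None else None
        for idx, (dy, dx) in enumerate(offsets):
            block = pad[y0 + dy: y0 + dy + rows, dx: dx + w_px]
            vals[:, idx] = block.ravel()
            if valid is not None:
                vblock = vpad[y0 + dy: y0 + dy + rows, dx: dx + w_px]
                valid[:, idx] = vblock.ravel()
        yield slice(y0, y0 + rows), vals, valid


def _neighborhood_histograms(vals: np.ndarray,
                             valid: np.ndarray | None) -> np.ndarray:
    npix, k = vals.shape
    idx = np.arange(npix, dtype=np.int64)[:, None] * 256 + vals.astype(np.int64)
    if valid is None:
        counts = np.bincount(idx.ravel(), minlength=npix * 256)
    else:
        counts = np.bincount(idx.ravel(), weights=valid.ravel().astype(float),
                             minlength=npix * 256)
    return counts.reshape(npix, 256)


def _local_otsu_map(img: np.ndarray, radius: int, border: str) -> np.ndarray:
    if border == "replicate":
        # sliding-histogram rank filter on an edge-padded raster; agrees
        # bin-for-bin with _otsu_from_counts on the neighborhood histogram
        from skimage.filters import rank

        pad = np.pad(img, radius, mode="edge")
        t = rank.otsu(pad, disk_footprint(radius))
        return t[radius:-radius, radius:-radius].astype(float)
    t = np.empty(img.shape, dtype=float)
    for rows, vals, valid in _iter_neighborhood_chunks(img, radius, border):
        hist = _neighborhood_histograms(vals, valid)
        t[rows] = _otsu_from_counts(hist).reshape(-1, img.shape[1])
    return t


def _local_median_map(img: np.ndarray, radius: int, border: str) -> np.ndarray:
    if border == "replicate":
        fp = disk_footprint(radius)
        return ndimage.median_filter(img, footprint=fp, mode="nearest").astype(float)
    out = np.empty(img.shape, dtype=float)
    for rows, vals, valid in _iter_neighborhood_chunks(img, radius, border):
        v = vals.astype(float)
        v[~valid] = np.nan
        out[rows] = np.nanmedian(v, axis=1).reshape(-1, img.shape[1])
    return out


def _local_minmax(img: np.ndarray, radius: int,
                  border: str) -> tuple[np.ndarray, np.ndarray]:
    if border == "replicate":
        fp = disk_footprint(radius)
        mx = ndimage.maximum_filter(img, footprint=fp, mode="nearest")
        mn = ndimage.minimum_filter(img, footprint=fp, mode="nearest")
        return mx.astype(float), mn.astype(float)
    mx = np.empty(img.shape, dtype=float)
    mn = np.empty(img.shape, dtype=float)
    for rows, vals, valid in _iter_neighborhood_chunks(img, radius, border):
        v = vals.astype(float)
        v[~valid] = np.nan
        mx[rows] = np.nanmax(v, axis=1).reshape(-1, img.shape[1])
        mn[rows] = np.nanmin(v, axis=1).reshape(-1, img.shape[1])
    return mx, mn


def binarize_local(
    image: GrayImage, spec: ThresholdSpec, border: str = "replicate"
) -> BinaryImage:
    """Per-pixel thresholding over a circular disc neighborhood.

    Thresholds per method (mean/std are neighborhood statistics):

    * bernsen: midgray = (max + min) / 2; if max - min < bernsen_contrast
      the whole neighborhood is low-contrast and the pixel is assigned by
      midgray vs 128, else white iff pixel > midgray,
    * mean: t = mean - mean_c,
    * median: t = median - median_c,
    * niblack: t = mean + niblack_k * std - niblack_c,
    * otsu: Otsu's criterion on the neighborhood histogram,
    * phansalkar: t = m * (1 + p*exp(-q*m) + k*(s/r - 1)) with the mean m
      and std s normalized to [0, 1] (designed for low-contrast images,
      hence its sensitivity to contrast changes).
    """
    _check_local(image, spec, border)
    img = image.pixels
    p = img.astype(float)
    r = spec.radius_px
    method = spec.method

    if method == "local_mean":
        m, _ = _local_mean_std(img, r, border)
        t = m - spec.param("mean_c")
        white = p > t
    elif method == "local_niblack":
        m, s = _local_mean_std(img, r, border)
        t = m + spec.param("niblack_k") * s - spec.param("niblack_c")
        white = p > t
    elif method == "local_phansalkar":
        m, s = _local_mean_std(img, r, border)
        mn, sn = m / 255.0, s / 255.0
        kk = spec.param("phansalkar_k")
        rr = spec.param("phansalkar_r")
        pp = spec.param("phansalkar_p")
        qq = spec.param("phansalkar_q")
        t = 255.0 * mn * (1.0 + pp * np.exp(-qq * mn) + kk * (sn / rr - 1.0))
        white = p > t
    elif method == "local_median":
        t = _local_median_map(img, r, border) - spec.param("median_c")
        white = p > t
    elif method == "local_otsu":
        t = _local_otsu_map(img, r, border)
        white = p > t
    elif method == "local_bernsen":
        mx, mn = _local_minmax(img, r, border)
        mid = (mx + mn) / 2.0
        low_contrast = (mx - mn) < spec.param("bernsen_contrast")
        white = np.where(low_contrast, mid > 128.0, p > mid)
    else:  # pragma: no cover
        raise ValueError(method)
    return BinaryImage(white.astype(np.uint8), image.pitch_um)


def binarize(image: GrayImage, spec: ThresholdSpec,
             border: str = "replicate") -> BinaryImage:
    """Dispatch to the global or local binarizer according to the spec."""
    if spec.is_local:
        return binarize_local(image, spec, border=border)
    return binarize_global(image, spec)
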