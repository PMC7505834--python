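"""Contrast adjustment and pre-binarization image processing.

Four operations are applied (independently, never chained) to angiograms
before thresholding:

* pointwise contrast change ``f(p) = a * (p - 128) + 128`` with a in
  {1.5, 2.0} (a = 1.0 is the identity),
* histogram normalization stretching the central mass of the histogram
  to the full [0, 255] range while saturating a small tail fraction,
* contrast-limited adaptive histogram equalization (CLAHE) with a tile
  grid, a per-tile slope (clip) limit, and bilinear blending of tile
  mappings,
* rigid registration of repeat acquisitions against a reference image.

Registration is estimated by phase correlation plus a bounded rotation
search rather than keypoint matching; the contract is sub-pixel /
sub-quarter-degree recovery of a rigid misalignment, not a particular
feature detector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize
from skimage.registration import phase_cross_correlation
from skimage.transform import AffineTransform, warp

from .images import GrayImage

__all__ = [
    "CONTRAST_CENTER",
    "adjust_contrast",
    "normalize_histogram",
    "ClaheParams",
    "clahe",
    "RigidTransform",
    "apply_rigid",
    "register_rigid",
]

CONTRAST_CENTER = 128.0


def adjust_contrast(image: GrayImage, gain: float) -> GrayImage:
    """Pointwise contrast change ``f(p) = gain*(p - 128) + 128``.

    The value 128 is the fixed point; the result is rounded
    half-away-from-zero and clipped to [0, 255], so for full-range input
    any gain > 1 clips both tails.
    """
    if gain <= 0:
        raise ValueError("gain must be positive")
    f = gain * (image.pixels.astype(float) - CONTRAST_CENTER) + CONTRAST_CENTER
    return GrayImage.from_float(f, image.pitch_um)


def normalize_histogram(image: GrayImage, saturated_percent: float = 0.3) -> GrayImage:
    """Stretch the histogram so that min maps to 0 and max to 255.

    ``saturated_percent`` is the total fraction of pixels allowed to
    saturate (default 0.3%); half of it is driven to 0 at the low end and
    half to 255 at the high end.  Anchors are taken from the cumulative
    histogram: the lowest gray level whose cumulative count exceeds the
    tail budget, and symmetrically from above.  A constant image is
    returned unchanged with a warning.
    """
    if not (0 <= saturated_percent < 100):
        raise ValueError("saturated_percent must lie in [0, 100)")
    p = image.pixels
    if p.min() == p.max():
        warnings.warn("constant image: histogram normalization is a no-op")
        return image.copy()
    hist = np.bincount(p.ravel(), minlength=256)
    n = hist.sum()
    tail = n * saturated_percent / 100.0 / 2.0
    cum = np.cumsum(hist)
    lo = int(np.argmax(cum > tail))
    cum_rev = np.cumsum(hist[::-1])
    hi = 255 - int(np.argmax(cum_rev > tail))
    if lo >= hi:
        warnings.warn("degenerate histogram after saturation: returning input")
        return image.copy()
    out = (p.astype(float) - lo) * 255.0 / (hi - lo)
    return GrayImage.from_float(out, image.pitch_um)


@dataclass(frozen=True)
class ClaheParams:
    """CLAHE parameters: tile side, histogram bins, and slope (clip) limit."""

    block_size: int = 127
    histogram_bins: int = 256
    max_slope: float = 3.0

    def __post_init__(self) -> None:
        if self.block_size < 3 or self.block_size % 2 == 0:
            raise ValueError("block_size must be odd and >= 3")
        if self.histogram_bins < 2:
            raise ValueError("histogram_bins must be >= 2")
        if self.max_slope < 1:
            raise ValueError("max_slope must be >= 1")


def _clip_histogram(hist: np.ndarray, limit: float) -> np.ndarray:
    """Clip histogram counts at `limit`, redistributing the excess uniformly."""
    h = hist.astype(float).copy()
    nbins = h.size
    total = h.sum()
    for _ in range(128):
        excess = np.clip(h - limit, 0, None).sum()
        if excess <= 1e-9 * max(total, 1.0):
            break
        h = np.minimum(h, limit)
        h += excess / nbins
    return np.minimum(h, limit)


def _tile_mapping(tile: np.ndarray, params: ClaheParams) -> np.ndarray:
    """Equalization lookup table (length 256) for one tile."""
    nbins = params.histogram_bins
    bin_of = (np.arange(256) * nbins) // 256
    hist = np.bincount(bin_of[tile.ravel()], minlength=nbins)
    n = tile.size
    limit = params.max_slope * n / nbins
    h = _clip_histogram(hist, limit)
    cdf = np.cumsum(h) / h.sum()
    cdf0 = cdf[0]
    if cdf0 >= 1.0:
        return np.arange(256, dtype=float)
    # anchor the first bin at 0 so a uniform (fully clipped) histogram
    # yields the identity mapping
    lut_bins = 255.0 * (cdf - cdf0) / (1.0 - cdf0)
    return lut_bins[bin_of]


def clahe(image: GrayImage, params: ClaheParams | None = None) -> GrayImage:
    """Contrast-limited adaptive histogram equalization, 8-bit in / 8-bit out.

    The image is divided into ceil(size / block_size) tiles per axis;
    each tile's histogram is clipped so the equalization slope never
    exceeds ``max_slope``, and per-pixel output is the bilinear blend of
    the four surrounding tile mappings (replicated beyond the outermost
    tile centers).  Constant images map to constant images.
    """
    params = params or ClaheParams()
    img = image.pixels
    h_px, w_px = img.shape
    ny = max(1, int(np.ceil(h_px / params.block_size)))
    nx = max(1, int(np.ceil(w_px / params.block_size)))
    y_edges = np.linspace(0, h_px, ny + 1).astype(int)
    x_edges = np.linspace(0, w_px, nx + 1).astype(int)
    luts = np.empty((ny, nx, 256))
    for i in range(ny):
        for j in range(nx):
            tile = img[y_edges[i]:y_edges[i + 1], x_edges[j]:x_edges[j + 1]]
            luts[i, j] = _tile_mapping(tile, params)
    y_centers = (y_edges[:-1] + y_edges[1:] - 1) / 2.0
    x_centers = (x_edges[:-1] + x_edges[1:] - 1) / 2.0
    ty = np.interp(np.arange(h_px), y_centers, np.arange(ny))
    tx = np.interp(np.arange(w_px), x_centers, np.arange(nx))
    iy0 = np.clip(np.floor(ty).astype(int), 0, ny - 1)
    ix0 = np.clip(np.floor(tx).astype(int), 0, nx - 1)
    iy1 = np.minimum(iy0 + 1, ny - 1)
    ix1 = np.minimum(ix0 + 1, nx - 1)
    wy = (ty - iy0)[:, None]
    wx = (tx - ix0)[None, :]
    iy0g, ix0g = iy0[:, None], ix0[None, :]
    iy1g, ix1g = iy1[:, None], ix1[None, :]
    out = (
        (1 - wy) * (1 - wx) * luts[iy0g, ix0g, img]
        + (1 - wy) * wx * luts[iy0g, ix1g, img]
        + wy * (1 - wx) * luts[iy1g, ix0g, img]
        + wy * wx * luts[iy1g, ix1g, img]
    )
    return GrayImage.from_float(out, image.pitch_um)


@dataclass(frozen=True)
class RigidTransform:
    """Rigid alignment: rotation (degrees, about image center) then translation.

    ``translation`` is in (row, col) pixel order.  ``success`` is False
    when estimation failed and the identity transform was returned.
    """

    translation: tuple[float, float] = (0.0, 0.0)
    rotation_deg: float = 0.0
    success: bool = True

    @property
    def is_identity(self) -> bool:
        return self.rotation_deg == 0.0 and self.translation == (0.0, 0.0)


def apply_rigid(
    pixels: np.ndarray,
    translation: tuple[float, float] = (0.0, 0.0),
    rotation_deg: float = 0.0,
    order: int = 1,
) -> np.ndarray:
    """Rotate about the raster center then translate, with edge replication.

    Pure-identity transforms skip interpolation entirely so that zero
    jitter reproduces the input bit-exactly.
    """
    dy, dx = translation
    if dy == 0.0 and dx == 0.0 and rotation_deg == 0.0:
        return np.asarray(pixels, dtype=float).copy()
    arr = np.asarray(pixels, dtype=float)
    h_px, w_px = arr.shape
    cy, cx = (h_px - 1) / 2.0, (w_px - 1) / 2.0
    # skimage transforms use (x, y) coordinates
    forward = (
        AffineTransform(translation=(-cx, -cy))
        + AffineTransform(rotation=np.deg2rad(rotation_deg))
        + AffineTransform(translation=(cx + dx, cy + dy))
    )
    return warp(arr, forward.inverse, order=order, mode="edge", preserve_range=True)


def register_rigid(
    moving: GrayImage,
    reference: GrayImage,
    *,
    upsample_factor: int = 20,
    max_rotation_deg: float = 3.0,
    angle_step_deg: float = 0.5,
) -> tuple[GrayImage, RigidTransform]:
    """Estimate and apply the rigid transform aligning `moving` to `reference`.

    Translation comes from sub-pixel phase correlation; rotation from a
    coarse grid over +/- `max_rotation_deg` refined by bounded scalar
    minimization of the phase-correlation residual.  On failure (flat
    images, non-finite residuals) the identity transform is returned
    with a warning rather than raising mid-pipeline.
    """
    if moving.shape != reference.shape:
        raise ValueError("moving and reference must share dimensions")
    ref = reference.pixels.astype(float)
    mov = moving.pixels.astype(float)
    if ref.std() == 0 or mov.std() == 0:
        warnings.warn("flat image: registration skipped (identity transform)")
        return moving.copy(), RigidTransform(success=False)

    def residual(angle: float) -> tuple[np.ndarray, float]:
        cand = apply_rigid(mov, rotation_deg=angle)
        # plain cross-correlation: the default phase normalization yields a
        # near-constant residual, useless as a rotation objective
        shift, error, _ = phase_cross_correlation(
            ref, cand, upsample_factor=upsample_factor, normalization=None
        )
        return shift, float(error)

    try:
        best_angle = 0.0
        shift, best_err = residual(0.0)
        if max_rotation_deg > 0:
            grid = np.arange(-max_rotation_deg, max_rotation_deg + 1e-9,
                             angle_step_deg)
            for a in grid:
                if a == 0.0:
                    continue
                s, e = residual(float(a))
                if e < best_err:
                    best_angle, best_err, shift = float(a), e, s
            res = optimize.minimize_scalar(
                lambda a: residual(float(a))[1],
                bounds=(best_angle - angle_step_deg, best_angle + angle_step_deg),
                method="bounded",
                options={"xatol": 0.01},
            )
            if np.isfinite(res.fun) and res.fun <= best_err:
                best_angle = float(res.x)
                shift, best_err = residual(best_angle)
        if not np.all(np.isfinite(shift)) or not np.isfinite(best_err):
            raise FloatingPointError("non-finite registration residual")
    except Exception as exc:  # estimation failure must not kill the pipeline
        warnings.warn(f"registration failed ({exc}): identity transform")
        return moving.copy(), RigidTransform(success=False)

    transform = RigidTransform(
        translation=(float(shift[0]), float(shift[1])),
        rotation_deg=best_angle,
    )
    resampled = apply_rigid(mov, transform.translation, transform.rotation_deg)
    return GrayImage.from_float(resampled, moving.pitch_um), transform
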