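"""Quantification of binarized angiograms.

Three metric families are computed from a binary flow mask:

* vessel area density (VAD): the percentage of white pixels,
* vessel length: the binary image is thinned to a 1-px-wide skeleton
  and the skeleton pixels are counted (an optional mode instead sums
  Euclidean steps between adjacent skeleton pixels),
* flow-deficit statistics (choriocapillaris only): the mask is
  inverted, dark no-flow regions become 8-connected components, and
  their count and mean area are reported.  No size filter is applied
  and components touching the image edge are included.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize as _sk_skeletonize

from .images import BinaryImage

__all__ = [
    "MetricRecord",
    "SkeletonImage",
    "vessel_area_density",
    "skeletonize",
    "vessel_length",
    "flow_deficits",
    "quantify_image",
]

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass
class MetricRecord:
    """Per-image quantification results; fields are None when inapplicable."""

    vad_percent: float
    vessel_length_px: float | None = None
    vessel_length_um: float | None = None
    fd_count: int | None = None
    fd_mean_size_px2: float | None = None
    fd_mean_size_um2: float | None = None


@dataclass
class SkeletonImage:
    """1-px-wide medial lines of a binary mask (1 = skeleton pixel)."""

    pixels: np.ndarray
    pitch_um: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.dtype == bool:
            arr = arr.astype(np.uint8)
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("skeleton pixels must be 0 or 1")
        self.pixels = arr.astype(np.uint8)

    @property
    def mask(self) -> np.ndarray:
        return self.pixels.astype(bool)


def vessel_area_density(binary: BinaryImage) -> float:
    """Percentage of white (flow) pixels."""
    return 100.0 * float(binary.pixels.sum()) / binary.pixels.size


def skeletonize(binary: BinaryImage) -> SkeletonImage:
    """Binary thinning to 1-px-wide lines, preserving 8-connectivity."""
    skel = _sk_skeletonize(binary.mask)
    return SkeletonImage(skel, binary.pitch_um)


def vessel_length(
    skeleton: SkeletonImage, pitch_um: float | None = None, mode: str = "pixel"
) -> tuple[float, float]:
    """Vessel length from a skeleton, in pixels and microns.

    ``mode="pixel"`` (default) counts skeleton pixels, mirroring
    skeleton-analysis tools that tag and count all pixels of the thinned
    image.  ``mode="euclidean"`` sums steps between 8-adjacent skeleton
    pixels (1 for orthogonal, sqrt(2) for diagonal neighbors).
    """
    pitch = skeleton.pitch_um if pitch_um is None else pitch_um
    m = skeleton.mask
    if mode == "pixel":
        length = float(m.sum())
    elif mode == "euclidean":
        orth = float((m[:, 1:] & m[:, :-1]).sum() + (m[1:, :] & m[:-1, :]).sum())
        diag = float((m[1:, 1:] & m[:-1, :-1]).sum() + (m[1:, :-1] & m[:-1, 1:]).sum())
        length = orth + np.sqrt(2.0) * diag
    else:
        raise ValueError("mode must be 'pixel' or 'euclidean'")
    return length, length * pitch


def flow_deficits(
    binary_cc: BinaryImage, pitch_um: float | None = None
) -> tuple[int, float | None, float | None]:
    """Count and mean size of flow deficits in a binarized CC image.

    The binary image is inverted (black no-flow pixels become the
    foreground), components are labeled with 8-connectivity, and the
    count and arithmetic-mean component area are returned.  With zero
    deficits the mean size is None (missing), never 0.
    """
    pitch = binary_cc.pitch_um if pitch_um is None else pitch_um
    deficits = ~binary_cc.mask
    labels, count = ndimage.label(deficits, structure=_EIGHT)
    if count == 0:
        return 0, None, None
    mean_px2 = float(deficits.sum()) / count
    return int(count), mean_px2, mean_px2 * pitch * pitch


def quantify_image(binary: BinaryImage, plexus: str) -> MetricRecord:
    """All applicable metrics for one binarized image.

    Vessel length applies to the retinal plexuses (FRL/SCP/DCP); flow
    deficits to the choriocapillaris (CC); VAD to everything.
    """
    rec = MetricRecord(vad_percent=vessel_area_density(binary))
    if plexus == "CC":
        rec.fd_count, rec.fd_mean_size_px2, rec.fd_mean_size_um2 = flow_deficits(binary)
    else:
        skel = skeletonize(binary)
        rec.vessel_length_px, rec.vessel_length_um = vessel_length(skel)
    return rec
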