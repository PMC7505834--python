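"""Canonical 8-bit image containers, device profiles, and raster I/O.

Everything downstream of acquisition operates on 8-bit grayscale en-face
angiograms (pixel values 0-255) with a known physical pixel pitch.  The
pitch is derived from the device profile: a 3 x 3 mm scan rendered at
``image_size_px`` pixels has a pitch of ``3000 / image_size_px`` microns
per pixel, which is what converts the fixed 15-pixel local-threshold
radius into device-specific physical radii.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import imageio.v3 as iio
import numpy as np
import pandas as pd

__all__ = [
    "round_half_away",
    "DeviceProfile",
    "PLEX",
    "CIRRUS",
    "AVANTI",
    "DEVICE_PROFILES",
    "pixel_radius_to_um",
    "GrayImage",
    "BinaryImage",
    "load_image",
    "PLEXUSES",
    "RETINAL_PLEXUSES",
    "CohortEntry",
    "CohortDataset",
]

#: the four en-face slabs analyzed: full retinal layer, superficial and deep
#: capillary plexuses, and the choriocapillaris.
PLEXUSES = ("FRL", "SCP", "DCP", "CC")
RETINAL_PLEXUSES = ("FRL", "SCP", "DCP")


def round_half_away(x: Any) -> np.ndarray:
    """Round to nearest integer with halves away from zero.

    ``np.round`` rounds halves to even; 8-bit image arithmetic here uses
    the away-from-zero convention consistently.
    """
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


@dataclass(frozen=True)
class DeviceProfile:
    """Physical description of an en-face export: raster size and field width."""

    name: str
    image_size_px: int
    scan_size_mm: float = 3.0

    def __post_init__(self) -> None:
        if self.image_size_px <= 0:
            raise ValueError("image_size_px must be positive")
        if self.scan_size_mm <= 0:
            raise ValueError("scan_size_mm must be positive")

    @property
    def pitch_um(self) -> float:
        """Physical size of one pixel in microns."""
        return self.scan_size_mm * 1000.0 / self.image_size_px


PLEX = DeviceProfile("plex", 1024)
CIRRUS = DeviceProfile("cirrus", 429)
AVANTI = DeviceProfile("avanti", 304)
DEVICE_PROFILES = {p.name: p for p in (PLEX, CIRRUS, AVANTI)}


def pixel_radius_to_um(radius_px: int, profile: DeviceProfile) -> float:
    """Convert a pixel radius to microns for a device, to one decimal place.

    A fixed 15 px neighborhood radius corresponds to 43.9 um on a
    1024 px / 3 mm raster but 148.0 um on a 304 px / 3 mm raster.
    """
    if radius_px <= 0:
        raise ValueError("radius_px must be positive")
    return round(radius_px * profile.pitch_um, 1)


@dataclass
class GrayImage:
    """8-bit grayscale raster with physical pixel pitch (microns/pixel)."""

    pixels: np.ndarray
    pitch_um: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise ValueError("GrayImage requires a 2-D array")
        if arr.dtype != np.uint8:
            if not np.issubdtype(arr.dtype, np.integer):
                raise ValueError(
                    "non-integer pixels; use GrayImage.from_float for conversion"
                )
            if arr.min() < 0 or arr.max() > 255:
                raise ValueError("pixel values must lie in [0, 255]")
            arr = arr.astype(np.uint8)
        self.pixels = arr
        if self.pitch_um <= 0:
            raise ValueError("pitch_um must be positive")

    @classmethod
    def from_float(cls, arr: np.ndarray, pitch_um: float) -> "GrayImage":
        """Clip a float array to [0, 255], round half-away-from-zero, wrap."""
        out = np.clip(round_half_away(arr), 0, 255).astype(np.uint8)
        return cls(out, pitch_um)

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, arr: np.ndarray) -> "GrayImage":
        """New image sharing this image's pitch (integer input)."""
        return GrayImage(np.asarray(arr), self.pitch_um)

    def copy(self) -> "GrayImage":
        return GrayImage(self.pixels.copy(), self.pitch_um)

    def save(self, path: str | Path) -> None:
        iio.imwrite(Path(path), self.pixels)


@dataclass
class BinaryImage:
    """Binary flow mask; 1 = white = flow, same raster geometry as its source."""

    pixels: np.ndarray
    pitch_um: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels)
        if arr.ndim != 2:
            raise ValueError("BinaryImage requires a 2-D array")
        if arr.dtype == bool:
            arr = arr.astype(np.uint8)
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("binary pixels must be 0 or 1")
        self.pixels = arr.astype(np.uint8)
        if self.pitch_um <= 0:
            raise ValueError("pitch_um must be positive")

    @property
    def mask(self) -> np.ndarray:
        return self.pixels.astype(bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def inverted(self) -> "BinaryImage":
        return BinaryImage(1 - self.pixels, self.pitch_um)

    def save(self, path: str | Path) -> None:
        iio.imwrite(Path(path), self.pixels * np.uint8(255))


def _to_8bit(arr: np.ndarray) -> np.ndarray:
    """Rescale an integer or float raster to [0, 255] by max-range division."""
    if arr.dtype == np.uint8:
        return arr
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        scaled = arr.astype(float) * 255.0 / info.max
    else:
        # float rasters are taken on the unit range
        scaled = np.clip(arr.astype(float), 0.0, 1.0) * 255.0
    return np.clip(round_half_away(scaled), 0, 255).astype(np.uint8)


def load_image(path: str | Path, profile: DeviceProfile) -> GrayImage:
    """Read a PNG/TIFF raster as an 8-bit GrayImage with the profile's pitch.

    Multi-channel inputs are collapsed to luminance (ITU-R 601 weights)
    with a warning; higher bit depths are rescaled to [0, 255].
    """
    path = Path(path)
    raw = iio.imread(path)
    arr = np.asarray(raw)
    if arr.ndim == 3:
        warnings.warn(f"multi-channel raster {path.name}: converting to luminance")
        rgb = arr[..., :3].astype(float)
        lum = 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]
        if np.issubdtype(raw.dtype, np.integer):
            info = np.iinfo(raw.dtype)
            arr = np.clip(round_half_away(lum), 0, info.max).astype(raw.dtype)
        else:
            arr = lum
    return GrayImage(_to_8bit(arr), profile.pitch_um)


@dataclass
class CohortEntry:
    """One acquisition: who, which repeat, which slab, which device, what was done."""

    subject_id: str
    repeat_index: int
    plexus: str
    device: str
    processing: str
    image: GrayImage
    truth: Any | None = None  # PhantomTruth for synthetic cohorts


@dataclass
class CohortDataset:
    """Subjects x repeats grid of images with provenance labels.

    Invariants: the (subject, repeat, plexus, device, processing) key is
    unique and every subject contributes the same number of repeats.
    """

    entries: list[CohortEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        keys = [
            (e.subject_id, e.repeat_index, e.plexus, e.device, e.processing)
            for e in self.entries
        ]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (subject, repeat, plexus, device, processing)")
        for e in self.entries:
            if e.plexus not in PLEXUSES:
                raise ValueError(f"unknown plexus {e.plexus!r}")
        counts: dict[str, set[int]] = {}
        for e in self.entries:
            counts.setdefault(e.subject_id, set()).add(e.repeat_index)
        sizes = {len(v) for v in counts.values()}
        if len(sizes) > 1:
            raise ValueError("every subject must have the same number of repeats")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def subjects(self) -> list[str]:
        return sorted({e.subject_id for e in self.entries})

    @property
    def n_repeats(self) -> int:
        if not self.entries:
            return 0
        return len({e.repeat_index for e in self.entries if
                    e.subject_id == self.entries[0].subject_id})

    def select(self, **filters: Any) -> list[CohortEntry]:
        """Entries matching all given attribute=value filters."""
        out = self.entries
        for attr, val in filters.items():
            out = [e for e in out if getattr(e, attr) == val]
        return out

    def get(self, subject_id: str, repeat_index: int, **filters: Any) -> CohortEntry:
        hits = self.select(subject_id=subject_id, repeat_index=repeat_index, **filters)
        if len(hits) != 1:
            raise KeyError(f"{len(hits)} entries match {subject_id}/{repeat_index}")
        return hits[0]

    def save(self, directory: str | Path) -> Path:
        """Write images as PNG plus a manifest CSV; returns the manifest path."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        rows = []
        for e in self.entries:
            fname = (
                f"{e.subject_id}_r{e.repeat_index}_{e.plexus}_{e.device}"
                f"_{e.processing}.png"
            )
            e.image.save(directory / fname)
            rows.append(
                {
                    "subject_id": e.subject_id,
                    "repeat": e.repeat_index,
                    "plexus": e.plexus,
                    "device": e.device,
                    "processing": e.processing,
                    "path": fname,
                    "image_size_px": e.image.width_px,
                    "scan_size_mm": round(
                        e.image.pitch_um * e.image.width_px / 1000.0, 6),
                }
            )
        manifest = directory / "manifest.csv"
        pd.DataFrame(rows).to_csv(manifest, index=False)
        return manifest

    @classmethod
    def load(
        cls,
        manifest: str | Path,
        profiles: dict[str, DeviceProfile] | None = None,
    ) -> "CohortDataset":
        manifest = Path(manifest)
        profiles = profiles or DEVICE_PROFILES
        df = pd.read_csv(manifest)
        entries = []
        for _, row in df.iterrows():
            device = str(row["device"])
            if "image_size_px" in df.columns and not pd.isna(row["image_size_px"]):
                profile = DeviceProfile(device, int(row["image_size_px"]),
                                        float(row.get("scan_size_mm", 3.0)))
            else:
                profile = profiles[device]
            img = load_image(manifest.parent / str(row["path"]), profile)
            entries.append(
                CohortEntry(
                    subject_id=str(row["subject_id"]),
                    repeat_index=int(row["repeat"]),
                    plexus=str(row["plexus"]),
                    device=str(row["device"]),
                    processing=str(row.get("processing", "none")),
                    image=img,
                )
            )
        return cls(entries)
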