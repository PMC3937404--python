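"""Volumetric image I/O and the shared data containers.

Conventions used throughout the package:

* 0-based voxel indices, axis order ``(z, y, x)`` for 3D and ``(y, x)``
  for 2D images — i.e. the native numpy axis order of ``tifffile``.
* ``spacing`` is the physical size of one voxel per axis (e.g. µm/voxel)
  in the same axis order as the arrays; all physical coordinates are
  ``index * spacing``.
* Intensities are processed as floating point internally regardless of
  the input bit depth.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import tifffile

logger = logging.getLogger(__name__)

__all__ = [
    "Volume",
    "SeedPoint",
    "TwangParams",
    "LabelImage",
    "read_volume",
    "write_volume",
    "write_label_image",
    "read_label_image",
    "write_seeds_csv",
    "read_seeds_csv",
    "write_regionprops_csv",
]


@dataclass(frozen=True)
class Volume:
    """An n-D scalar intensity image with per-axis physical voxel spacing."""

    data: np.ndarray
    spacing: tuple[float, ...]

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        object.__setattr__(self, "data", data)
        spacing = tuple(float(s) for s in self.spacing)
        object.__setattr__(self, "spacing", spacing)
        if data.ndim not in (2, 3):
            raise ValueError(f"Volume must be 2D or 3D, got {data.ndim}D")
        if len(spacing) != data.ndim:
            raise ValueError(
                f"spacing has {len(spacing)} entries for a {data.ndim}D image"
            )
        if any(s <= 0 for s in spacing):
            raise ValueError(f"spacing must be strictly positive, got {spacing}")
        if not np.all(np.isfinite(data)):
            raise ValueError("Volume data contains non-finite values (NaN/Inf)")

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def astype_float(self) -> "Volume":
        """Return a float64 view of this volume (no-op if already float)."""
        if self.data.dtype == np.float64:
            return self
        return Volume(self.data.astype(np.float64), self.spacing)


@dataclass(frozen=True)
class SeedPoint:
    """A detected blob centroid.

    ``position`` is in voxel coordinates (same axis order as the image),
    ``scale`` is the Gaussian standard deviation that maximised the
    scale-normalised LoG response there, ``radius`` the physical radius
    estimate derived from that scale, and ``response`` the value of the
    LoG scale-space maximum-intensity projection at the position.
    """

    position: tuple[int, ...]
    scale: float
    radius: float
    response: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", tuple(int(p) for p in self.position))
        if self.radius <= 0:
            raise ValueError(f"radius must be positive, got {self.radius}")


@dataclass
class TwangParams:
    """Parameters of the segmentation pipeline.

    The scale triplet (``sigma_min``, ``sigma_max``, ``sigma_step``) spans
    the LoG scale range used for seed detection; ``gradient_sigma`` is the
    standard deviation of the Gaussian used to smooth the image before
    taking gradients; ``kernel_multiplier`` scales the plateau radius of
    the distance-weighting kernel and ``kernel_sigma`` controls its
    Gaussian falloff.  All sigmas are physical units (voxels under unit
    spacing).  Defaults follow the 3D light-sheet parameterisation.
    """

    sigma_min: float = 6.0
    sigma_max: float = 9.0
    sigma_step: float = 3.0
    gradient_sigma: float = 3.0
    kernel_multiplier: float = 1.5
    kernel_sigma: float = 3.0
    seed_intensity_threshold: float = 0.0
    fusion_distance: float | None = None
    connectivity: int | None = None  # None -> full connectivity for ndim

    def __post_init__(self) -> None:
        if self.sigma_min > self.sigma_max:
            raise ValueError("sigma_min must not exceed sigma_max")
        if self.sigma_step <= 0:
            raise ValueError("sigma_step must be positive")
        for name in ("sigma_min", "gradient_sigma", "kernel_multiplier", "kernel_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class LabelImage:
    """An n-D non-negative integer label image; 0 is background."""

    labels: np.ndarray
    spacing: tuple[float, ...]

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if not np.issubdtype(labels.dtype, np.integer):
            raise ValueError(f"labels must be integer, got dtype {labels.dtype}")
        if labels.min(initial=0) < 0:
            raise ValueError("labels must be non-negative")
        object.__setattr__(self, "labels", labels)
        spacing = tuple(float(s) for s in self.spacing)
        object.__setattr__(self, "spacing", spacing)
        if len(spacing) != labels.ndim or any(s <= 0 for s in spacing):
            raise ValueError(f"invalid spacing {spacing} for {labels.ndim}D labels")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape

    def label_values(self) -> np.ndarray:
        vals = np.unique(self.labels)
        return vals[vals > 0]


def _tiff_spacing(tif: tifffile.TiffFile, ndim: int) -> tuple[float, ...] | None:
    """Extract per-axis spacing from TIFF resolution tags, if present."""
    page = tif.pages[0]
    tags = page.tags
    xres = tags.get("XResolution")
    yres = tags.get("YResolution")
    if xres is None or yres is None:
        return None

    def _to_spacing(value) -> float | None:
        num, den = value
        if num == 0:
            return None
        return den / num  # resolution is voxels per unit -> invert

    sx = _to_spacing(xres.value)
    sy = _to_spacing(yres.value)
    if sx is None or sy is None:
        return None
    if ndim == 2:
        return (sy, sx)
    sz = 1.0
    if tif.imagej_metadata and "spacing" in tif.imagej_metadata:
        sz = float(tif.imagej_metadata["spacing"])
    return (sz, sy, sx)


def read_volume(
    path: str | Path, spacing_override: Sequence[float] | None = None
) -> Volume:
    """Read a single- or multi-page TIFF into a :class:`Volume`.

    Spacing precedence: explicit ``spacing_override`` > TIFF resolution
    metadata > unit spacing (with a warning).  A multi-page file becomes a
    3D volume with the page axis first.
    """
    path = Path(path)
    try:
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            if data.ndim not in (2, 3):
                raise ValueError(
                    f"{path}: expected a 2D or 3D TIFF, got shape {data.shape}"
                )
            meta_spacing = _tiff_spacing(tif, data.ndim)
    except (OSError, tifffile.TiffFileError) as exc:
        raise IOError(f"cannot read TIFF {path}: {exc}") from exc

    if spacing_override is not None:
        spacing = tuple(float(s) for s in spacing_override)
    elif meta_spacing is not None:
        spacing = meta_spacing
    else:
        spacing = (1.0,) * data.ndim
        logger.warning(
            "%s: no spacing metadata and no override; assuming unit spacing", path
        )
    return Volume(data, spacing)


def write_volume(volume: Volume, path: str | Path) -> None:
    """Write a volume to a (multi-page) TIFF, preserving dtype."""
    tifffile.imwrite(Path(path), volume.data)


def write_label_image(labels: LabelImage, path: str | Path) -> None:
    """Write a label image as a 16-bit TIFF (errors if >65535 labels)."""
    max_label = int(labels.labels.max(initial=0))
    if max_label > 65535:
        raise OverflowError(
            f"label image has max label {max_label}, exceeding 16-bit TIFF range"
        )
    tifffile.imwrite(Path(path), labels.labels.astype(np.uint16))


def read_label_image(
    path: str | Path, spacing_override: Sequence[float] | None = None
) -> LabelImage:
    vol = read_volume(path, spacing_override)
    return LabelImage(np.asarray(vol.data).astype(np.int64), vol.spacing)


_AXIS_NAMES = {2: ("y", "x"), 3: ("z", "y", "x")}


def write_seeds_csv(seeds: Iterable[SeedPoint], path: str | Path, ndim: int = 3) -> None:
    """Write seed points to CSV: id, per-axis position, scale, radius, response."""
    seeds = list(seeds)
    if seeds:
        ndim = len(seeds[0].position)
    axes = _AXIS_NAMES[ndim]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", *axes, "scale", "radius", "response"])
        for i, seed in enumerate(seeds):
            writer.writerow(
                [i, *seed.position, seed.scale, seed.radius, seed.response]
            )


def read_seeds_csv(path: str | Path) -> list[SeedPoint]:
    seeds = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return []
        axes = [a for a in ("z", "y", "x") if a in reader.fieldnames]
        for row in reader:
            seeds.append(
                SeedPoint(
                    position=tuple(int(row[a]) for a in axes),
                    scale=float(row["scale"]),
                    radius=float(row["radius"]),
                    response=float(row["response"]),
                )
            )
    return seeds


def write_regionprops_csv(segments: Iterable, path: str | Path, ndim: int = 3) -> None:
    """Write per-segment region properties to CSV.

    Columns: id, physical centroid per axis, volume_voxels, volume_physical,
    mean_intensity, bounding box min/max per axis, otsu_threshold.
    """
    segments = [s for s in segments if s is not None]
    if segments:
        ndim = len(segments[0].offset)
    axes = _AXIS_NAMES[ndim]
    header = (
        ["id"]
        + [f"centroid_{a}" for a in axes]
        + ["volume_voxels", "volume_physical", "mean_intensity"]
        + [f"bbox_min_{a}" for a in axes]
        + [f"bbox_max_{a}" for a in axes]
        + ["otsu_threshold"]
    )
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for seg in segments:
            bbox_min, bbox_max = seg.bbox
            writer.writerow(
                [
                    seg.seed_id,
                    *seg.centroid,
                    seg.volume_voxels,
                    seg.volume_physical,
                    seg.mean_intensity,
                    *bbox_min,
                    *bbox_max,
                    seg.otsu_threshold,
                ]
            )
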