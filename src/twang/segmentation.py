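"""Per-seed TWANG segmentation.

TWANG (Threshold of Weighted intensity And seed-Normal Gradient dot
product image) turns the hard problem of separating densely packed
nuclei into many easy, independent thresholding problems.  For each
detected seed point a region is cropped from the raw image and
transformed so that voxels belonging to the seed's own nucleus keep
their intensity, while voxels on neighbouring nuclei or background are
suppressed — after which plain Otsu thresholding separates the nucleus.

The transform combines two cues:

* **Gradient direction.** On the boundary of a bright nucleus the image
  gradient points inward, i.e. opposite the unit normal from the seed to
  the voxel.  The transformed dot product
  ``psi = (1 - <n, g/|g|>) / 2`` therefore scores 1 on the seed's own
  boundary, 0.5 for perpendicular gradients, and 0 on the near edge of a
  neighbouring nucleus (whose gradient points away from the seed).  psi
  is contrast invariant.
* **Distance.** A plateau-Gaussian kernel keeps full weight within a
  scaled seed-radius plateau and decays as a Gaussian beyond it.

The combined image copies raw intensities within the seed radius and
multiplies the rest by ``w * psi``.  Because each nucleus is extracted
from its own crop as the connected component containing the seed, merged
segments cannot occur by construction.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from joblib import Parallel, delayed
from scipy import ndimage

from .seed_detection import _separable_gaussian
from .volume_io import LabelImage, SeedPoint, TwangParams, Volume

logger = logging.getLogger(__name__)

__all__ = [
    "CropRegion",
    "SegmentCandidate",
    "crop_region",
    "smoothed_gradient",
    "seed_normal_field",
    "dot_product_transform",
    "weighting_kernel",
    "combine_images",
    "otsu_threshold",
    "extract_segment",
    "segment_all",
    "assemble_label_image",
]


@dataclass(frozen=True)
class CropRegion:
    """A sub-volume of raw intensities around one seed."""

    data: np.ndarray
    offset: tuple[int, ...]
    seed_local: tuple[int, ...]
    spacing: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(
            not (0 <= s < n) for s, n in zip(self.seed_local, self.data.shape)
        ):
            raise ValueError(
                f"seed_local {self.seed_local} outside crop of shape {self.data.shape}"
            )


@dataclass(frozen=True)
class SegmentCandidate:
    """One seed's extracted nucleus mask and region properties."""

    seed_id: int
    offset: tuple[int, ...]
    mask: np.ndarray
    otsu_threshold: float
    centroid: tuple[float, ...]  # physical units, full-image frame
    volume_voxels: int
    volume_physical: float
    mean_intensity: float
    bbox: tuple[tuple[int, ...], tuple[int, ...]]  # (min, max) inclusive, full frame


def crop_region(volume: Volume, seed: SeedPoint) -> CropRegion:
    """Crop a cuboid of physical half-width ``2 * seed.radius`` per axis.

    The side length of 4r guarantees the weighting kernel's plateau
    (multiplier <= 1.5) and most of its Gaussian tail lie inside the crop.
    Clamped to image bounds at the borders.
    """
    shape = volume.shape
    half = [
        int(math.ceil(2.0 * seed.radius / s)) for s in volume.spacing
    ]
    lo = [max(0, p - h) for p, h in zip(seed.position, half)]
    hi = [min(n, p + h + 1) for p, h, n in zip(seed.position, half, shape)]
    slices = tuple(slice(a, b) for a, b in zip(lo, hi))
    data = volume.data[slices].astype(np.float64, copy=True)
    seed_local = tuple(p - a for p, a in zip(seed.position, lo))
    return CropRegion(
        data=data, offset=tuple(lo), seed_local=seed_local, spacing=volume.spacing
    )


def smoothed_gradient(crop: CropRegion, gradient_sigma: float = 3.0) -> np.ndarray:
    """Gaussian-smoothed intensity gradient in physical units.

    Returns an array of shape ``(ndim, *crop.shape)``; component ``a`` is
    the derivative along axis ``a`` of the smoothed crop, divided by the
    spacing of that axis so the vectors live in physical space.
    """
    if gradient_sigma <= 0:
        raise ValueError("gradient_sigma must be positive")
    voxel_sigma = tuple(gradient_sigma / s for s in crop.spacing)
    grad = np.empty((crop.data.ndim, *crop.data.shape))
    for axis in range(crop.data.ndim):
        orders = [0] * crop.data.ndim
        orders[axis] = 1
        grad[axis] = (
            _separable_gaussian(crop.data, voxel_sigma, orders)
            / crop.spacing[axis]
        )
    return grad


def seed_normal_field(crop: CropRegion) -> tuple[np.ndarray, np.ndarray]:
    """Unit normals from the seed to every voxel, plus physical distances.

    The displacement is the Hadamard product of the index offset with the
    voxel spacing.  At the seed voxel itself the normal is undefined and
    stored as the zero vector (it lies inside the copy-through radius and
    never influences the output).
    """
    ndim = crop.data.ndim
    grids = np.indices(crop.data.shape, dtype=np.float64)
    d = np.empty_like(grids)
    for axis in range(ndim):
        d[axis] = (grids[axis] - crop.seed_local[axis]) * crop.spacing[axis]
    dist = np.sqrt((d**2).sum(axis=0))
    normals = np.zeros_like(d)
    nonzero = dist > 0
    for axis in range(ndim):
        normals[axis][nonzero] = d[axis][nonzero] / dist[nonzero]
    return normals, dist


def dot_product_transform(normals: np.ndarray, gradients: np.ndarray) -> np.ndarray:
    """Transformed dot product ``psi = (1 - <n, g/|g|>) / 2`` in [0, 1].

    Gradients anti-parallel to the outward seed normal (as on the seed's
    own bright-object boundary) score 1; perpendicular 0.5; parallel
    (a neighbouring cell's near edge) 0.  Zero gradients and the zero
    normal at the seed voxel score a neutral 0.5.
    """
    gnorm = np.sqrt((gradients**2).sum(axis=0))
    nnorm = np.sqrt((normals**2).sum(axis=0))
    valid = (gnorm > 0) & (nnorm > 0)
    cos = np.zeros_like(gnorm)
    dot = (normals * gradients).sum(axis=0)
    cos[valid] = dot[valid] / gnorm[valid]
    psi = (1.0 - cos) / 2.0
    psi[~valid] = 0.5
    return np.clip(psi, 0.0, 1.0)


def weighting_kernel(
    distances: np.ndarray,
    radius: float,
    kernel_multiplier: float = 1.5,
    kernel_sigma: float = 3.0,
) -> np.ndarray:
    """Plateau-Gaussian distance weighting in (0, 1].

    Weight 1 within the plateau ``|d| <= m * radius`` and Gaussian decay
    ``exp(-(|d| - m*r)**2 / (2 * sigma_w**2))`` beyond it.
    """
    if radius <= 0 or kernel_multiplier <= 0 or kernel_sigma <= 0:
        raise ValueError("radius, kernel_multiplier and kernel_sigma must be positive")
    plateau = kernel_multiplier * radius
    excess = np.maximum(distances - plateau, 0.0)
    return np.exp(-(excess**2) / (2.0 * kernel_sigma**2))


def combine_images(
    crop: CropRegion,
    psi: np.ndarray,
    weights: np.ndarray,
    seed_radius: float,
    distances: np.ndarray | None = None,
) -> np.ndarray:
    """Copy raw intensities within the seed radius; weight the rest.

    ``combined(x) = I(x)`` when ``|d(x)| <= seed_radius``, else
    ``I(x) * w(x) * psi(x)``.
    """
    if distances is None:
        _, distances = seed_normal_field(crop)
    combined = crop.data * weights * psi
    inside = distances <= seed_radius
    combined[inside] = crop.data[inside]
    return combined


N_OTSU_BINS = 256


def otsu_threshold(values: np.ndarray) -> tuple[float, bool]:
    """Otsu's threshold over a 256-bin histogram of the field's range.

    Returns ``(threshold, degenerate)``; foreground is ``values >
    threshold``.  A constant field is degenerate: the threshold equals
    the constant and the foreground is empty.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    if values.size == 0:
        raise ValueError("cannot threshold an empty field")
    vmin, vmax = values.min(), values.max()
    if vmin == vmax:
        return float(vmin), True
    counts, edges = np.histogram(values, bins=N_OTSU_BINS, range=(vmin, vmax))
    counts = counts.astype(np.float64)
    # Between-class variance w0*w1*(mu0-mu1)^2 at every bin boundary;
    # candidate thresholds are the upper edges of bins 0..254.
    centers = (edges[:-1] + edges[1:]) / 2.0
    w0 = np.cumsum(counts)[:-1]
    w1 = counts.sum() - w0
    m0 = np.cumsum(counts * centers)[:-1]
    m1 = (counts * centers).sum() - m0
    valid = (w0 > 0) & (w1 > 0)
    var_between = np.zeros(N_OTSU_BINS - 1)
    var_between[valid] = (
        w0[valid] * w1[valid] * (m0[valid] / w0[valid] - m1[valid] / w1[valid]) ** 2
    )
    # Empty bins between the classes give a plateau of equal variance;
    # take the first index within rounding error of the maximum so ties
    # break toward the smaller threshold regardless of summation order.
    vmax = var_between.max()
    best = int(np.argmax(var_between >= vmax * (1.0 - 1e-10)))
    return float(edges[best + 1]), False


def extract_segment(
    combined: np.ndarray,
    crop: CropRegion,
    seed: SeedPoint,
    seed_id: int,
    connectivity: int | None = None,
) -> SegmentCandidate | None:
    """Binarise the combined image and keep the seed's connected component.

    Foreground is ``combined > otsu``; of the foreground components (full
    connectivity by default) the one containing the seed voxel is kept.
    If the seed voxel itself fell below threshold, the nearest foreground
    component within the seed radius is used instead.  Properties are
    computed on the raw intensities under the mask; returns None when no
    component can be attributed to the seed.
    """
    threshold, degenerate = otsu_threshold(combined)
    if degenerate:
        logger.debug("seed %d: degenerate (constant) combined image", seed_id)
        return None
    foreground = combined > threshold
    if not foreground.any():
        logger.debug("seed %d: empty foreground", seed_id)
        return None
    structure = _structure_from_connectivity(combined.ndim, connectivity)
    labeled, _ = ndimage.label(foreground, structure=structure)
    comp = labeled[crop.seed_local]
    if comp == 0:
        # nearest foreground voxel (physical distance) within seed radius
        _, dist = seed_normal_field(crop)
        dist_fg = np.where(foreground, dist, np.inf)
        nearest = np.unravel_index(np.argmin(dist_fg), dist_fg.shape)
        if dist_fg[nearest] > seed.radius:
            logger.debug("seed %d: no foreground within seed radius", seed_id)
            return None
        comp = labeled[nearest]
    mask = labeled == comp

    idx = np.nonzero(mask)
    n_vox = int(mask.sum())
    voxel_volume = float(np.prod(crop.spacing))
    centroid = tuple(
        float((idx[a].mean() + crop.offset[a]) * crop.spacing[a])
        for a in range(mask.ndim)
    )
    bbox_min = tuple(int(idx[a].min() + crop.offset[a]) for a in range(mask.ndim))
    bbox_max = tuple(int(idx[a].max() + crop.offset[a]) for a in range(mask.ndim))
    return SegmentCandidate(
        seed_id=seed_id,
        offset=crop.offset,
        mask=mask,
        otsu_threshold=threshold,
        centroid=centroid,
        volume_voxels=n_vox,
        volume_physical=n_vox * voxel_volume,
        mean_intensity=float(crop.data[mask].mean()),
        bbox=(bbox_min, bbox_max),
    )


def _structure_from_connectivity(ndim: int, connectivity: int | None) -> np.ndarray:
    """Full connectivity (8 in 2D, 26 in 3D) unless a face-connectivity
    neighbourhood (4/6) was explicitly requested."""
    if connectivity in (4, 6):
        return ndimage.generate_binary_structure(ndim, 1)
    return np.ones((3,) * ndim, dtype=bool)


def segment_seed(
    volume: Volume, seed: SeedPoint, seed_id: int, params: TwangParams
) -> SegmentCandidate | None:
    """Run the full per-seed transform chain for one seed."""
    crop = crop_region(volume, seed)
    if crop.data.max() == crop.data.min():
        # flat crop: no object, nothing to threshold
        logger.debug("seed %d: constant crop, discarded", seed_id)
        return None
    gradients = smoothed_gradient(crop, params.gradient_sigma)
    normals, distances = seed_normal_field(crop)
    psi = dot_product_transform(normals, gradients)
    weights = weighting_kernel(
        distances, seed.radius, params.kernel_multiplier, params.kernel_sigma
    )
    combined = combine_images(crop, psi, weights, seed.radius, distances)
    return extract_segment(combined, crop, seed, seed_id, params.connectivity)


def _segment_one_safe(volume, seed, seed_id, params):
    try:
        return segment_seed(volume, seed, seed_id, params)
    except Exception:  # one failing seed must not abort the batch
        logger.exception("seed %d failed", seed_id)
        return None


def segment_all(
    volume: Volume,
    seeds: list[SeedPoint],
    params: TwangParams,
    workers: int = 1,
) -> list[SegmentCandidate | None]:
    """Segment every seed independently; seeds are distributed over workers.

    Returns one slot per seed (None where the seed yielded no segment),
    ordered by seed id.  The result is bit-identical for any worker
    count: each seed's computation touches only its own crop.
    """
    if not seeds:
        return []
    volume = volume.astype_float()
    if workers <= 1:
        return [
            _segment_one_safe(volume, seed, i, params) for i, seed in enumerate(seeds)
        ]
    results = Parallel(n_jobs=workers, prefer="threads")(
        delayed(_segment_one_safe)(volume, seed, i, params)
        for i, seed in enumerate(seeds)
    )
    return list(results)


def assemble_label_image(
    segments: list[SegmentCandidate | None],
    shape: tuple[int, ...],
    spacing: tuple[float, ...],
    seeds: list[SeedPoint] | None = None,
) -> LabelImage:
    """Paint segment masks into one label image; label = seed_id + 1.

    Where masks overlap, a voxel goes to the seed physically closest to
    it (ties to the smaller seed id), so every labelled region maps to
    exactly one seed — no merged segments can arise by construction.
    """
    labels = np.zeros(shape, dtype=np.int32)
    best_dist = np.full(shape, np.inf)
    spacing_arr = np.asarray(spacing)
    for seg in segments:
        if seg is None:
            continue
        slices = tuple(
            slice(o, o + s) for o, s in zip(seg.offset, seg.mask.shape)
        )
        idx = np.nonzero(seg.mask)
        coords = np.stack(
            [(idx[a] + seg.offset[a]) * spacing_arr[a] for a in range(len(shape))],
            axis=1,
        )
        if seeds is not None:
            seed_pos = np.asarray(seeds[seg.seed_id].position) * spacing_arr
        else:
            seed_pos = np.asarray(seg.centroid)
        d = np.sqrt(((coords - seed_pos) ** 2).sum(axis=1))
        sub_labels = labels[slices]
        sub_best = best_dist[slices]
        # strict < : earlier (smaller seed_id) segment wins distance ties
        win = d < sub_best[idx]
        sub_labels[idx] = np.where(win, seg.seed_id + 1, sub_labels[idx])
        sub_best[idx] = np.where(win, d, sub_best[idx])
    return LabelImage(labels, tuple(spacing))
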