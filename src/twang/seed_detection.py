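"""Nucleus seed detection via a LoG scale-space maximum-intensity projection.

Blobs (stained nuclei) are detected with a scale-normalised
Laplacian-of-Gaussian filter evaluated over a small discrete set of
scales.  Instead of holding the whole scale stack in memory and searching
for extrema across space *and* scale, the responses are folded
iteratively into a single per-voxel maximum image (the scale-space MIP)
together with a per-voxel record of the scale that attained the maximum.
Seed extraction then reduces to local-extrema detection in the direct
8/26-neighbourhood of the MIP, followed by fusion of close maxima and an
intensity threshold that discards dark seeds on the background.

The filter is isotropic in physical space: for voxel spacing ``h_a``
along axis ``a``, the Gaussian standard deviation in voxel units is
``sigma / h_a``.  Responses are negated and multiplied by ``sigma**2``
(t-normalisation) so that bright blobs of radius ``sigma * sqrt(d)``
produce positive maxima comparable across scales.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_io import SeedPoint, TwangParams, Volume

__all__ = [
    "ScaleSpaceResult",
    "log_filter",
    "scale_space_mip",
    "build_scales",
    "radius_from_scale",
    "detect_seeds",
]

# Gaussian kernels are truncated at 4 sigma with mirror boundary handling;
# oracle tests rely on the same settings.
GAUSS_TRUNCATE = 4.0
GAUSS_MODE = "mirror"

# Effective voxel-space sigma below this is unresolvable on the grid.
MIN_VOXEL_SIGMA = 0.3


@dataclass(frozen=True)
class ScaleSpaceResult:
    """LoG scale-space MIP with per-voxel argmax-scale bookkeeping."""

    mip: Volume
    scale_map: Volume
    scales: tuple[float, ...]


def log_filter(volume: Volume, sigma: float) -> Volume:
    """Scale-normalised negated LoG response of ``volume`` at scale ``sigma``.

    ``sigma`` is a physical length; the per-axis voxel-space standard
    deviation is ``sigma / spacing``.  Bright blobs yield positive maxima.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    voxel_sigma = tuple(sigma / s for s in volume.spacing)
    if min(voxel_sigma) < MIN_VOXEL_SIGMA:
        raise ValueError(
            f"sigma={sigma} gives voxel-space std. dev. {voxel_sigma} below "
            f"{MIN_VOXEL_SIGMA} on at least one axis; filter unresolvable"
        )
    data = volume.data.astype(np.float64, copy=False)
    # Separable filtering with explicit kernels; differentiation happens in
    # voxel units and is rescaled per axis to physical units.
    response = np.zeros_like(data)
    for axis in range(data.ndim):
        orders = [0] * data.ndim
        orders[axis] = 2
        d2 = _separable_gaussian(data, voxel_sigma, orders)
        response += d2 / volume.spacing[axis] ** 2
    response *= -(sigma**2)
    return Volume(response, volume.spacing)


def _gauss_kernel1d(sigma: float, order: int) -> np.ndarray:
    """Sampled Gaussian (derivative) kernel, truncated at 4 sigma.

    The second-derivative kernel is corrected to sum exactly to zero so
    constant and affine images produce an exactly zero LoG response
    despite truncation.
    """
    radius = max(1, int(GAUSS_TRUNCATE * sigma + 0.5))
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    phi = np.exp(-0.5 * (x / sigma) ** 2)
    phi /= phi.sum()
    if order == 0:
        return phi
    if order == 1:
        k = -(x / sigma**2) * phi  # sums to zero exactly by antisymmetry
        return k / -(k * x).sum()  # unit response to a unit ramp
    if order == 2:
        k = ((x**2 - sigma**2) / sigma**4) * phi
        k -= k.sum() / k.size  # zero response to constants
        return k / ((k * x**2).sum() / 2.0)  # exact curvature of quadratics
    raise ValueError(f"unsupported derivative order {order}")


def _separable_gaussian(
    data: np.ndarray, sigmas: tuple[float, ...], orders: list[int]
) -> np.ndarray:
    out = data
    for axis, (s, o) in enumerate(zip(sigmas, orders)):
        kernel = _gauss_kernel1d(s, o)
        # correlate1d with the reversed kernel == convolution; matters only
        # for the antisymmetric first-derivative kernel
        out = ndimage.correlate1d(out, kernel[::-1], axis=axis, mode=GAUSS_MODE)
    return out


def build_scales(sigma_min: float, sigma_max: float, sigma_step: float) -> list[float]:
    """Arithmetic scale progression from ``sigma_min`` to ``sigma_max``.

    Always includes ``sigma_min``; ``sigma_max`` is appended if the step
    does not hit it exactly.
    """
    if sigma_min > sigma_max:
        raise ValueError("sigma_min must not exceed sigma_max")
    if sigma_step <= 0:
        raise ValueError("sigma_step must be positive")
    scales = []
    k = 0
    while True:
        s = sigma_min + k * sigma_step
        if s > sigma_max + 1e-12:
            break
        scales.append(float(s))
        k += 1
    if not math.isclose(scales[-1], sigma_max, rel_tol=1e-12, abs_tol=1e-12):
        scales.append(float(sigma_max))
    return scales


def radius_from_scale(sigma: float, ndim: int) -> float:
    """Physical blob radius for a LoG response maximal at scale ``sigma``.

    A solid bright d-dimensional ball of radius r maximises the
    t-normalised LoG centre response at sigma = r / sqrt(d), hence
    r = sigma * sqrt(d).
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    if ndim not in (2, 3):
        raise ValueError(f"ndim must be 2 or 3, got {ndim}")
    return sigma * math.sqrt(ndim)


def scale_space_mip(volume: Volume, scales: list[float]) -> ScaleSpaceResult:
    """Fold LoG responses over ``scales`` into a max/argmax image pair.

    Computed iteratively so at most two full response volumes are resident
    at any time.  Ties go to the first (smallest) scale.
    """
    if not scales:
        raise ValueError("scales must be non-empty")
    if any(b <= a for a, b in zip(scales, scales[1:])):
        raise ValueError(f"scales must be strictly increasing, got {scales}")
    mip = log_filter(volume, scales[0]).data
    scale_map = np.full(volume.shape, scales[0], dtype=np.float64)
    for sigma in scales[1:]:
        response = log_filter(volume, sigma).data
        better = response > mip  # strict: first scale wins ties
        mip = np.where(better, response, mip)
        scale_map[better] = sigma
    return ScaleSpaceResult(
        mip=Volume(mip, volume.spacing),
        scale_map=Volume(scale_map, volume.spacing),
        scales=tuple(scales),
    )


def _local_maxima(mip: np.ndarray) -> np.ndarray:
    """Boolean mask of local maxima over the full direct neighbourhood.

    A voxel qualifies if it is >= all neighbours and > at least one;
    within a connected plateau of qualifying equal-valued voxels only the
    lexicographically smallest index is kept (deterministic tie-break).
    """
    footprint = np.ones((3,) * mip.ndim, dtype=bool)
    footprint[(1,) * mip.ndim] = False
    nbr_max = ndimage.maximum_filter(mip, footprint=footprint, mode="nearest")
    nbr_min = ndimage.minimum_filter(mip, footprint=footprint, mode="nearest")
    candidates = (mip >= nbr_max) & (mip > nbr_min)
    if not candidates.any():
        return candidates
    # Adjacent candidates necessarily share the same value (each >= the
    # other); collapse each plateau to its first voxel in scan order.
    labeled, n = ndimage.label(candidates, structure=np.ones((3,) * mip.ndim))
    if n == int(candidates.sum()):
        return candidates
    keep = np.zeros_like(candidates)
    first_idx = ndimage.minimum_position(
        np.arange(mip.size).reshape(mip.shape), labeled, index=range(1, n + 1)
    )
    for idx in first_idx:
        keep[tuple(idx)] = True
    return keep


def _fuse_seeds(
    seeds: list[SeedPoint], spacing: tuple[float, ...], fusion_distance: float
) -> list[SeedPoint]:
    """Greedy fusion: strongest response wins within ``fusion_distance``."""
    # Position is the secondary key so equal responses break ties reproducibly.
    order = sorted(seeds, key=lambda s: (-s.response, s.position))
    spacing_arr = np.asarray(spacing)
    accepted: list[SeedPoint] = []
    accepted_pos = np.empty((0, len(spacing)))
    for seed in order:
        pos = np.asarray(seed.position) * spacing_arr
        if accepted_pos.size:
            d = np.sqrt(((accepted_pos - pos) ** 2).sum(axis=1))
            if (d <= fusion_distance).any():
                continue
        accepted.append(seed)
        accepted_pos = np.vstack([accepted_pos, pos])
    accepted.sort(key=lambda s: s.position)
    return accepted


def detect_seeds(ss: ScaleSpaceResult, params: TwangParams) -> list[SeedPoint]:
    """Extract seed points from a scale-space MIP.

    Strict local maxima of the MIP above ``seed_intensity_threshold`` are
    fused so that any two surviving seeds are separated by more than
    ``fusion_distance`` in physical units (default: the radius implied by
    the smallest scale).  Each seed carries the argmax scale at its
    position and the radius derived from it.
    """
    mip = ss.mip.data
    ndim = mip.ndim
    maxima = _local_maxima(mip)
    maxima &= mip > params.seed_intensity_threshold
    positions = np.argwhere(maxima)
    seeds = [
        SeedPoint(
            position=tuple(int(c) for c in pos),
            scale=float(ss.scale_map.data[tuple(pos)]),
            radius=radius_from_scale(float(ss.scale_map.data[tuple(pos)]), ndim),
            response=float(mip[tuple(pos)]),
        )
        for pos in positions
    ]
    fusion_distance = params.fusion_distance
    if fusion_distance is None:
        fusion_distance = radius_from_scale(params.sigma_min, ndim)
    if fusion_distance > 0 and len(seeds) > 1:
        seeds = _fuse_seeds(seeds, ss.mip.spacing, fusion_distance)
    return seeds


def detect_seeds_from_volume(
    volume: Volume, params: TwangParams
) -> tuple[list[SeedPoint], ScaleSpaceResult]:
    """Convenience wrapper: scale-space MIP then seed extraction."""
    scales = build_scales(params.sigma_min, params.sigma_max, params.sigma_step)
    ss = scale_space_mip(volume.astype_float(), scales)
    return detect_seeds(ss, params), ss
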