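"""Synthetic fluorescent-nuclei phantoms with ground-truth labels.

Generates 2D/3D images of roundish nuclei (disks/spheres) with
configurable radius range, clustering probability, PSF blur, noise and
anisotropic voxel spacing.  The phantoms emulate the character of
simulated nucleus benchmarks — clustered objects at low signal-to-noise
ratio — so the whole pipeline can be validated without any external
downloads.  Texture and optical-sectioning physics are deliberately not
modelled: spheres at the configured SNR are sufficient to exercise every
operator.

Ground truth is the pre-blur geometry: labels are rasterised before the
point-spread-function blur and noise are applied, matching how simulated
benchmarks pair sharp labels with blurred images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .volume_io import LabelImage, SeedPoint, Volume

__all__ = ["PhantomSpec", "PhantomTruth", "generate_phantom", "fig2_style_fixture"]


@dataclass(frozen=True)
class PhantomSpec:
    """Specification of one synthetic nuclei image.

    ``clustering_probability`` is the fraction of nuclei placed touching
    or nearly touching an existing nucleus (centre distance 0.8-1.2 of
    the radius sum); the rest are isolated (distance > 1.5 of the radius
    sum from every other nucleus).  ``noise_sigma`` is additive Gaussian
    read noise; ``poisson`` switches on shot noise on the blurred signal.
    """

    shape: tuple[int, ...] = (60, 150, 150)
    spacing: tuple[float, ...] = (1.0, 1.0, 1.0)
    n_nuclei: int = 20
    radius_range: tuple[float, float] = (6.0, 9.0)
    clustering_probability: float = 0.75
    intensity_fg: float = 200.0
    intensity_bg: float = 20.0
    psf_sigma: float = 1.0
    noise_sigma: float = 20.0
    poisson: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if len(self.shape) != len(self.spacing):
            raise ValueError("shape and spacing must have the same length")
        if self.radius_range[0] > self.radius_range[1]:
            raise ValueError("radius_range must be (min, max) with min <= max")
        if not 0.0 <= self.clustering_probability <= 1.0:
            raise ValueError("clustering_probability must be in [0, 1]")
        if self.intensity_fg <= self.intensity_bg or self.intensity_bg < 0:
            raise ValueError("need intensity_fg > intensity_bg >= 0")


@dataclass(frozen=True)
class PhantomTruth:
    """Ground truth for one phantom: labels, centroids and radii.

    ``centroids`` are physical coordinates; ``snr`` is the measured
    (mean foreground - mean background) / background std of the final
    image, recorded so tests can condition on the realised noise level.
    """

    labels: LabelImage
    centroids: np.ndarray  # (n, ndim), physical units
    radii: np.ndarray  # (n,), physical units
    snr: float


_MAX_ATTEMPTS = 5000


def _place_centres(
    spec: PhantomSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample nucleus centres (physical coords) and radii."""
    extent = np.asarray(spec.shape) * np.asarray(spec.spacing)
    centres: list[np.ndarray] = []
    radii: list[float] = []
    for i in range(spec.n_nuclei):
        r = float(rng.uniform(*spec.radius_range))
        clustered = bool(centres) and rng.random() < spec.clustering_probability
        placed = False
        for _ in range(_MAX_ATTEMPTS):
            if clustered:
                j = int(rng.integers(len(centres)))
                pair_dist = float(rng.uniform(0.8, 1.2)) * (radii[j] + r)
                direction = rng.normal(size=len(spec.shape))
                direction /= np.linalg.norm(direction)
                c = centres[j] + pair_dist * direction
            else:
                # keep the object (and some blur margin) inside the image
                margin = r + 2 * spec.psf_sigma
                if np.any(extent <= 2 * margin):
                    raise ValueError("image too small for the requested radii")
                c = rng.uniform(margin, extent - margin)
            if np.any(c < r) or np.any(c > extent - r):
                continue
            ok = True
            for k, (ck, rk) in enumerate(zip(centres, radii)):
                d = float(np.linalg.norm(c - ck))
                limit = (0.8 if clustered and k == j else 1.5) * (rk + r)
                if clustered and k == j:
                    ok = 0.8 * (rk + r) <= d  # the chosen partner: near-touching
                else:
                    # non-partners must stay clear in both placement modes
                    ok = d > (1.2 if clustered else 1.5) * (rk + r)
                if not ok:
                    break
            if ok:
                centres.append(c)
                radii.append(r)
                placed = True
                break
        if not placed:
            raise RuntimeError(
                f"could not place nucleus {i + 1}/{spec.n_nuclei}; "
                f"placed {len(centres)} before giving up"
            )
    return np.asarray(centres), np.asarray(radii)


def _rasterise(
    spec: PhantomSpec, centres: np.ndarray, radii: np.ndarray
) -> np.ndarray:
    """Paint sphere labels; overlap voxels go to the nearest centre."""
    labels = np.zeros(spec.shape, dtype=np.int32)
    best = np.full(spec.shape, np.inf)
    spacing = np.asarray(spec.spacing)
    for i, (c, r) in enumerate(zip(centres, radii), start=1):
        lo = np.maximum(np.floor((c - r) / spacing).astype(int), 0)
        hi = np.minimum(np.ceil((c + r) / spacing).astype(int) + 1, spec.shape)
        slices = tuple(slice(a, b) for a, b in zip(lo, hi))
        grids = np.indices(tuple(hi - lo), dtype=np.float64)
        dist2 = np.zeros(tuple(hi - lo))
        for a in range(len(spec.shape)):
            dist2 += ((grids[a] + lo[a]) * spacing[a] - c[a]) ** 2
        dist = np.sqrt(dist2)
        inside = dist <= r
        sub_lab, sub_best = labels[slices], best[slices]
        win = inside & (dist < sub_best)
        sub_lab[win] = i
        sub_best[win] = dist[win]
    return labels


def generate_phantom(spec: PhantomSpec) -> tuple[Volume, PhantomTruth]:
    """Generate one phantom image with ground truth.

    Nuclei are uniform-radius spheres placed by rejection sampling, then
    painted at ``intensity_fg`` on an ``intensity_bg`` background,
    blurred with a Gaussian PSF of physical std ``psf_sigma`` and
    corrupted by the configured noise.  Fully reproducible from
    ``rng_seed``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    if spec.n_nuclei > 0:
        centres, radii = _place_centres(spec, rng)
        labels = _rasterise(spec, centres, radii)
    else:
        centres = np.empty((0, len(spec.shape)))
        radii = np.empty((0,))
        labels = np.zeros(spec.shape, dtype=np.int32)

    image = np.full(spec.shape, spec.intensity_bg, dtype=np.float64)
    image[labels > 0] = spec.intensity_fg
    if spec.psf_sigma > 0:
        voxel_sigma = tuple(spec.psf_sigma / s for s in spec.spacing)
        image = ndimage.gaussian_filter(image, sigma=voxel_sigma, mode="mirror")
    if spec.poisson:
        image = rng.poisson(np.maximum(image, 0)).astype(np.float64)
    if spec.noise_sigma > 0:
        image = image + rng.normal(0.0, spec.noise_sigma, size=spec.shape)

    fg = labels > 0
    bg = ~fg
    bg_std = float(image[bg].std()) if bg.any() else float("nan")
    if fg.any() and bg.any() and bg_std > 0:
        snr = float((image[fg].mean() - image[bg].mean()) / bg_std)
    else:
        snr = float("nan")
    return (
        Volume(image, spec.spacing),
        PhantomTruth(
            labels=LabelImage(labels, spec.spacing),
            centroids=centres,
            radii=radii,
            snr=snr,
        ),
    )


def fig2_style_fixture() -> tuple[Volume, SeedPoint, LabelImage]:
    """Deterministic 2D two-nucleus crop for pipeline walkthroughs.

    A central nucleus with a partially overlapping neighbour, plus a
    seed on the central one — the canonical hard case for thresholding
    (a plain Otsu would merge the pair).  Returns (image, seed, truth).
    """
    shape = (96, 96)
    spacing = (1.0, 1.0)
    centre_a = np.array([48.0, 40.0])
    centre_b = np.array([48.0, 70.0])  # centre distance 30 < r_a + r_b = 32
    r_a, r_b = 16.0, 16.0
    labels = np.zeros(shape, dtype=np.int32)
    grids = np.indices(shape, dtype=np.float64)
    d_a = np.sqrt(((grids[0] - centre_a[0])) ** 2 + (grids[1] - centre_a[1]) ** 2)
    d_b = np.sqrt(((grids[0] - centre_b[0])) ** 2 + (grids[1] - centre_b[1]) ** 2)
    labels[(d_b <= r_b)] = 2
    labels[(d_a <= r_a) & ((d_a <= d_b) | (d_b > r_b))] = 1
    # overlap voxels nearer to B stay with B
    labels[(d_b <= r_b) & (d_b < d_a)] = 2

    image = np.full(shape, 20.0)
    image[labels > 0] = 200.0
    image = ndimage.gaussian_filter(image, sigma=1.5, mode="mirror")
    rng = np.random.default_rng(42)
    image = image + rng.normal(0.0, 6.0, size=shape)

    seed = SeedPoint(
        position=(48, 40), scale=r_a / np.sqrt(2), radius=r_a, response=1.0
    )
    return Volume(image, spacing), seed, LabelImage(labels, spacing)
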