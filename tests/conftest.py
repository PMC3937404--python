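import numpy as np
import pytest

from twang import PhantomSpec, Volume, generate_phantom


def render_sphere(
    shape, center, radius, spacing=None, fg=200.0, bg=20.0
) -> np.ndarray:
    """Solid sphere/disk painted at fg on a bg background (no blur/noise)."""
    spacing = spacing or (1.0,) * len(shape)
    grids = np.indices(shape, dtype=np.float64)
    dist2 = np.zeros(shape)
    for a in range(len(shape)):
        dist2 += (grids[a] * spacing[a] - center[a]) ** 2
    img = np.full(shape, bg)
    img[dist2 <= radius**2] = fg
    return img


def render_gaussian_spot(
    shape, center, sigma0, amplitude=100.0, bg=0.0
) -> np.ndarray:
    grids = np.indices(shape, dtype=np.float64)
    dist2 = np.zeros(shape)
    for a in range(len(shape)):
        dist2 += (grids[a] - center[a]) ** 2
    return bg + amplitude * np.exp(-dist2 / (2.0 * sigma0**2))


@pytest.fixture(scope="session")
def sparse_phantom_3d():
    """30 well-separated spheres at high SNR in 3D."""
    spec = PhantomSpec(
        shape=(60, 180, 180),
        n_nuclei=30,
        radius_range=(5.0, 7.0),
        clustering_probability=0.0,
        noise_sigma=10.0,
        rng_seed=7,
    )
    return spec, *generate_phantom(spec)


@pytest.fixture(scope="session")
def clustered_phantom_3d():
    """Benchmark-style clustered phantom (default spec, 75% clustering)."""
    spec = PhantomSpec(rng_seed=3)
    return spec, *generate_phantom(spec)
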