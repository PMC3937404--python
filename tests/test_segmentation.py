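import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from conftest import render_sphere
from twang import (
    SeedPoint,
    TwangParams,
    Volume,
    assemble_label_image,
    combine_images,
    crop_region,
    dot_product_transform,
    extract_segment,
    otsu_threshold,
    seed_normal_field,
    segment_all,
    segment_seed,
    smoothed_gradient,
    weighting_kernel,
)
from twang.segmentation import CropRegion, SegmentCandidate


def _seed(position, radius, ndim=None):
    ndim = ndim or len(position)
    return SeedPoint(
        position=position, scale=radius / np.sqrt(ndim), radius=radius, response=1.0
    )


class TestCropRegion:
    def test_interior_crop_shape_is_4r_plus_one(self):
        vol = Volume(np.zeros((64, 64, 64)), (1.0, 1.0, 1.0))
        crop = crop_region(vol, _seed((32, 32, 32), 5.0))
        assert crop.data.shape == (21, 21, 21)
        assert crop.seed_local == (10, 10, 10)

    def test_corner_seed_is_clamped(self):
        vol = Volume(np.zeros((32, 32, 32)), (1.0, 1.0, 1.0))
        crop = crop_region(vol, _seed((0, 0, 0), 5.0))
        assert crop.offset == (0, 0, 0)
        assert crop.seed_local == (0, 0, 0)
        assert crop.data.shape == (11, 11, 11)

    def test_anisotropic_half_widths(self):
        vol = Volume(np.zeros((64, 64, 64)), (1.0, 1.0, 2.0))
        crop = crop_region(vol, _seed((32, 32, 32), 6.0))
        assert crop.data.shape == (25, 25, 13)  # half-widths (12, 12, 6)


class TestSmoothedGradient:
    def test_constant_crop_has_zero_gradient(self):
        crop = CropRegion(np.full((15, 15), 9.0), (0, 0), (7, 7), (1.0, 1.0))
        np.testing.assert_allclose(smoothed_gradient(crop, 3.0), 0.0, atol=1e-12)

    def test_ramp_gradient_matches_finite_difference_oracle(self):
        shape = (31, 31, 31)
        ramp = 2.0 * np.indices(shape, dtype=np.float64)[0]
        crop = CropRegion(ramp, (0, 0, 0), (15, 15, 15), (1.0, 1.0, 1.0))
        grad = smoothed_gradient(crop, 3.0)
        interior = (slice(14, 17),) * 3
        np.testing.assert_allclose(grad[0][interior], 2.0, atol=1e-3)
        np.testing.assert_allclose(grad[1][interior], 0.0, atol=1e-3)
        np.testing.assert_allclose(grad[2][interior], 0.0, atol=1e-3)
        # independent central-difference oracle on the smoothed image
        from twang.seed_detection import _separable_gaussian

        smoothed = _separable_gaussian(ramp, (3.0, 3.0, 3.0), [0, 0, 0])
        fd = (smoothed[16, 15, 15] - smoothed[14, 15, 15]) / 2.0
        assert grad[0][15, 15, 15] == pytest.approx(fd, abs=1e-3)

    def test_anisotropic_spacing_rescales_to_physical_units(self):
        # spacing 0.5 -> voxel sigma 6 -> kernel radius 24; crop is wide
        # enough that the centre is beyond boundary influence
        shape = (31, 61)
        ramp = np.indices(shape, dtype=np.float64)[1] * 2.0  # 2 per voxel
        crop = CropRegion(ramp, (0, 0), (15, 30), (1.0, 0.5))
        grad = smoothed_gradient(crop, 3.0)
        # 2 intensity units per voxel of 0.5 physical units -> slope 4
        assert grad[1][15, 30] == pytest.approx(4.0, abs=1e-3)


class TestSeedNormalField:
    @pytest.mark.parametrize(
        "offset,spacing,expected_n,expected_d",
        [
            ((0, 0, 5), (1, 1, 1), (0, 0, 1), 5.0),
            ((0, 0, 5), (1, 1, 2), (0, 0, 1), 10.0),
            ((3, 4, 0), (1, 1, 1), (0.6, 0.8, 0.0), 5.0),
        ],
    )
    def test_hadamard_displacement_examples(self, offset, spacing, expected_n, expected_d):
        crop = CropRegion(
            np.zeros((13, 13, 13)), (0, 0, 0), (6, 6, 6), tuple(float(s) for s in spacing)
        )
        normals, dist = seed_normal_field(crop)
        voxel = tuple(6 + o for o in offset)
        np.testing.assert_allclose([normals[a][voxel] for a in range(3)], expected_n)
        assert dist[voxel] == pytest.approx(expected_d)

    def test_seed_voxel_normal_is_zero(self):
        crop = CropRegion(np.zeros((7, 7)), (0, 0), (3, 3), (1.0, 1.0))
        normals, dist = seed_normal_field(crop)
        assert dist[3, 3] == 0.0
        assert normals[0][3, 3] == 0.0 and normals[1][3, 3] == 0.0


class TestDotProductTransform:
    def test_alignment_endpoint_values(self):
        n = np.zeros((2, 1, 3))
        n[0, 0, :] = 1.0  # outward normal along axis 0
        g = np.zeros((2, 1, 3))
        g[0, 0, 0] = -2.5  # anti-parallel
        g[1, 0, 1] = 4.0  # perpendicular
        g[0, 0, 2] = 0.7  # parallel
        psi = dot_product_transform(n, g)
        assert psi[0, 0] == pytest.approx(1.0, abs=1e-12)
        assert psi[0, 1] == pytest.approx(0.5, abs=1e-12)
        assert psi[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_zero_gradient_is_neutral(self):
        n = np.zeros((2, 1, 1))
        n[0] = 1.0
        g = np.zeros((2, 1, 1))
        assert dot_product_transform(n, g)[0, 0] == 0.5

    def test_contrast_invariance_on_random_crop(self):
        rng = np.random.default_rng(5)
        data = rng.random((17, 17)) * 80 + 10
        crop = CropRegion(data, (0, 0), (8, 8), (1.0, 1.0))
        crop_scaled = CropRegion(7.3 * data, (0, 0), (8, 8), (1.0, 1.0))
        normals, _ = seed_normal_field(crop)
        psi1 = dot_product_transform(normals, smoothed_gradient(crop, 3.0))
        psi2 = dot_product_transform(normals, smoothed_gradient(crop_scaled, 3.0))
        np.testing.assert_allclose(psi1, psi2, atol=1e-9)

    @settings(deadline=None, max_examples=25)
    @given(
        data=hnp.arrays(
            np.float64,
            (2, 9, 9),
            elements=st.floats(-10, 10, allow_nan=False),
        )
    )
    def test_psi_always_in_unit_interval(self, data):
        n, g = data[:1].repeat(2, axis=0), data[1:].repeat(2, axis=0)
        psi = dot_product_transform(n, g)
        assert np.all(psi >= 0.0) and np.all(psi <= 1.0)


class TestWeightingKernel:
    def test_plateau_and_one_sigma_falloff(self):
        r, m, sw = 5.0, 1.5, 3.0
        d = np.array([0.0, m * r, m * r + sw, m * r + 2 * sw])
        w = weighting_kernel(d, r, m, sw)
        assert w[0] == 1.0
        assert w[1] == 1.0
        assert w[2] == pytest.approx(np.exp(-0.5), abs=1e-12)
        assert w[3] == pytest.approx(np.exp(-2.0), abs=1e-12)

    def test_weights_are_in_unit_interval(self):
        rng = np.random.default_rng(6)
        d = rng.random((20, 20)) * 50
        w = weighting_kernel(d, 4.0, 1.5, 3.0)
        assert np.all(w > 0.0) and np.all(w <= 1.0)


class TestCombineImages:
    def _fields(self, seed_radius=4.0):
        rng = np.random.default_rng(7)
        data = rng.random((15, 15)) * 100 + 17
        crop = CropRegion(data, (0, 0), (7, 7), (1.0, 1.0))
        normals, dist = seed_normal_field(crop)
        psi = dot_product_transform(normals, smoothed_gradient(crop, 3.0))
        w = weighting_kernel(dist, seed_radius)
        return crop, psi, w, dist

    def test_copy_through_within_seed_radius(self):
        crop, psi, w, dist = self._fields()
        combined = combine_images(crop, psi, w, 4.0, dist)
        inside = dist <= 4.0
        np.testing.assert_array_equal(combined[inside], crop.data[inside])

    def test_zero_psi_annihilates_outside(self):
        crop, _, w, dist = self._fields()
        combined = combine_images(crop, np.zeros_like(w), w, 4.0, dist)
        assert np.all(combined[dist > 4.0] == 0.0)

    def test_positive_homogeneity(self):
        crop, psi, w, dist = self._fields()
        a = 3.7
        crop2 = CropRegion(a * crop.data, crop.offset, crop.seed_local, crop.spacing)
        c1 = combine_images(crop, psi, w, 4.0, dist)
        c2 = combine_images(crop2, psi, w, 4.0, dist)
        np.testing.assert_allclose(c2, a * c1, rtol=1e-12)


def oracle_otsu(values, nbins=256):
    """Exhaustive search over all bin boundaries, direct class statistics.

    Empty bins between the classes form a plateau of analytically equal
    between-class variance (identical class memberships); the tie falls to
    the first boundary on the plateau, judged at 1e-10 relative tolerance
    so last-ulp summation noise cannot move the pick.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    counts, edges = np.histogram(values, bins=nbins, range=(values.min(), values.max()))
    centers = (edges[:-1] + edges[1:]) / 2
    variances = np.full(nbins - 1, -1.0)
    for k in range(1, nbins):
        w0 = counts[:k].sum()
        w1 = counts[k:].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[:k] * centers[:k]).sum() / w0
        mu1 = (counts[k:] * centers[k:]).sum() / w1
        variances[k - 1] = w0 * w1 * (mu0 - mu1) ** 2
    best = int(np.argmax(variances >= variances.max() * (1.0 - 1e-10)))
    return edges[best + 1]


class TestOtsuThreshold:
    def test_bimodal_field_is_separated(self):
        values = np.array([0.0] * 100 + [100.0] * 100)
        t, degenerate = otsu_threshold(values)
        assert not degenerate
        assert 0.0 < t < 100.0

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_exhaustive_oracle_on_random_fields(self, seed):
        rng = np.random.default_rng(seed)
        # mixture of two Gaussian classes with random parameters
        n0, n1 = rng.integers(20, 200, size=2)
        values = np.concatenate(
            [
                rng.normal(rng.uniform(0, 50), rng.uniform(1, 20), n0),
                rng.normal(rng.uniform(60, 150), rng.uniform(1, 20), n1),
            ]
        )
        t, degenerate = otsu_threshold(values)
        assert not degenerate
        t_oracle = oracle_otsu(values)
        assert t == pytest.approx(t_oracle, abs=1e-12)
        np.testing.assert_array_equal(values > t, values > t_oracle)

    def test_agrees_with_skimage_to_half_a_bin(self):
        from skimage.filters import threshold_otsu

        rng = np.random.default_rng(11)
        values = np.concatenate(
            [rng.normal(20, 5, 300), rng.normal(120, 10, 200)]
        )
        t, _ = otsu_threshold(values)
        bin_width = (values.max() - values.min()) / 256
        assert abs(t - threshold_otsu(values, nbins=256)) <= bin_width / 2 + 1e-9

    def test_constant_field_is_degenerate(self):
        t, degenerate = otsu_threshold(np.full(40, 3.5))
        assert degenerate
        assert t == 3.5


class TestExtractSegment:
    def test_isolated_sphere_volume_recovered(self):
        radius = 6.0
        img = render_sphere((41, 41, 41), (20.0, 20.0, 20.0), radius)
        vol = Volume(img, (1.0, 1.0, 1.0))
        seed = _seed((20, 20, 20), radius)
        seg = segment_seed(vol, seed, 0, TwangParams())
        assert seg is not None
        expected = 4.0 / 3.0 * np.pi * radius**3
        assert abs(seg.volume_voxels - expected) / expected <= 0.20
        np.testing.assert_allclose(seg.centroid, (20.0, 20.0, 20.0), atol=0.5)

    def test_touching_spheres_neighbor_is_excluded(self):
        radius = 6.0
        img = render_sphere((41, 41, 41), (20.0, 20.0, 14.0), radius, bg=20.0)
        neighbor = render_sphere((41, 41, 41), (20.0, 20.0, 26.0), radius, bg=0.0, fg=180.0)
        img = np.maximum(img, neighbor + 20.0)
        vol = Volume(img, (1.0, 1.0, 1.0))
        seg = segment_seed(vol, _seed((20, 20, 14), radius), 0, TwangParams())
        assert seg is not None
        # rebuild full-frame mask
        full = np.zeros(vol.shape, dtype=bool)
        slices = tuple(
            slice(o, o + s) for o, s in zip(seg.offset, seg.mask.shape)
        )
        full[slices] = seg.mask
        grids = np.indices(vol.shape, dtype=np.float64)
        d_b = np.sqrt(
            (grids[0] - 20) ** 2 + (grids[1] - 20) ** 2 + (grids[2] - 26) ** 2
        )
        neighbor_truth = (d_b <= radius) & (d_b < np.sqrt(
            (grids[0] - 20) ** 2 + (grids[1] - 20) ** 2 + (grids[2] - 14) ** 2
        ))
        leak = (full & neighbor_truth).sum() / neighbor_truth.sum()
        assert leak <= 0.05

    def test_flat_background_crop_yields_none(self):
        """A crop with no object degenerates under Otsu and is discarded."""
        vol = Volume(np.full((25, 25, 25), 20.0), (1.0, 1.0, 1.0))
        seg = segment_seed(vol, _seed((12, 12, 12), 5.0), 0, TwangParams())
        assert seg is None


class TestSegmentAll:
    def test_empty_seed_list(self):
        vol = Volume(np.zeros((10, 10)), (1.0, 1.0))
        assert segment_all(vol, [], TwangParams()) == []

    def test_one_slot_per_seed_and_worker_determinism(self, sparse_phantom_3d):
        spec, vol, truth = sparse_phantom_3d
        params = TwangParams(sigma_min=2.5, sigma_max=4.5, sigma_step=0.5,
                             seed_intensity_threshold=20.0)
        from twang import detect_seeds_from_volume

        seeds, _ = detect_seeds_from_volume(vol, params)
        assert len(seeds) > 0
        seq = segment_all(vol, seeds, params, workers=1)
        par = segment_all(vol, seeds, params, workers=4)
        assert len(seq) == len(seeds) == len(par)
        for a, b in zip(seq, par):
            assert (a is None) == (b is None)
            if a is not None:
                assert a.seed_id == b.seed_id
                assert a.offset == b.offset
                assert a.otsu_threshold == b.otsu_threshold
                np.testing.assert_array_equal(a.mask, b.mask)
                assert a.centroid == b.centroid


class TestAssembleLabelImage:
    def _candidate(self, seed_id, offset, mask, centroid):
        return SegmentCandidate(
            seed_id=seed_id,
            offset=offset,
            mask=mask,
            otsu_threshold=0.0,
            centroid=centroid,
            volume_voxels=int(mask.sum()),
            volume_physical=float(mask.sum()),
            mean_intensity=1.0,
            bbox=(offset, tuple(o + s - 1 for o, s in zip(offset, mask.shape))),
        )

    def test_disjoint_masks_painted_verbatim(self):
        m = np.ones((2, 2), dtype=bool)
        segs = [
            self._candidate(0, (0, 0), m, (0.5, 0.5)),
            self._candidate(1, (5, 5), m, (5.5, 5.5)),
        ]
        seeds = [_seed((0, 0), 2.0), _seed((5, 5), 2.0)]
        labels = assemble_label_image(segs, (8, 8), (1.0, 1.0), seeds)
        assert labels.labels[0, 0] == 1 and labels.labels[1, 1] == 1
        assert labels.labels[5, 5] == 2 and labels.labels[6, 6] == 2
        assert (labels.labels > 0).sum() == 8

    def test_equidistant_overlap_goes_to_smaller_seed_id(self):
        m = np.ones((1, 3), dtype=bool)
        segs = [
            self._candidate(0, (0, 0), m, (0.0, 0.0)),
            self._candidate(1, (0, 2), m, (0.0, 4.0)),
        ]
        seeds = [_seed((0, 0), 2.0), _seed((0, 4), 2.0)]
        labels = assemble_label_image(segs, (1, 5), (1.0, 1.0), seeds)
        # voxel (0,2) is exactly 2.0 from both seeds -> smaller seed id wins
        assert labels.labels[0, 2] == 1

    def test_label_count_bounded_by_seed_count(self, sparse_phantom_3d):
        spec, vol, truth = sparse_phantom_3d
        params = TwangParams(sigma_min=2.5, sigma_max=4.5, sigma_step=0.5,
                             seed_intensity_threshold=20.0)
        from twang import detect_seeds_from_volume

        seeds, _ = detect_seeds_from_volume(vol, params)
        segs = segment_all(vol, seeds, params)
        labels = assemble_label_image(segs, vol.shape, vol.spacing, seeds)
        assert len(labels.label_values()) <= len(seeds)
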