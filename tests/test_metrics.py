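"""Segmentation, component analysis, distances, FWHM, volume agreement."""

import numpy as np
import pytest

from qsmcalc.core_io import Mask, ScalarVolume, ValidationError, VoxelGrid
from qsmcalc.metrics import (
    center_to_center,
    component_analysis,
    match_components,
    profile_fwhm,
    segment_qsm,
    threshold_ct,
    volume_agreement,
)
from qsmcalc.phantom import Sphere, SpherePhantomSpec, make_ct, sphere_occupancy


class TestThresholdCT:
    def test_default_is_130_hu(self, small_grid):
        data = np.full(small_grid.shape, 129.9)
        data[3, 3, 3] = 130.0
        m = threshold_ct(ScalarVolume(small_grid, data, "hounsfield"))
        assert m.count == 1
        assert m.data[3, 3, 3]

    def test_soft_tissue_only_empty(self, small_grid):
        m = threshold_ct(ScalarVolume(small_grid, np.full(small_grid.shape, 20.0), "hounsfield"))
        assert m.count == 0

    def test_quantity_tag_enforced(self, small_grid):
        with pytest.raises(ValidationError):
            threshold_ct(ScalarVolume(small_grid, np.zeros(small_grid.shape), "field_Hz"))

    def test_synthetic_ct_partial_volume_rule(self, small_grid):
        spec = SpherePhantomSpec(
            spheres=(Sphere((0.2, 0.1, -0.3), 4.0, -2.0, 800.0),),
            background_hounsfield=20.0,
        )
        ct = make_ct(spec, small_grid, 4)
        occ = sphere_occupancy(spec, small_grid, 4)[0]
        m = threshold_ct(ct)
        assert m.count == int(np.count_nonzero(occ >= (130.0 - 20.0) / 780.0))


class TestSegmentQSM:
    def test_uniform_zero_fixed_mode_empty(self, small_grid):
        chi = ScalarVolume(small_grid, np.zeros(small_grid.shape), "susceptibility_ppm")
        assert segment_qsm(chi, mode="fixed", chi_threshold_ppm=-0.5).count == 0

    def test_half_min_threshold_definition(self, small_grid):
        data = np.zeros(small_grid.shape)
        data[10:14, 10:14, 10:14] = -2.0
        data[11:13, 11:13, 11:13] = -2.0
        data[20:22, 20:22, 20:22] = -0.9  # below half of -2? no: -0.9 < -1 is false
        chi = ScalarVolume(small_grid, data, "susceptibility_ppm")
        m = segment_qsm(chi, mode="half_min", min_voxels=1)
        assert m.data[10:14, 10:14, 10:14].all()
        assert not m.data[20:22, 20:22, 20:22].any()

    def test_half_min_requires_diamagnetic_signal(self, small_grid):
        chi = ScalarVolume(small_grid, np.abs(np.ones(small_grid.shape)), "susceptibility_ppm")
        with pytest.raises(ValidationError, match="diamagnetic"):
            segment_qsm(chi, mode="half_min")

    def test_min_voxels_prunes_specks(self, small_grid):
        data = np.zeros(small_grid.shape)
        data[5, 5, 5] = -3.0  # single-voxel speck
        data[20:24, 20:24, 20:24] = -3.0
        chi = ScalarVolume(small_grid, data, "susceptibility_ppm")
        m = segment_qsm(chi, mode="fixed", chi_threshold_ppm=-1.0, min_voxels=2)
        assert not m.data[5, 5, 5]
        assert m.data[20:24, 20:24, 20:24].all()


class TestComponents:
    def test_single_voxel_component_geometry(self):
        grid = VoxelGrid((8, 8, 6), (1.0, 1.0, 2.5), origin_mm=(0, 0, 0))
        m = np.zeros(grid.shape, bool)
        m[2, 3, 4] = True
        rep = component_analysis(Mask(grid, m))
        assert len(rep.components) == 1
        c = rep.components[0]
        assert c.volume_mm3 == pytest.approx(2.5)
        assert c.voxel_count == 1
        assert c.centroid_mm == pytest.approx((2.0, 3.0, 10.0))

    def test_corner_touching_voxels_are_one_component(self, small_grid):
        m = np.zeros(small_grid.shape, bool)
        m[5, 5, 5] = True
        m[6, 6, 6] = True  # touches only at a corner: 26-connectivity joins
        rep = component_analysis(Mask(small_grid, m))
        assert len(rep.components) == 1
        assert rep.components[0].voxel_count == 2

    def test_volume_conservation(self, small_grid):
        rng = np.random.default_rng(8)
        m = rng.random(small_grid.shape) > 0.7
        rep = component_analysis(Mask(small_grid, m))
        total = sum(c.volume_mm3 for c in rep.components)
        assert total == pytest.approx(np.count_nonzero(m) * small_grid.voxel_volume_mm3)

    def test_digital_sphere_volume(self, small_grid):
        # generic sub-voxel placement; symmetric alignments are degenerate
        # (many boundary voxels tie at occupancy 0.5)
        spec = SpherePhantomSpec(spheres=(Sphere((0.3, -0.2, 0.15), 5.0, -2.0, 800.0),))
        occ = sphere_occupancy(spec, small_grid, 4)[0]
        rep = component_analysis(Mask(small_grid, occ > 0.5))
        assert rep.components[0].volume_mm3 == pytest.approx(523.6, rel=0.03)

    def test_empty_mask_gives_empty_report(self, small_grid):
        rep = component_analysis(Mask(small_grid, np.zeros(small_grid.shape, bool)))
        assert rep.components == []

    def test_distance_matrix_symmetric_zero_diagonal(self, small_grid):
        m = np.zeros(small_grid.shape, bool)
        m[5:7, 5:7, 5:7] = True
        m[20:22, 8:10, 8:10] = True
        m[30:32, 20:22, 12:14] = True
        rep = component_analysis(Mask(small_grid, m))
        d = rep.pairwise_distances_mm
        np.testing.assert_allclose(d, d.T)
        np.testing.assert_allclose(np.diag(d), 0.0)


class TestDistances:
    def test_three_four_five(self):
        grid = VoxelGrid((40, 40, 10), (1, 1, 1))
        m = np.zeros(grid.shape, bool)
        m[5, 5, 5] = True
        m[8, 9, 5] = True  # displaced by (3, 4, 0)
        rep = component_analysis(Mask(grid, m))
        assert center_to_center(rep) == pytest.approx([5.0])

    def test_single_component_rejected(self, small_grid):
        m = np.zeros(small_grid.shape, bool)
        m[5:7, 5:7, 5:7] = True
        with pytest.raises(ValidationError):
            center_to_center(component_analysis(Mask(small_grid, m)))

    def test_matching_pairs_nearest_centroids(self, small_grid):
        a = np.zeros(small_grid.shape, bool)
        b = np.zeros(small_grid.shape, bool)
        a[5:8, 5:8, 5:8] = True
        a[25:28, 25:28, 12:15] = True
        b[6:9, 5:8, 5:8] = True  # shifted by one voxel
        b[25:28, 26:29, 12:15] = True
        ra = component_analysis(Mask(small_grid, a))
        rb = component_analysis(Mask(small_grid, b))
        pairs = match_components(ra, rb)
        assert pairs == [(0, 0), (1, 1)]


class TestFWHM:
    def _volume_from_profile(self, values):
        grid = VoxelGrid((len(values), 3, 3), (1.0, 1.0, 1.0), origin_mm=(0, -1, -1))
        data = np.zeros(grid.shape)
        data[:, :, :] = np.asarray(values)[:, None, None]
        return ScalarVolume(grid, data, "hounsfield"), grid

    def test_triangular_profile_exact(self):
        vol, grid = self._volume_from_profile([0, 0, 1, 2, 4, 2, 1, 0, 0])
        _, _, fwhm = profile_fwhm(vol, (0, 0, 0), (8, 0, 0), n_samples=17)
        assert fwhm == pytest.approx(2.0, abs=1e-9)

    def test_gaussian_profile_closed_form(self):
        sigma = 3.0
        x = np.arange(61)
        vals = np.exp(-((x - 30.0) ** 2) / (2 * sigma**2))
        vol, _ = self._volume_from_profile(vals)
        _, _, fwhm = profile_fwhm(vol, (0, 0, 0), (60, 0, 0), n_samples=601)
        assert fwhm == pytest.approx(2.3548 * sigma, rel=0.02)

    def test_negative_polarity_dip(self):
        vals = -np.array([0, 0, 1, 2, 4, 2, 1, 0, 0], float)
        vol, _ = self._volume_from_profile(vals)
        _, profile, fwhm = profile_fwhm(
            vol, (0, 0, 0), (8, 0, 0), n_samples=17, polarity="negative"
        )
        assert fwhm == pytest.approx(2.0, abs=1e-9)
        assert profile.min() == pytest.approx(-4.0)  # values on the original scale

    def test_flat_profile_rejected(self):
        vol, _ = self._volume_from_profile(np.ones(9))
        with pytest.raises(ValidationError):
            profile_fwhm(vol, (0, 0, 0), (8, 0, 0), n_samples=17)

    def test_minimum_sampling_enforced(self):
        vol, _ = self._volume_from_profile([0, 1, 0])
        with pytest.raises(ValidationError):
            profile_fwhm(vol, (0, 0, 0), (2, 0, 0), n_samples=8)


class TestVolumeAgreement:
    def test_identity_line(self):
        r = volume_agreement([1, 2, 3], [1, 2, 3])
        assert r.slope == pytest.approx(1.0)
        assert r.intercept == pytest.approx(0.0, abs=1e-12)
        assert r.r_squared == pytest.approx(1.0)

    def test_exact_affine_relation(self):
        x = np.arange(1.0, 6.0)
        r = volume_agreement(x, 2 * x + 1)
        assert r.slope == pytest.approx(2.0)
        assert r.intercept == pytest.approx(1.0)
        assert r.r_squared == pytest.approx(1.0)

    def test_slope_unbiased_under_symmetric_noise(self):
        rng = np.random.default_rng(12)
        x = np.linspace(10, 600, 12)
        slopes = []
        for _ in range(200):
            y = 1.5 * x - 4.0 + rng.normal(0, 5.0, size=x.size)
            slopes.append(volume_agreement(x, y).slope)
        assert np.mean(slopes) == pytest.approx(1.5, rel=0.02)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            volume_agreement([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
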