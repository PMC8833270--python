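"""Phase chain: unwrapping, background removal, detrending, combination."""

import numpy as np
import pytest

from qsmcalc.core_io import AcquisitionProtocol, Mask, ScalarVolume, ValidationError, VoxelGrid
from qsmcalc.phantom import Sphere, SpherePhantomSpec, forward_field, rasterize_susceptibility
from qsmcalc.phase import (
    DEFAULT_VSHARP_RADII_MM,
    ConvergenceError,
    laplacian_unwrap,
    lbv_background_removal,
    per_echo_field,
    poly4_detrend,
    t2star_weighted_combine,
    unwrap_echo_train,
    vsharp_background_removal,
)

from conftest import wrap_phase


def _outside_inside_fields(grid, protocol):
    """Forward fields of one source outside and one inside the box ROI."""
    out_spec = SpherePhantomSpec(spheres=(Sphere((0, 63, 0), 6.0, 9.0, 0.0),))
    in_spec = SpherePhantomSpec(spheres=(Sphere((0, 0, 0), 5.0, -2.0, 800.0),))
    f_out = forward_field(rasterize_susceptibility(out_spec, grid, 2)[0], protocol)
    f_in = forward_field(rasterize_susceptibility(in_spec, grid, 2)[0], protocol)
    return f_out, f_in


class TestLaplacianUnwrap:
    def test_zero_phase_maps_to_zero(self, small_grid):
        out = laplacian_unwrap(ScalarVolume(small_grid, np.zeros(small_grid.shape), "phase_rad"))
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_wrapped_linear_ramp_recovered(self, small_grid):
        nx = small_grid.shape[0]
        i = np.arange(nx)[:, None, None]
        true = 3 * np.pi * i / (nx - 1) * np.ones(small_grid.shape)
        out = laplacian_unwrap(ScalarVolume(small_grid, wrap_phase(true), "phase_rad"))
        diff = out.data - true
        interior = diff[4:-4, 4:-4, 4:-4]
        assert np.abs(interior - interior.mean()).max() < 0.05

    def test_smooth_blob_congruent_recovery(self, small_grid):
        x, y, z = np.meshgrid(
            *[np.arange(n) - n / 2 for n in small_grid.shape], indexing="ij"
        )
        blob = 2.5 * np.exp(-(x**2 + y**2 + z**2) / (2 * 6.0**2))
        out = laplacian_unwrap(ScalarVolume(small_grid, wrap_phase(blob), "phase_rad"))
        d = out.data - blob
        interior = d[8:-8, 8:-8, 8:-8]
        assert np.abs(interior - interior.mean()).max() < 1e-6

    def test_non_finite_rejected(self, small_grid):
        bad = np.zeros(small_grid.shape)
        bad[0, 0, 0] = np.nan
        with pytest.raises(ValidationError):
            laplacian_unwrap(ScalarVolume(small_grid, bad, "phase_rad"))

    def test_echo_train_scales_with_te(self, small_grid, protocol):
        # field of 40 Hz: late echoes wrap several times but stay TE-proportional
        x, _, _ = small_grid.coordinate_arrays()
        field = 40.0 * np.exp(-(x**2) / (2 * 10.0**2))
        tes = list(protocol.te_s)
        phases = [
            ScalarVolume(small_grid, wrap_phase(2 * np.pi * field * te), "phase_rad")
            for te in tes
        ]
        unwrapped = unwrap_echo_train(phases, tes)
        for u, te in zip(unwrapped[1:], tes[1:]):
            expect = 2 * np.pi * field * te
            d = u.data - expect
            interior = d[4:-4, 4:-4, 4:-4]
            assert np.abs(interior - interior.mean()).max() < 1e-6


class TestLBV:
    def test_zero_field_zero_local(self, container_geometry):
        grid, mask = container_geometry
        res = lbv_background_removal(
            ScalarVolume(grid, np.zeros(grid.shape), "field_Hz"), mask
        )
        np.testing.assert_allclose(res.local_field.data, 0.0, atol=1e-9)
        assert not (res.valid_mask.data & ~mask.data).any()

    def test_outside_source_removed(self, container_geometry, protocol):
        grid, mask = container_geometry
        f_out, _ = _outside_inside_fields(grid, protocol)
        res = lbv_background_removal(f_out, mask)
        v = res.valid_mask.data
        bg = np.sqrt(np.mean(f_out.data[v] ** 2))
        assert np.sqrt(np.mean(res.local_field.data[v] ** 2)) < 0.02 * bg

    def test_inside_source_preserved(self, container_geometry, protocol):
        grid, mask = container_geometry
        f_out, f_in = _outside_inside_fields(grid, protocol)
        tot = ScalarVolume(grid, f_out.data + f_in.data, "field_Hz")
        res = lbv_background_removal(tot, mask)
        v = res.valid_mask.data
        err = res.local_field.data[v] - f_in.data[v]
        rel = np.sqrt(np.mean(err**2)) / np.sqrt(np.mean(f_in.data[v] ** 2))
        assert rel < 0.10

    def test_non_convergence_raises(self, container_geometry, protocol):
        grid, mask = container_geometry
        f_out, _ = _outside_inside_fields(grid, protocol)
        with pytest.raises(ConvergenceError):
            lbv_background_removal(f_out, mask, tol=1e-14, max_iter=2)

    def test_empty_mask_rejected(self, container_geometry):
        grid, _ = container_geometry
        with pytest.raises(ValidationError):
            lbv_background_removal(
                ScalarVolume(grid, np.zeros(grid.shape), "field_Hz"),
                Mask(grid, np.zeros(grid.shape, bool)),
            )


class TestVSharp:
    def test_default_radius_family(self):
        assert DEFAULT_VSHARP_RADII_MM[0] == 1.0
        assert DEFAULT_VSHARP_RADII_MM[-1] == 25.0
        np.testing.assert_allclose(np.diff(DEFAULT_VSHARP_RADII_MM), 2.0)
        assert len(DEFAULT_VSHARP_RADII_MM) == 13

    def test_zero_field_zero_local(self, container_geometry):
        grid, mask = container_geometry
        res = vsharp_background_removal(
            ScalarVolume(grid, np.zeros(grid.shape), "field_Hz"), mask
        )
        np.testing.assert_allclose(res.local_field.data, 0.0, atol=1e-12)

    def test_outside_source_removed(self, container_geometry, protocol):
        grid, mask = container_geometry
        f_out, _ = _outside_inside_fields(grid, protocol)
        res = vsharp_background_removal(f_out, mask)
        v = res.valid_mask.data
        bg = np.sqrt(np.mean(f_out.data[v] ** 2))
        assert np.sqrt(np.mean(res.local_field.data[v] ** 2)) < 0.05 * bg

    def test_inside_source_preserved(self, container_geometry, protocol):
        grid, mask = container_geometry
        f_out, f_in = _outside_inside_fields(grid, protocol)
        tot = ScalarVolume(grid, f_out.data + f_in.data, "field_Hz")
        res = vsharp_background_removal(tot, mask)
        v = res.valid_mask.data
        err = res.local_field.data[v] - f_in.data[v]
        rel = np.sqrt(np.mean(err**2)) / np.sqrt(np.mean(f_in.data[v] ** 2))
        assert rel < 0.10

    def test_valid_mask_shrinks_within_input(self, container_geometry, protocol):
        grid, mask = container_geometry
        f_out, _ = _outside_inside_fields(grid, protocol)
        res = vsharp_background_removal(f_out, mask)
        assert not (res.valid_mask.data & ~mask.data).any()
        assert res.valid_mask.count < mask.count

    def test_tiny_mask_rejected(self, small_grid):
        m = np.zeros(small_grid.shape, bool)
        m[20, 20, 16] = True
        with pytest.raises(ValidationError):
            vsharp_background_removal(
                ScalarVolume(small_grid, np.zeros(small_grid.shape), "field_Hz"),
                Mask(small_grid, m),
                kernel_radii_mm=(3.0, 5.0),
            )


class TestPolyDetrend:
    def _mask(self, grid):
        m = np.zeros(grid.shape, bool)
        m[4:-4, 4:-4, 4:-4] = True
        return Mask(grid, m)

    def test_degree_four_removed_exactly(self, small_grid):
        x, y, z = small_grid.coordinate_arrays()
        poly = 1.0 + 0.1 * x - 0.05 * y * z + 0.002 * x**2 * y**2 + 0.001 * z**4
        vol = ScalarVolume(small_grid, poly, "field_Hz")
        res = poly4_detrend(vol, self._mask(small_grid))
        assert np.abs(res.data).max() < 1e-8 * np.ptp(poly)

    def test_constant_removed(self, small_grid):
        vol = ScalarVolume(small_grid, np.full(small_grid.shape, 7.0), "field_Hz")
        res = poly4_detrend(vol, self._mask(small_grid))
        np.testing.assert_allclose(res.data, 0.0, atol=1e-10)

    def test_compact_blob_survives(self, small_grid, protocol):
        spec = SpherePhantomSpec(spheres=(Sphere((0, 0, 0), 3.0, -1.0, 0.0),))
        blob = forward_field(rasterize_susceptibility(spec, small_grid, 2)[0], protocol)
        x, y, z = small_grid.coordinate_arrays()
        trend = 3.0 + 0.2 * x + 0.01 * y**2
        vol = ScalarVolume(small_grid, blob.data + trend, "field_Hz")
        res = poly4_detrend(vol, self._mask(small_grid))
        peak_true = np.abs(blob.data).max()
        peak_idx = np.unravel_index(np.argmax(np.abs(blob.data)), blob.data.shape)
        assert abs(abs(res.data[peak_idx]) - peak_true) < 0.10 * peak_true

    def test_insufficient_mask_rejected(self, small_grid):
        m = np.zeros(small_grid.shape, bool)
        m[10:12, 10:13, 10:12] = True  # 12 voxels < 35 monomials
        with pytest.raises(ValidationError):
            poly4_detrend(
                ScalarVolume(small_grid, np.zeros(small_grid.shape), "field_Hz"),
                Mask(small_grid, m),
            )


class TestFieldConversionAndCombine:
    def test_phase_to_field_arithmetic(self, small_grid):
        vol = ScalarVolume(small_grid, np.full(small_grid.shape, 2 * np.pi), "phase_rad")
        f = per_echo_field(vol, 0.010)
        np.testing.assert_allclose(f.data, 100.0)
        f2 = per_echo_field(vol, 0.020)
        np.testing.assert_allclose(f2.data, 50.0)

    def test_nonpositive_te_rejected(self, small_grid):
        vol = ScalarVolume(small_grid, np.zeros(small_grid.shape), "phase_rad")
        with pytest.raises(ValidationError):
            per_echo_field(vol, 0.0)

    def test_equal_fields_pass_through(self, small_grid, protocol):
        f = ScalarVolume(small_grid, np.full(small_grid.shape, 3.3), "field_Hz")
        r2 = ScalarVolume(small_grid, np.full(small_grid.shape, 37.0), "r2star_per_s")
        out = t2star_weighted_combine([f] * protocol.n_echoes, r2, protocol)
        np.testing.assert_allclose(out.data, 3.3, rtol=1e-12)

    def test_te_weighting_at_zero_r2star(self, small_grid):
        protocol = AcquisitionProtocol(te_s=(0.0057, 0.0127))
        zero = ScalarVolume(small_grid, np.zeros(small_grid.shape), "field_Hz")
        one = ScalarVolume(small_grid, np.ones(small_grid.shape), "field_Hz")
        r2 = ScalarVolume(small_grid, np.zeros(small_grid.shape), "r2star_per_s")
        out = t2star_weighted_combine([zero, one], r2, protocol)
        np.testing.assert_allclose(out.data, 12.7 / 18.4, rtol=1e-12)

    def test_large_r2star_prefers_first_echo(self, small_grid, protocol):
        fields = [
            ScalarVolume(small_grid, np.full(small_grid.shape, float(i)), "field_Hz")
            for i in range(protocol.n_echoes)
        ]
        out_prev = None
        for r2val in (0.0, 100.0, 1000.0):
            r2 = ScalarVolume(small_grid, np.full(small_grid.shape, r2val), "r2star_per_s")
            out = t2star_weighted_combine(fields, r2, protocol)
            mean = out.data.mean()
            if out_prev is not None:
                assert mean < out_prev  # weight mass moves to earlier echoes
            out_prev = mean
        r2 = ScalarVolume(small_grid, np.full(small_grid.shape, 1e5), "r2star_per_s")
        out = t2star_weighted_combine(fields, r2, protocol)
        np.testing.assert_allclose(out.data, 0.0, atol=1e-4)

    def test_length_mismatch_rejected(self, small_grid, protocol):
        f = ScalarVolume(small_grid, np.zeros(small_grid.shape), "field_Hz")
        r2 = ScalarVolume(small_grid, np.zeros(small_grid.shape), "r2star_per_s")
        with pytest.raises(ValidationError):
            t2star_weighted_combine([f] * 3, r2, protocol)


class TestStageLinearity:
    """Background-removal stages are linear in the field."""

    @pytest.mark.parametrize("alpha", [0.5, 2.0])
    def test_lbv_vsharp_scale_equivariance(self, container_geometry, protocol, alpha):
        grid, mask = container_geometry
        f_out, f_in = _outside_inside_fields(grid, protocol)
        tot = f_out.data + f_in.data
        for op in (
            lambda v: lbv_background_removal(v, mask).local_field.data,
            lambda v: vsharp_background_removal(v, mask).local_field.data,
        ):
            base = op(ScalarVolume(grid, tot, "field_Hz"))
            scaled = op(ScalarVolume(grid, alpha * tot, "field_Hz"))
            np.testing.assert_allclose(
                scaled, alpha * base, atol=1e-6 * np.abs(base).max()
            )
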