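"""Phase-difference images, slow-phase removal, temporal harmonic, and
edge-adaptive derivatives / curl."""

import numpy as np
import pytest

from mrepost import (
    DisplacementSeries,
    GridSpec,
    HarmonicField,
    adaptive_gradient,
    curl,
    first_temporal_harmonic,
    phase_difference_wave,
    remove_slow_phase,
    wavelength_mm,
)
from tests.conftest import plane_wave_series


class TestPhaseDifference:
    def _images(self, grid, rng, phase):
        mag = 1.0 + rng.random((*grid.shape, 1, 4))
        pos = mag * np.exp(1j * phase)
        neg = mag * np.ones_like(pos)
        return pos, neg

    def test_identical_images_give_zero_phase(self, grid, rng):
        pos = rng.random((*grid.shape, 1, 4)) * np.exp(1j * rng.random((*grid.shape, 1, 4)))
        out = phase_difference_wave(pos, pos, grid)
        assert np.allclose(np.angle(out.values), 0.0, atol=1e-12)

    def test_phase_is_encoding_difference_and_magnitudes_multiply(self, grid, rng):
        theta = rng.uniform(-1.5, 1.5, size=(*grid.shape, 1, 4))
        pos, neg = self._images(grid, rng, theta)
        out = phase_difference_wave(pos, neg, grid)
        assert np.allclose(np.angle(out.values), theta, atol=1e-12)
        assert np.allclose(np.abs(out.values), np.abs(pos) * np.abs(neg), atol=1e-12)

    def test_shape_mismatch_rejected(self, grid, rng):
        a = rng.random((*grid.shape, 1, 4)).astype(complex)
        with pytest.raises(ValueError):
            phase_difference_wave(a, a[..., :2], grid)


class TestRemoveSlowPhase:
    def test_constant_phase_removed(self):
        grid = GridSpec(shape=(16, 16, 4))
        vals = np.exp(1j * 0.7) * np.ones((*grid.shape, 1, 4))
        out = remove_slow_phase(DisplacementSeries(vals, grid))
        assert np.allclose(out.values, 0.0, atol=1e-10)

    def test_invariant_to_global_phase_shift(self):
        grid = GridSpec(shape=(16, 16, 4))
        rng = np.random.default_rng(0)
        base = np.exp(1j * rng.uniform(-0.4, 0.4, size=(*grid.shape, 1, 4)))
        out1 = remove_slow_phase(DisplacementSeries(base, grid))
        out2 = remove_slow_phase(DisplacementSeries(base * np.exp(1j * 1.1), grid))
        assert np.allclose(out1.values, out2.values, atol=1e-10)

    def test_high_frequency_ripple_survives(self):
        # ripple at 8 cycles across 32 voxels sits far above the 3x3 k-space
        # passband, so it passes through nearly unchanged
        grid = GridSpec(shape=(32, 32, 2))
        x = np.arange(32)
        ripple = 0.3 * np.sin(2 * np.pi * 8 * x / 32)
        phase = np.broadcast_to(ripple[:, None, None, None, None], (*grid.shape, 1, 2))
        out = remove_slow_phase(DisplacementSeries(np.exp(1j * phase), grid))
        assert np.allclose(out.values, phase, atol=0.02)


class TestFirstTemporalHarmonic:
    def test_unit_sinusoid_gives_unit_amplitude(self, grid):
        series = plane_wave_series(grid, 3.0)
        harm = first_temporal_harmonic(series)
        assert np.allclose(np.abs(harm.values), 1.0, atol=1e-12)

    def test_phase_encodes_spatial_phase(self, grid):
        series = plane_wave_series(grid, 3.0)
        harm = first_temporal_harmonic(series)
        lam = series.wavelength
        x = np.arange(grid.shape[0]) * grid.spacing
        expected = 2 * np.pi * x / lam
        measured = np.unwrap(np.angle(-1j * np.exp(1j * 0) * harm.values[:, 0, 0, 0]))
        # relative spatial phase matches the wave's phase ramp
        assert np.allclose(
            np.diff(measured), np.diff(expected), atol=1e-9
        )

    def test_dc_and_second_harmonic_rejected(self, grid):
        const = DisplacementSeries(np.ones((*grid.shape, 1, 8)), grid)
        assert np.allclose(first_temporal_harmonic(const).values, 0.0, atol=1e-12)
        p = np.arange(8)
        second = np.sin(2 * 2 * np.pi * p / 8)
        vals = np.broadcast_to(second, (*grid.shape, 1, 8)).copy()
        assert np.allclose(
            first_temporal_harmonic(DisplacementSeries(vals, grid)).values, 0.0, atol=1e-12
        )

    def test_linearity(self, grid, rng):
        a = rng.normal(size=(*grid.shape, 1, 8))
        b = rng.normal(size=(*grid.shape, 1, 8))
        ha = first_temporal_harmonic(DisplacementSeries(a, grid)).values
        hb = first_temporal_harmonic(DisplacementSeries(b, grid)).values
        hab = first_temporal_harmonic(DisplacementSeries(2 * a + 3 * b, grid)).values
        assert np.allclose(hab, 2 * ha + 3 * hb, atol=1e-10)

    def test_requires_three_offsets(self, grid):
        series = DisplacementSeries(np.zeros((*grid.shape, 1, 2)), grid)
        with pytest.raises(ValueError):
            first_temporal_harmonic(series)


class TestAdaptiveGradient:
    def test_linear_ramp_exact_including_edges(self, grid):
        xs = grid.coordinates()[0]
        mask = np.ones(grid.shape, dtype=bool)
        deriv, valid = adaptive_gradient(2.5 * xs, mask, axis=0, spacing=grid.spacing, mode="adaptive")
        assert valid.all()
        assert np.allclose(deriv, 2.5, atol=1e-12)

    def test_constant_field_zero_gradient(self, grid):
        mask = np.ones(grid.shape, dtype=bool)
        deriv, _ = adaptive_gradient(np.full(grid.shape, 7.0), mask, 1, grid.spacing, "adaptive")
        assert np.allclose(deriv, 0.0, atol=1e-12)

    def test_central_difference_sine_oracle(self, grid):
        # (sin(k(x+h)) - sin(k(x-h))) / 2h = cos(kx) * sin(kh)/h
        lam = wavelength_mm(3.0, grid)
        k = 2 * np.pi / lam
        h = grid.spacing
        xs = grid.coordinates()[0]
        mask = np.ones(grid.shape, dtype=bool)
        deriv, valid = adaptive_gradient(np.sin(k * xs), mask, 0, h, "traditional")
        interior = np.zeros(grid.shape, dtype=bool)
        interior[1:-1] = True
        assert np.allclose(
            deriv[interior], (np.cos(k * xs) * np.sin(k * h) / h)[interior], atol=1e-12
        )
        assert valid.all()

    def test_modes_agree_away_from_edges(self, grid, rng):
        mask = np.zeros(grid.shape, dtype=bool)
        mask[4:20, 4:20, 4:20] = True
        f = rng.normal(size=grid.shape)
        da, va = adaptive_gradient(f, mask, 0, grid.spacing, "adaptive")
        dt, vt = adaptive_gradient(f, mask, 0, grid.spacing, "traditional")
        inner = np.zeros(grid.shape, dtype=bool)
        inner[5:19, 4:20, 4:20] = True
        assert np.array_equal(da[inner], dt[inner])
        assert va.all() == mask.all() or np.array_equal(va, mask)

    def test_adaptive_keeps_every_in_mask_voxel(self, grid, rng):
        mask = np.zeros(grid.shape, dtype=bool)
        mask[4:20, 4:20, 4:20] = True
        f = rng.normal(size=grid.shape)
        _, valid = adaptive_gradient(f, mask, 0, grid.spacing, "adaptive")
        assert np.array_equal(valid, mask)


class TestCurl:
    def _vector_field(self, grid, fn):
        vals = np.stack([fn(i) for i in range(3)], axis=-1)
        return HarmonicField(
            values=vals.astype(complex), grid=grid, valid=np.ones((*grid.shape, 3), dtype=bool)
        )

    def test_curl_of_gradient_vanishes_in_interior(self, grid):
        # u = grad(phi) with phi = x^2 + y^2 has identically zero discrete curl
        xs, ys, zs = grid.coordinates()
        comps = [2 * xs, 2 * ys, np.zeros(grid.shape)]
        field = self._vector_field(grid, lambda i: comps[i])
        mask = np.ones(grid.shape, dtype=bool)
        c = curl(field, mask, mode="traditional")
        interior = np.zeros(grid.shape, dtype=bool)
        interior[1:-1, 1:-1, 1:-1] = True
        assert np.allclose(c.values[interior], 0.0, atol=1e-12)

    def test_single_component_sine_oracle(self, grid):
        # u = (0, 0, sin(kx)) -> curl_y = -d u_z/dx = -cos(kx) sin(kh)/h
        lam = wavelength_mm(3.0, grid)
        k = 2 * np.pi / lam
        h = grid.spacing
        xs = grid.coordinates()[0]
        comps = [np.zeros(grid.shape), np.zeros(grid.shape), np.sin(k * xs)]
        field = self._vector_field(grid, lambda i: comps[i])
        mask = np.ones(grid.shape, dtype=bool)
        c = curl(field, mask, mode="traditional")
        interior = np.zeros(grid.shape, dtype=bool)
        interior[1:-1, 1:-1, 1:-1] = True
        expected = -np.cos(k * xs) * np.sin(k * h) / h
        assert np.allclose(c.values[..., 1][interior].real, expected[interior], atol=1e-12)
        assert np.allclose(c.values[..., 0][interior], 0.0, atol=1e-12)
        assert np.allclose(c.values[..., 2][interior], 0.0, atol=1e-12)

    def test_adaptive_mode_loses_no_in_mask_voxels(self, grid, rng):
        mask = np.zeros(grid.shape, dtype=bool)
        mask[3:21, 3:21, 3:21] = True
        field = self._vector_field(grid, lambda i: rng.normal(size=grid.shape))
        c = curl(field, mask, mode="adaptive")
        assert np.array_equal(c.valid.all(axis=-1), mask)

    def test_modes_agree_in_interior(self, grid, rng):
        mask = np.zeros(grid.shape, dtype=bool)
        mask[3:21, 3:21, 3:21] = True
        field = self._vector_field(grid, lambda i: rng.normal(size=grid.shape))
        ca = curl(field, mask, mode="adaptive")
        ct = curl(field, mask, mode="traditional")
        inner = np.zeros(grid.shape, dtype=bool)
        inner[4:20, 4:20, 4:20] = True
        assert np.allclose(ca.values[inner], ct.values[inner], atol=1e-12)

    def test_two_d_convention_zeroes_z_terms(self, grid, rng):
        # slicewise 2-D data: u_z = 0 and all z-derivatives zero, so only
        # curl_z = du_y/dx - du_x/dy survives
        ux = rng.normal(size=grid.shape)
        uy = rng.normal(size=grid.shape)
        comps = [ux, uy, rng.normal(size=grid.shape)]  # u_z content must be ignored
        field = self._vector_field(grid, lambda i: comps[i])
        mask = np.ones(grid.shape, dtype=bool)
        c = curl(field, mask, mode="traditional", two_d=True)
        assert np.allclose(c.values[..., 0], 0.0, atol=1e-12)
        assert np.allclose(c.values[..., 1], 0.0, atol=1e-12)
        dyx, _ = adaptive_gradient(uy.astype(complex), mask, 0, grid.spacing, "traditional")
        dxy, _ = adaptive_gradient(ux.astype(complex), mask, 1, grid.spacing, "traditional")
        assert np.allclose(c.values[..., 2], dyx - dxy, atol=1e-12)
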