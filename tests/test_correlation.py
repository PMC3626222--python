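"""Plane-wise 2D filtering vs literal 3D correlation, and operator algebra."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import holopattern as hp
from holopattern.correlation import recenter
from holopattern.optics import band_mask

from conftest import (
    make_config,
    random_band_limited_field,
    random_band_limited_kernel,
    random_band_limited_spectrum,
)


def unit_kernel(config):
    """Flat in-band spectrum acting as the identity (band-limited delta)."""
    n = config.nx * config.ny
    vals = np.where(band_mask(config), 1.0 / np.sqrt(n), 0.0).astype(complex)
    return hp.SpectralKernel(vals, config)


def direct_corr2d(u, h):
    """Literal circular cross-correlation sum: c(r) = sum_v u(v) conj(h(v-r)).

    Both arrays are given in the centred spatial convention; the sum runs in
    corner coordinates matching correlate_plane's zero-lag-at-(0,0) output.
    """
    ub = np.fft.ifftshift(u)
    hb = np.fft.ifftshift(h)
    ny, nx = ub.shape
    out = np.zeros((ny, nx), dtype=complex)
    for ry in range(ny):
        for rx in range(nx):
            out[ry, rx] = np.sum(ub * np.conj(np.roll(hb, (ry, rx), (0, 1))))
    return out


class TestCorrelatePlane:
    def test_identity_kernel_returns_band_limited_plane(self, cfg16, rng):
        u = random_band_limited_field(cfg16, rng)
        out = hp.correlate_plane(hp.field_to_spectrum(u), unit_kernel(cfg16), 0.0)
        assert np.allclose(recenter(out), u.values, atol=1e-10)

    def test_matched_filter_peak_equals_template_energy(self, cfg16, rng):
        u = random_band_limited_field(cfg16, rng)
        kernel = hp.SpectralKernel(hp.field_to_spectrum(u).values, cfg16)
        out = hp.correlate_plane(hp.field_to_spectrum(u), kernel, 0.0)
        assert out[0, 0] == pytest.approx(u.energy(), rel=1e-10)
        # zero lag dominates: autocorrelation peak is at the origin
        assert np.abs(out).max() == pytest.approx(abs(out[0, 0]), rel=1e-10)

    def test_correlation_commutes_with_propagation(self, cfg16, rng):
        spec = random_band_limited_spectrum(cfg16, rng)
        kernel = random_band_limited_kernel(cfg16, rng)
        r_at_z = hp.correlate_plane(spec, kernel, 3.0)
        r_at_0 = hp.correlate_plane(spec, kernel, 0.0)
        propagated = hp.propagate(
            hp.ComplexField(recenter(r_at_0), 0.0, cfg16), 3.0
        ).values
        peak = np.abs(r_at_z).max()
        assert np.max(np.abs(recenter(r_at_z) - propagated)) <= 1e-10 * peak

    def test_config_mismatch_rejected(self, cfg16, cfg8, rng):
        spec = random_band_limited_spectrum(cfg16, rng)
        kernel = random_band_limited_kernel(cfg8, rng)
        with pytest.raises(ValueError, match="config"):
            hp.correlate_plane(spec, kernel, 0.0)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(dy=st.integers(0, 15), dx=st.integers(0, 15), z=st.floats(-4, 4))
    def test_shift_invariance(self, dy, dx, z):
        cfg = make_config(16, 16)
        rng = np.random.default_rng(7)
        u = random_band_limited_field(cfg, rng)
        kernel = random_band_limited_kernel(cfg, rng)
        base = hp.correlate_plane(hp.field_to_spectrum(u), kernel, z)
        shifted_field = hp.ComplexField(np.roll(u.values, (dy, dx), (0, 1)), 0.0, cfg)
        shifted = hp.correlate_plane(hp.field_to_spectrum(shifted_field), kernel, z)
        assert np.allclose(shifted, np.roll(base, (dy, dx), (0, 1)), atol=1e-9)

    def test_linearity_in_field_conjugate_linearity_in_kernel(self, cfg16, rng):
        s1 = random_band_limited_spectrum(cfg16, rng)
        s2 = random_band_limited_spectrum(cfg16, rng)
        k = random_band_limited_kernel(cfg16, rng)
        a, b = 1.7 - 0.3j, -0.4 + 2.1j
        combo = hp.Spectrum2D(a * s1.values + b * s2.values, cfg16)
        lhs = hp.correlate_plane(combo, k, 1.0)
        rhs = a * hp.correlate_plane(s1, k, 1.0) + b * hp.correlate_plane(s2, k, 1.0)
        assert np.allclose(lhs, rhs, atol=1e-9)
        scaled_k = hp.SpectralKernel(a * k.values, cfg16)
        assert np.allclose(
            hp.correlate_plane(s1, scaled_k, 1.0),
            np.conj(a) * hp.correlate_plane(s1, k, 1.0),
            atol=1e-9,
        )


class TestImpulseResponse:
    def test_unit_kernel_gives_centred_band_limited_delta(self, cfg16):
        h = hp.impulse_response_at(unit_kernel(cfg16), 0.0)
        assert np.argmax(np.abs(h)) == np.ravel_multi_index((8, 8), cfg16.shape)
        assert h[8, 8].real > 0

    def test_energy_independent_of_z(self, cfg16, rng):
        kernel = random_band_limited_kernel(cfg16, rng)
        e0 = np.sum(np.abs(hp.impulse_response_at(kernel, 0.0)) ** 2)
        for z in (-3.0, 1.5, 7.0):
            ez = np.sum(np.abs(hp.impulse_response_at(kernel, z)) ** 2)
            assert abs(ez - e0) / e0 <= 1e-10

    def test_space_domain_correlation_matches_spectral_route(self, cfg16, rng):
        """2D correlation of the plane-z field with h_0 is the 3D output at z."""
        u = random_band_limited_field(cfg16, rng)
        kernel = random_band_limited_kernel(cfg16, rng)
        z = 2.5
        u_z = hp.propagate(u, z)
        h0 = hp.impulse_response_at(kernel, 0.0)
        direct = direct_corr2d(u_z.values, h0)
        spectral = hp.correlate_plane(hp.field_to_spectrum(u), kernel, z)
        peak = np.abs(spectral).max()
        assert np.max(np.abs(direct - spectral)) <= 1e-10 * peak


class TestVolumeCorrelation:
    def test_identity_kernel_returns_volume(self, cfg16, rng):
        u = random_band_limited_field(cfg16, rng)
        vol = hp.reconstruct_volume(u, np.linspace(-2, 2, 5))
        out = hp.correlate_volume(vol, unit_kernel(cfg16))
        for plane_out, plane_in in zip(out.planes, vol.planes):
            assert np.allclose(recenter(plane_out), plane_in.values, atol=1e-10)

    def test_zero_field_gives_zero_output(self, cfg8, rng):
        zero = hp.ComplexField(np.zeros(cfg8.shape), 0.0, cfg8)
        vol = hp.reconstruct_volume(zero, np.linspace(-1, 1, 4))
        out = hp.brute_force_correlate3d(vol, random_band_limited_kernel(cfg8, rng))
        assert np.max(np.abs(out.stack())) == 0.0

    def test_plane_wise_equals_brute_force_3d(self, cfg8, rng):
        u = random_band_limited_field(cfg8, rng)
        vol = hp.reconstruct_volume(u, np.arange(4) * 0.7 - 1.0)
        kernel = random_band_limited_kernel(cfg8, rng)
        fast = hp.correlate_volume(vol, kernel).stack()
        slow = hp.brute_force_correlate3d(vol, kernel).stack()
        assert np.max(np.abs(fast - slow)) <= 1e-8 * np.abs(fast).max()

    def test_brute_force_refuses_large_grids(self, rng):
        cfg = make_config(32, 32)
        u = random_band_limited_field(cfg, rng)
        vol = hp.reconstruct_volume(u, [0.0, 0.5])
        with pytest.raises(ValueError, match="brute-force"):
            hp.brute_force_correlate3d(vol, random_band_limited_kernel(cfg, rng))

    def test_point_source_localized_by_its_template(self, cfg16, rng):
        """Correlating with a point's template peaks at the point's location."""
        point = np.zeros(cfg16.shape, dtype=complex)
        point[8, 8] = 1.0
        template = hp.ComplexField(point, 0.0, cfg16)
        kernel = hp.SpectralKernel(hp.field_to_spectrum(template).values, cfg16)
        shifted = hp.ComplexField(np.roll(point, (3, 5), (0, 1)), 0.0, cfg16)
        vol = hp.reconstruct_volume(
            hp.spectrum_to_field(hp.field_to_spectrum(shifted), 0.0), [0.0, 1.0]
        )
        out = recenter(hp.correlate_volume(vol, kernel).stack())
        iz, iy, ix = np.unravel_index(np.argmax(out[0:1].__abs__()), out[0:1].shape)
        assert (iy, ix) == (8 + 3, 8 + 5)

    def test_empty_volume_rejected(self, cfg16, rng):
        with pytest.raises(ValueError):
            hp.FieldVolume([], [], cfg16)
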