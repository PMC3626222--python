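"""Cascade operators: correlation layer, cubic threshold, modulus, padding."""

import numpy as np
import pytest

import holopattern as hp
from holopattern.correlation import recenter
from holopattern.filters import (
    FilterLayer,
    FilterModel,
    ThresholdCoeffs,
    kernel_on_grid,
    trainable_mask,
)
from holopattern.optics import band_mask
from holopattern.training import _delta_support

from conftest import make_config, random_band_limited_field, random_band_limited_kernel


def literal_correlation_layer(stack_centred, kernel):
    """Eq-style lexicographic oracle: per-plane circular correlation sums.

    The layer operator correlates every plane of the input volume with the
    kernel's reference-plane impulse response, with per-axis circular
    (modulo) indexing; this evaluates those sums explicitly.
    """
    h0 = np.fft.ifftshift(hp.impulse_response_at(kernel, 0.0))
    out = []
    for plane in stack_centred:
        pb = np.fft.ifftshift(plane)
        ny, nx = pb.shape
        o = np.zeros((ny, nx), dtype=complex)
        for ry in range(ny):
            for rx in range(nx):
                acc = 0.0 + 0.0j
                for vy in range(ny):
                    for vx in range(nx):
                        acc += pb[vy, vx] * np.conj(h0[(vy - ry) % ny, (vx - rx) % nx])
                o[ry, rx] = acc
        out.append(o)
    return np.stack(out)


class TestCorrelationOperator:
    def test_delta_kernel_is_identity(self, rng):
        cfg = make_config(8, 8)
        u = random_band_limited_field(cfg, rng)
        vol = hp.reconstruct_volume(u, [0.0, 0.5])
        delta = hp.pad_kernel(_delta_support((8, 8), cfg), cfg.shape, cfg)
        out = hp.apply_correlation_op(vol, delta)
        for got, want in zip(out.planes, vol.planes):
            assert np.allclose(recenter(got), want.values, atol=1e-10)

    def test_matches_literal_lexicographic_sum(self, rng):
        cfg = make_config(4, 4, na=1.4, pitch=0.2)
        u = random_band_limited_field(cfg, rng)
        vol = hp.reconstruct_volume(u, [0.0, 0.4])
        kernel = random_band_limited_kernel(cfg, rng)
        got = hp.apply_correlation_op(vol, kernel).stack()
        want = literal_correlation_layer(vol.stack(), kernel)
        assert np.max(np.abs(got - want)) <= 1e-12 * max(np.abs(want).max(), 1.0)

    def test_shift_commutation(self, rng):
        cfg = make_config(16, 16)
        u = random_band_limited_field(cfg, rng)
        kernel = random_band_limited_kernel(cfg, rng)
        vol = hp.reconstruct_volume(u, [0.0, 1.0])
        base = hp.apply_correlation_op(vol, kernel).stack()
        shifted_plane = hp.ComplexField(np.roll(u.values, (2, 5), (0, 1)), 0.0, cfg)
        svol = hp.reconstruct_volume(shifted_plane, [0.0, 1.0])
        shifted = hp.apply_correlation_op(svol, kernel).stack()
        assert np.allclose(shifted, np.roll(base, (2, 5), (-2, -1)), atol=1e-9)


class TestThresholdAndModulus:
    @pytest.mark.parametrize(
        "coeffs,x,expected",
        [
            ((0, 0, 1, 0), 2.0 + 1.0j, 2.0 + 1.0j),  # identity
            ((0, 0, 0, 3.5j), -7.0, 3.5j),  # constant
            ((1, 1, 1, 1), 2.0, 15.0),  # direct cubic evaluation
        ],
    )
    def test_threshold_pointwise(self, coeffs, x, expected):
        out = hp.apply_threshold(np.full((2, 2, 2), x, dtype=complex), ThresholdCoeffs(*coeffs))
        assert np.allclose(out, expected)

    def test_modulus_examples_and_nonnegativity(self, rng):
        assert hp.apply_modulus(np.array(1j)) == pytest.approx(1.0)
        assert hp.apply_modulus(np.array(3 + 4j)) == pytest.approx(25.0)
        x = rng.standard_normal((3, 4, 4)) + 1j * rng.standard_normal((3, 4, 4))
        assert np.all(hp.apply_modulus(x) >= 0)


class TestPadding:
    def test_pad_then_unpad_is_identity(self, rng):
        cfg = make_config(32, 32)
        support = rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16))
        support[~trainable_mask((16, 16), cfg)] = 0.0
        kernel = hp.pad_kernel(support, cfg.shape, cfg)
        assert np.count_nonzero(kernel.values) <= 256
        assert np.array_equal(hp.unpad_kernel(kernel, (16, 16)), support)

    def test_support_larger_than_grid_rejected(self, rng):
        cfg = make_config(8, 8)
        with pytest.raises(ValueError, match="larger"):
            hp.pad_kernel(np.zeros((16, 16), complex), cfg.shape, cfg)

    def test_cross_grid_transfer_preserves_correlation_values(self):
        """A kernel trained on a small grid gives the same peak on a big one.

        The grids are sampled coarsely enough that the aperture circle
        covers the whole Nyquist square, so no band cutoff interferes and
        the spatial zero-padding transfer must be exact.
        """
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # deliberately undersampled
            small = make_config(16, 16, pitch=0.36, na=1.4, n_medium=1.5)
            big = make_config(64, 64, pitch=0.36, na=1.4, n_medium=1.5)
        rod = hp.RodSpec(2.0, 0.8, orientation=30.0)
        tmpl = hp.ComplexField(hp.render_rod(rod, small) - 1.0, 0.0, small)
        kernel_small = hp.SpectralKernel(hp.field_to_spectrum(tmpl).values, small)
        peak_small = hp.correlate_plane(hp.field_to_spectrum(tmpl), kernel_small, 0.0)[0, 0]

        model = FilterModel([FilterLayer(kernel_small.values)], small)
        kernel_big = kernel_on_grid(model, 0, big)
        # the transferred impulse response is the embedded small one
        h_small = hp.impulse_response_at(kernel_small, 0.0)
        h_big = hp.impulse_response_at(kernel_big, 0.0)
        assert np.allclose(h_big[24:40, 24:40], h_small, atol=1e-10)
        outside = h_big.copy()
        outside[24:40, 24:40] = 0.0
        assert np.max(np.abs(outside)) <= 1e-10

        plane_big = hp.ComplexField(hp.render_rod(rod, big) - 1.0, 0.0, big)
        out_big = hp.correlate_plane(hp.field_to_spectrum(plane_big), kernel_big, 0.0)
        assert out_big[0, 0] == pytest.approx(peak_small, rel=1e-9)


class TestFullCascade:
    def test_single_delta_layer_gives_band_limited_intensity(self, rng):
        cfg = make_config(16, 16)
        u = random_band_limited_field(cfg, rng)
        vol = hp.reconstruct_volume(u, [0.0, 0.5, 1.0])
        model = FilterModel([FilterLayer(_delta_support((16, 16), cfg))], cfg)
        out = hp.apply_filter(model, vol)
        want = np.abs(np.fft.ifftshift(vol.stack(), axes=(-2, -1))) ** 2
        assert np.allclose(out, want, atol=1e-10)
        assert np.isrealobj(out) and np.all(out >= 0)

    def test_linear_limit_reduces_to_squared_correlation(self, rng):
        cfg = make_config(16, 16)
        u = random_band_limited_field(cfg, rng)
        vol = hp.reconstruct_volume(u, [-1.0, 0.0, 1.0])
        support = rng.standard_normal((8, 8)) + 1j * rng.standard_normal((8, 8))
        model = FilterModel([FilterLayer(support, ThresholdCoeffs.identity())], cfg)
        out = hp.apply_filter(model, vol)
        corr = hp.correlate_volume(vol, model.kernel(0)).stack()
        assert np.allclose(out, np.abs(corr) ** 2, atol=1e-10)

    def test_two_layer_cascade_matches_manual_composition(self, rng):
        cfg = make_config(8, 8)
        u = random_band_limited_field(cfg, rng)
        vol = hp.reconstruct_volume(u, [0.0, 0.6])
        sup1 = rng.standard_normal((8, 8)) + 1j * rng.standard_normal((8, 8))
        sup2 = rng.standard_normal((8, 8)) + 1j * rng.standard_normal((8, 8))
        c1 = ThresholdCoeffs(0.1, -0.2j, 0.9, 0.05)
        c2 = ThresholdCoeffs(0.0, 0.3, 1.1j, -0.1)
        model = FilterModel([FilterLayer(sup1, c1), FilterLayer(sup2, c2)], cfg)
        got = hp.apply_filter(model, vol)

        # manual composition through the literal per-plane correlation oracle
        k1, k2 = model.kernel(0), model.kernel(1)
        s = literal_correlation_layer(vol.stack(), k1)
        s = hp.apply_threshold(s, c1)
        s_centred = np.fft.fftshift(s, axes=(-2, -1))
        s = literal_correlation_layer(s_centred, k2)
        s = hp.apply_threshold(s, c2)
        want = hp.apply_modulus(s)
        assert np.max(np.abs(got - want)) <= 1e-10 * max(want.max(), 1.0)

    def test_cascade_shift_invariance(self, rng):
        cfg = make_config(16, 16)
        u = random_band_limited_field(cfg, rng)
        sup = rng.standard_normal((8, 8)) + 1j * rng.standard_normal((8, 8))
        model = FilterModel(
            [FilterLayer(sup, ThresholdCoeffs(0.2, 0.1, 1.0, 0.0))], cfg
        )
        out = hp.apply_filter(model, hp.reconstruct_volume(u, [0.0, 1.0]))
        shifted_u = hp.ComplexField(np.roll(u.values, (4, 7), (0, 1)), 0.0, cfg)
        out_shifted = hp.apply_filter(model, hp.reconstruct_volume(shifted_u, [0.0, 1.0]))
        assert np.allclose(out_shifted, np.roll(out, (4, 7), (-2, -1)), atol=1e-9)

    def test_empty_model_rejected(self, cfg16):
        with pytest.raises(ValueError, match="at least one layer"):
            FilterModel([], cfg16)
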