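"""Shared fixtures: small optical configs, band-limited fields, trained models."""

from __future__ import annotations

import numpy as np
import pytest

import holopattern as hp
from holopattern.detect import calibrate_threshold
from holopattern.filters import FilterLayer, FilterModel, ThresholdCoeffs
from holopattern.optics import band_mask
from holopattern.training import _delta_support


def make_config(nx=16, ny=16, pitch=0.25, wavelength=0.633, na=1.25, n_medium=1.33):
    return hp.OpticalConfig(
        wavelength=wavelength,
        pixel_pitch=pitch,
        nx=nx,
        ny=ny,
        numerical_aperture=na,
        medium_index=n_medium,
    )


def random_band_limited_spectrum(config, rng):
    """Random complex spectrum obeying the band cutoffs."""
    vals = rng.standard_normal(config.shape) + 1j * rng.standard_normal(config.shape)
    return hp.Spectrum2D(np.where(band_mask(config), vals, 0.0), config)


def random_band_limited_field(config, rng, z=0.0):
    return hp.spectrum_to_field(random_band_limited_spectrum(config, rng), z)


def random_band_limited_kernel(config, rng):
    vals = rng.standard_normal(config.shape) + 1j * rng.standard_normal(config.shape)
    return hp.SpectralKernel(np.where(band_mask(config), vals, 0.0), config)


@pytest.fixture
def cfg16():
    return make_config(16, 16)


@pytest.fixture
def cfg8():
    return make_config(8, 8)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


# ---------------------------------------------------------------------------
# trained models (expensive; shared across the training/detection tests)


@pytest.fixture(scope="session")
def scaled_training_set():
    """6 in-class + 6 out-of-class rod references, 4 orientations, 16x16x8."""
    return hp.build_training_set(
        n_inclass=6, n_outclass=6, volume_shape=(16, 16, 8), rotations=4, rng_seed=42
    )


@pytest.fixture(scope="session")
def matched_filter_1layer(scaled_training_set):
    return hp.matched_filter_model(scaled_training_set, kernel_extent=(16, 16), n_layers=1)


@pytest.fixture(scope="session")
def trained_1layer(scaled_training_set, matched_filter_1layer):
    """One-layer model annealed from the matched-filter warm start (fixed seed)."""
    model, trace = hp.anneal(
        matched_filter_1layer,
        scaled_training_set,
        hp.AnnealSchedule(seed=1),
        train_thresholds=True,
    )
    return model, trace


@pytest.fixture(scope="session")
def trained_2layer(scaled_training_set, trained_1layer):
    """The one-layer model extended with an identity second layer and re-annealed."""
    m1, _ = trained_1layer
    ts = scaled_training_set
    start = FilterModel(
        [
            FilterLayer(m1.layers[0].support.copy(), m1.layers[0].coeffs),
            FilterLayer(_delta_support((16, 16), ts.config), ThresholdCoeffs.identity()),
        ],
        ts.config,
    )
    model, trace = hp.anneal(
        start,
        ts,
        hp.AnnealSchedule(t_initial=0.1, steps_per_temperature=100, seed=7),
        train_thresholds=True,
    )
    stats = hp.evaluate(model, ts)
    threshold, calib = calibrate_threshold(model)
    stats.update(calib)
    stats["detection_threshold"] = threshold
    model.stats = stats
    return model, trace
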