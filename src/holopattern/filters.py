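"""Trainable nonlinear correlation-filter cascade.

The filter is a cascade ``M T_i H_i``: per layer a correlation ``H`` with a
2D spectral kernel, followed by a pointwise cubic-polynomial threshold
``T x = a x**3 + b x**2 + c x + d`` acting on complex values, and after the
last layer a squared-modulus stage ``M x = |x|**2`` producing the real,
nonnegative output intensity.

Each layer's kernel is a small trainable spectral support (16 x 16 by
default) embedded centred in the full spectral grid — zero-padding the
kernel to the image size, which keeps the trainable parameter count small
and controls edge effects.  The kernel is 2D; its z behaviour on a
propagating input is the derived propagation phase (see
:mod:`holopattern.correlation`), so the cascade correlates every plane of
the input volume with the kernel's reference-plane impulse response.  For a
reconstructed (propagating) field volume this is exactly one plane of the
full 3D correlation per z; for the post-threshold volumes deeper in the
cascade — no longer propagating fields — it is the defining sequential-2D
behaviour of the cascade.

Internally the cascade works on corner-convention arrays (zero lag at flat
index 0), matching the training objective's designated peak element.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .correlation import CorrelationVolume, SpectralKernel, correlate_volume
from .optics import FieldVolume, OpticalConfig, band_mask

__all__ = [
    "ThresholdCoeffs",
    "FilterLayer",
    "FilterModel",
    "pad_kernel",
    "unpad_kernel",
    "kernel_on_grid",
    "apply_correlation_op",
    "apply_threshold",
    "apply_modulus",
    "apply_filter",
    "trainable_mask",
]


@dataclass
class ThresholdCoeffs:
    """Coefficients of the pointwise cubic threshold ``a x^3 + b x^2 + c x + d``."""

    a: complex = 0.0
    b: complex = 0.0
    c: complex = 1.0
    d: complex = 0.0

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if not np.isfinite(complex(v)):
                raise ValueError("threshold coefficients must be finite")

    @classmethod
    def identity(cls) -> "ThresholdCoeffs":
        return cls(0.0, 0.0, 1.0, 0.0)

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c, self.d], dtype=np.complex128)

    def is_identity(self) -> bool:
        return bool(np.allclose(self.as_array(), [0, 0, 1, 0]))


@dataclass
class FilterLayer:
    """One cascade layer: trainable spectral support + threshold coefficients."""

    support: np.ndarray
    coeffs: ThresholdCoeffs = field(default_factory=ThresholdCoeffs.identity)

    def __post_init__(self) -> None:
        self.support = np.asarray(self.support, dtype=np.complex128)
        if self.support.ndim != 2:
            raise ValueError("kernel support must be 2D")


@dataclass
class FilterModel:
    """Trainable nonlinear filter: ordered layers tied to a training grid."""

    layers: list[FilterLayer]
    config: OpticalConfig
    stats: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.layers) < 1:
            raise ValueError("model needs at least one layer")
        ky, kx = self.kernel_extent
        if ky > self.config.ny or kx > self.config.nx:
            raise ValueError("kernel support larger than the grid")

    @property
    def kernel_extent(self) -> tuple[int, int]:
        return self.layers[0].support.shape  # type: ignore[return-value]

    def kernel(self, i: int) -> SpectralKernel:
        """Full-grid spectral kernel of layer ``i`` on the training grid."""
        return pad_kernel(self.layers[i].support, self.config.shape, self.config)


def _support_slices(extent: tuple[int, int], target: tuple[int, int]):
    ey, ex = extent
    ty, tx = target
    y0 = ty // 2 - ey // 2
    x0 = tx // 2 - ex // 2
    return slice(y0, y0 + ey), slice(x0, x0 + ex)


def pad_kernel(
    kernel_small: np.ndarray, target: tuple[int, int], config: OpticalConfig
) -> SpectralKernel:
    """Embed a small spectral support centred in the full spectral grid.

    The support entries are samples of the target grid's central bins (DC
    at ``target // 2``); everything else is zero and the band cutoffs are
    applied.  :func:`unpad_kernel` recovers the in-band support bit-exactly.
    """
    kernel_small = np.asarray(kernel_small, dtype=np.complex128)
    if kernel_small.shape[0] > target[0] or kernel_small.shape[1] > target[1]:
        raise ValueError("kernel support larger than the target grid")
    if target != config.shape:
        raise ValueError("target shape must match config grid")
    full = np.zeros(target, dtype=np.complex128)
    sy, sx = _support_slices(kernel_small.shape, target)
    full[sy, sx] = kernel_small
    return SpectralKernel.from_array(full, config)


def unpad_kernel(kernel: SpectralKernel, extent: tuple[int, int]) -> np.ndarray:
    """Extract the central spectral support block (inverse of :func:`pad_kernel`)."""
    sy, sx = _support_slices(extent, kernel.config.shape)
    return kernel.values[sy, sx].copy()


def kernel_on_grid(model: FilterModel, i: int, target: OpticalConfig) -> SpectralKernel:
    """Transfer layer ``i``'s kernel to another grid of the same pitch.

    The kernel's space-domain impulse response on the training grid is
    zero-padded (centred) to the target grid and transformed back — the
    standard way a small filter kernel is applied to a larger image, which
    preserves the literal correlation values.
    """
    if target == model.config:
        return model.kernel(i)
    if abs(target.pixel_pitch - model.config.pixel_pitch) > 1e-12:
        raise ValueError("kernel transfer requires matching pixel pitch")
    if target.ny < model.config.ny or target.nx < model.config.nx:
        raise ValueError("target grid smaller than the training grid")
    from .optics import fft2c, ifft2c  # local import to avoid cycle noise

    h = ifft2c(model.kernel(i).values)
    big = np.zeros(target.shape, dtype=np.complex128)
    sy, sx = _support_slices(h.shape, target.shape)
    big[sy, sx] = h
    return SpectralKernel.from_array(fft2c(big), target)


# ---------------------------------------------------------------------------
# cascade operators


def _corr_stack(stack: np.ndarray, kernel: SpectralKernel) -> np.ndarray:
    """Per-plane circular correlation of a corner-convention stack."""
    n = kernel.config.nx * kernel.config.ny
    k_corner = np.fft.ifftshift(kernel.values)
    x_hat = np.fft.fft2(stack, norm="ortho")
    return np.sqrt(n) * np.fft.ifft2(x_hat * np.conj(k_corner), norm="ortho")


def apply_correlation_op(x: FieldVolume, kernel: SpectralKernel) -> CorrelationVolume:
    """Correlation layer operator on a reconstructed field volume."""
    return correlate_volume(x, kernel)


def apply_threshold(x: np.ndarray, coeffs: ThresholdCoeffs) -> np.ndarray:
    """Elementwise cubic threshold on complex values."""
    x = np.asarray(x)
    return coeffs.a * x**3 + coeffs.b * x**2 + coeffs.c * x + coeffs.d


def apply_modulus(x: np.ndarray) -> np.ndarray:
    """Elementwise squared modulus (output intensity); real and >= 0."""
    return np.abs(np.asarray(x)) ** 2


def apply_filter(model: FilterModel, x: FieldVolume) -> np.ndarray:
    """Run the full cascade on a field volume.

    Returns the real nonnegative output volume ``(nz, ny, nx)`` in the
    corner (zero-lag-at-flat-index-0) convention.  If the input grid differs
    from the training grid the kernels are transferred with
    :func:`kernel_on_grid` (pitch must match).
    """
    if len(model.layers) == 0:
        raise ValueError("empty model")
    cfg = x.config
    kernels = [
        kernel_on_grid(model, i, cfg) if cfg != model.config else model.kernel(i)
        for i in range(len(model.layers))
    ]
    stack = np.fft.ifftshift(x.stack(), axes=(-2, -1))
    for layer, kern in zip(model.layers, kernels):
        stack = _corr_stack(stack, kern)
        stack = apply_threshold(stack, layer.coeffs)
    return apply_modulus(stack)


def trainable_mask(extent: tuple[int, int], config: OpticalConfig) -> np.ndarray:
    """Boolean mask of support entries that survive the band cutoffs.

    Support entries falling outside the propagating/aperture band are
    forced to zero by :func:`pad_kernel` and are therefore dead parameters;
    the trainer only perturbs the live ones.
    """
    sy, sx = _support_slices(extent, config.shape)
    return band_mask(config)[sy, sx].copy()
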