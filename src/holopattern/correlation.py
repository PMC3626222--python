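"""3D correlation of propagating fields via plane-wise 2D filtering.

Because a monochromatic field's 3D spectrum lives on the Ewald sphere, a
general 3D correlation filter applied to such a field has only 2D degrees
of freedom: the restriction ``H(kx, ky)`` of its transfer function to the
sphere.  One plane ``z`` of the 3D correlation output is then the inverse
2D transform of ``U(kx,ky) H*(kx,ky) exp(+j 2 pi z k_z)`` — a 2D circular
correlation of the reconstructed field in that plane with the kernel's
reference-plane impulse response.  :func:`correlate_volume` implements that
fast route; :func:`brute_force_correlate3d` evaluates the defining 3D
space-domain sum directly and serves as the independent oracle for the
equivalence.

Lag conventions: correlation outputs put zero lag at array index ``(0, 0)``
(:func:`recenter` moves it to the centre for display); the impulse response
is returned in the centred spatial convention shared with
:mod:`holopattern.optics`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .optics import (
    ComplexField,
    FieldVolume,
    OpticalConfig,
    Spectrum2D,
    band_mask,
    fft2c,
    field_to_spectrum,
    ifft2c,
    kz_grid,
)

__all__ = [
    "SpectralKernel",
    "CorrelationVolume",
    "correlate_plane",
    "impulse_response_at",
    "correlate_volume",
    "brute_force_correlate3d",
    "recenter",
]

#: largest grid the brute-force oracle will accept (nz, ny, nx)
_BRUTE_FORCE_LIMIT = (8, 16, 16)


@dataclass
class SpectralKernel:
    """2D spectral filter kernel defined at a reference plane.

    The kernel's z dependence is never stored: the impulse response at any
    plane is derived by propagation (see :func:`impulse_response_at`), which
    is exactly the statement that a 3D filter acting on a propagating field
    has only 2D degrees of freedom.
    """

    values: np.ndarray
    config: OpticalConfig

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        if self.values.shape != self.config.shape:
            raise ValueError("kernel shape does not match config")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("kernel values must be finite")
        if np.any(self.values[~band_mask(self.config)] != 0):
            raise ValueError("kernel has nonzero entries outside the band cutoffs")

    @classmethod
    def from_array(cls, values: np.ndarray, config: OpticalConfig) -> "SpectralKernel":
        """Build a kernel, zeroing anything outside the band cutoffs."""
        values = np.where(band_mask(config), np.asarray(values, dtype=np.complex128), 0.0)
        return cls(values, config)

    def energy(self) -> float:
        return float(np.sum(np.abs(self.values) ** 2))


@dataclass
class CorrelationVolume:
    """Stack of correlation output planes ``R_z`` on a z grid."""

    planes: list[np.ndarray]
    z_values: np.ndarray
    config: OpticalConfig

    def __post_init__(self) -> None:
        self.z_values = np.asarray(self.z_values, dtype=float)
        if len(self.planes) != len(self.z_values):
            raise ValueError("planes and z_values lengths differ")
        shape = self.config.shape
        for p in self.planes:
            if p.shape != shape:
                raise ValueError("correlation plane shape mismatch")
            if not np.all(np.isfinite(p)):
                raise ValueError("correlation values must be finite")

    def stack(self) -> np.ndarray:
        return np.stack(self.planes)

    def __len__(self) -> int:
        return len(self.planes)


def _phase(config: OpticalConfig, z: float) -> np.ndarray:
    kz = kz_grid(config).filled(0.0)
    return np.where(band_mask(config), np.exp(2j * np.pi * z * kz), 0.0)


def correlate_plane(spec: Spectrum2D, kernel: SpectralKernel, z: float) -> np.ndarray:
    """One plane of the 3D correlation of a propagating field.

    Computes the inverse 2D transform of ``U . H* . exp(+j 2 pi z k_z)``,
    scaled so the result equals the literal circular cross-correlation sum
    ``sum_v u_z(v) conj(h_0(v - r))`` with zero lag at index (0, 0).
    """
    if spec.config != kernel.config:
        raise ValueError("spectrum and kernel configs differ")
    n = spec.config.nx * spec.config.ny
    prod = spec.values * np.conj(kernel.values) * _phase(spec.config, z)
    return np.fft.ifftshift(np.sqrt(n) * ifft2c(prod))


def impulse_response_at(kernel: SpectralKernel, z: float) -> np.ndarray:
    """Space-domain impulse response of the 3D filter in the plane ``z``.

    The 3D impulse response of a kernel restricted to the Ewald sphere is
    itself a propagating field; its plane at ``z`` is the phase-propagated
    inverse transform of the 2D kernel.  Returned in the centred spatial
    convention; ``sum |h_z|**2`` is independent of z (the z dependence is a
    pure phase).
    """
    return ifft2c(kernel.values * _phase(kernel.config, z))


def correlate_volume(volume: FieldVolume, kernel: SpectralKernel) -> CorrelationVolume:
    """3D correlation of a reconstructed field volume, plane by plane.

    One shared spectrum is taken from the volume's first plane (any plane of
    a consistent volume gives the same spectrum); each output plane is then
    a single :func:`correlate_plane` call.
    """
    if len(volume) == 0:
        raise ValueError("empty volume")
    if volume.config != kernel.config:
        raise ValueError("volume and kernel configs differ")
    spec = field_to_spectrum(volume.planes[0])
    planes = [correlate_plane(spec, kernel, float(z)) for z in volume.z_values]
    return CorrelationVolume(planes, volume.z_values, volume.config)


def brute_force_correlate3d(volume: FieldVolume, kernel: SpectralKernel) -> CorrelationVolume:
    """Direct space-domain 3D correlation; the test oracle for small grids.

    Builds the 3D impulse response by evaluating :func:`impulse_response_at`
    at every axial lag realised on the grid and accumulates the explicit
    triple sum of the defining correlation integral: circular in x and y
    (FFT-native boundary), while the axial shift of the impulse response is
    evaluated by propagation — the impulse response of a propagating kernel
    is defined at every z, so no artificial axial wrap is introduced.  The
    axial sum over the volume's ``nz`` planes is normalised by ``nz``.

    Refuses grids larger than 16 x 16 x 8 (this is an oracle, not a fast
    path).
    """
    if len(volume) == 0:
        raise ValueError("empty volume")
    if volume.config != kernel.config:
        raise ValueError("volume and kernel configs differ")
    nz, (ny, nx) = len(volume), volume.config.shape
    mz, my, mx = _BRUTE_FORCE_LIMIT
    if nz > mz or ny > my or nx > mx:
        raise ValueError(f"grid {nz}x{ny}x{nx} exceeds the brute-force oracle limit")
    dz = np.diff(volume.z_values)
    if nz > 1 and not np.allclose(dz, dz[0], rtol=1e-12, atol=1e-12):
        raise ValueError("brute-force oracle requires a uniform z grid")
    step = float(dz[0]) if nz > 1 else 0.0

    # corner-convention copies of field planes and impulse-response planes
    u = [np.fft.ifftshift(p.values) for p in volume.planes]
    h = {
        d: np.fft.ifftshift(impulse_response_at(kernel, d * step))
        for d in range(-(nz - 1), nz)
    }

    out = []
    for p in range(nz):
        acc = np.zeros(volume.config.shape, dtype=np.complex128)
        for m in range(nz):
            hk = h[m - p]
            # explicit circular 2D correlation: c(r) = sum_v u(v) h*(v - r)
            for ry in range(ny):
                for rx in range(nx):
                    acc[ry, rx] += np.sum(u[m] * np.conj(np.roll(hk, (ry, rx), (0, 1))))
        out.append(acc / nz)
    return CorrelationVolume(out, volume.z_values, volume.config)


def recenter(arr: np.ndarray) -> np.ndarray:
    """Move zero lag from index (0, 0) to the array centre (display helper)."""
    return np.fft.fftshift(arr, axes=(-2, -1))
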