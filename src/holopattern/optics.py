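"""Monochromatic complex fields and angular-spectrum propagation.

A monochromatic field in a uniform dielectric is a superposition of plane
waves confined to the Ewald sphere ``|k| = n/lambda`` (wavenumber convention
``k = 1/lambda``, i.e. spatial frequencies in cycles per micron, no 2*pi).
Knowing the complex amplitude in one transverse plane therefore determines
the whole 3D field: the 2D spectrum of that plane, referred to the sphere,
is multiplied by the pure phase ``exp(+j 2 pi z k_z)`` to reach any parallel
plane.  This module implements that machinery on sampled grids.

Conventions (fixed package-wide):

* forward DFT kernel ``exp(-j 2 pi k . r)``; unitary normalisation
  (``norm="ortho"``) so Parseval holds exactly;
* spectral and spatial grids are centred: DC / the spatial origin sit at
  index ``(ny // 2, nx // 2)``;
* x is the fastest axis, arrays are indexed ``[y, x]`` (volumes
  ``[z, y, x]``); z increases away from the objective; lengths in microns;
* boundary conditions are circular (FFT-native) — callers that need linear
  behaviour must pad;
* only the positive ``k_z`` root (forward-propagating flux) is kept, and
  evanescent components are hard-zeroed, as is everything outside the
  numerical-aperture circle ``NA / lambda`` (the objective's band limit).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OpticalConfig",
    "ComplexField",
    "Spectrum2D",
    "FieldVolume",
    "fft2c",
    "ifft2c",
    "kz_grid",
    "band_mask",
    "field_to_spectrum",
    "spectrum_to_field",
    "propagate",
    "reconstruct_volume",
]


def fft2c(x: np.ndarray) -> np.ndarray:
    """Centred unitary 2D DFT over the last two axes (DC at centre)."""
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(x, axes=(-2, -1)), norm="ortho"),
        axes=(-2, -1),
    )


def ifft2c(x: np.ndarray) -> np.ndarray:
    """Inverse of :func:`fft2c`."""
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(x, axes=(-2, -1)), norm="ortho"),
        axes=(-2, -1),
    )


@dataclass(frozen=True)
class OpticalConfig:
    """Optical and sampling configuration governing all spectral grids.

    Parameters
    ----------
    wavelength : float
        Vacuum wavelength in microns.
    pixel_pitch : float
        Object-plane sample spacing in microns.
    nx, ny : int
        Samples per plane along x and y.
    numerical_aperture : float
        NA of the objective; sets the recorded band limit ``NA/lambda``.
    medium_index : float
        Refractive index of the propagation medium (>= 1); sets the
        evanescent cutoff ``n/lambda``.
    """

    wavelength: float
    pixel_pitch: float
    nx: int
    ny: int
    numerical_aperture: float = 1.25
    medium_index: float = 1.33

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")
        if self.nx <= 0 or self.ny <= 0:
            raise ValueError("grid size must be positive")
        if not (0 < self.numerical_aperture <= 1.5):
            raise ValueError("numerical_aperture must lie in (0, 1.5]")
        if self.medium_index < 1:
            raise ValueError("medium_index must be >= 1")
        nyq = self.wavelength / (2 * self.numerical_aperture)
        if self.pixel_pitch > nyq:
            warnings.warn(
                f"pixel_pitch={self.pixel_pitch} um undersamples the NA-limited "
                f"band (Nyquist pitch {nyq:.4g} um): the grid, not the aperture, "
                "will truncate the spectrum",
                stacklevel=2,
            )

    @property
    def shape(self) -> tuple[int, int]:
        """(ny, nx) array shape of one plane."""
        return (self.ny, self.nx)

    def kx(self) -> np.ndarray:
        """Centred 1D grid of transverse frequencies along x (cycles/um)."""
        return np.fft.fftshift(np.fft.fftfreq(self.nx, d=self.pixel_pitch))

    def ky(self) -> np.ndarray:
        return np.fft.fftshift(np.fft.fftfreq(self.ny, d=self.pixel_pitch))

    def k_transverse_sq(self) -> np.ndarray:
        """2D grid of ``kx**2 + ky**2`` (ny, nx)."""
        kx = self.kx()[None, :]
        ky = self.ky()[:, None]
        return kx * kx + ky * ky

    def x(self) -> np.ndarray:
        """Centred 1D spatial grid along x in microns (origin at nx//2)."""
        return (np.arange(self.nx) - self.nx // 2) * self.pixel_pitch

    def y(self) -> np.ndarray:
        return (np.arange(self.ny) - self.ny // 2) * self.pixel_pitch


def kz_grid(config: OpticalConfig) -> np.ma.MaskedArray:
    """Axial frequency ``k_z = sqrt((n/lambda)**2 - kx**2 - ky**2)``.

    Returns a masked array over the centred ``(ky, kx)`` grid; the mask
    flags the evanescent region (negative radicand), where no propagating
    plane wave exists.  Only the positive root is returned.
    """
    radicand = (config.medium_index / config.wavelength) ** 2 - config.k_transverse_sq()
    evanescent = radicand < 0
    kz = np.sqrt(np.where(evanescent, 0.0, radicand))
    return np.ma.MaskedArray(kz, mask=evanescent)


def band_mask(config: OpticalConfig) -> np.ndarray:
    """Boolean grid of frequencies kept after both hard cutoffs.

    True where ``kx**2+ky**2`` is within both the propagating band
    (``(n/lambda)**2``) and the aperture band (``(NA/lambda)**2``).
    """
    kt2 = config.k_transverse_sq()
    prop = kt2 <= (config.medium_index / config.wavelength) ** 2
    aperture = kt2 <= (config.numerical_aperture / config.wavelength) ** 2
    return prop & aperture


@dataclass
class ComplexField:
    """One 2D complex-amplitude plane at axial position ``z``."""

    values: np.ndarray
    z: float
    config: OpticalConfig

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        if self.values.shape != self.config.shape:
            raise ValueError(
                f"field shape {self.values.shape} does not match config {self.config.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field values must be finite")

    def energy(self) -> float:
        """Total intensity ``sum |u|**2`` (grid units)."""
        return float(np.sum(np.abs(self.values) ** 2))


@dataclass
class Spectrum2D:
    """Plane-wave spectrum referred to the Ewald-sphere convention.

    ``values[ky, kx]`` is the complex weight of the plane wave with
    transverse frequency ``(kx, ky)`` and axial frequency ``k_z(kx, ky)``,
    with the propagation phase stripped so that the spectrum is independent
    of the plane it was measured in; ``reference_z`` records that plane.
    Entries outside the propagating or aperture band are exactly zero.
    """

    values: np.ndarray
    config: OpticalConfig
    reference_z: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        if self.values.shape != self.config.shape:
            raise ValueError("spectrum shape does not match config")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectrum values must be finite")
        if np.any(self.values[~band_mask(self.config)] != 0):
            raise ValueError("spectrum has nonzero entries outside the band cutoffs")

    def energy(self) -> float:
        return float(np.sum(np.abs(self.values) ** 2))


@dataclass
class FieldVolume:
    """Ordered stack of :class:`ComplexField` planes on a common z grid."""

    planes: list[ComplexField]
    z_values: np.ndarray
    config: OpticalConfig = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.z_values = np.asarray(self.z_values, dtype=float)
        if len(self.planes) != len(self.z_values):
            raise ValueError("planes and z_values lengths differ")
        if len(self.planes) == 0:
            raise ValueError("empty volume")
        if np.any(np.diff(self.z_values) <= 0):
            raise ValueError("z_values must be strictly increasing")
        if self.config is None:
            self.config = self.planes[0].config
        for p in self.planes:
            if p.config != self.config:
                raise ValueError("all planes must share one config")

    def stack(self) -> np.ndarray:
        """Volume as a (nz, ny, nx) complex array."""
        return np.stack([p.values for p in self.planes])

    def __len__(self) -> int:
        return len(self.planes)


def _phase(config: OpticalConfig, z: float) -> np.ndarray:
    """In-band propagation phase ``exp(+j 2 pi z k_z)`` (zero outside band)."""
    kz = kz_grid(config).filled(0.0)
    mask = band_mask(config)
    return np.where(mask, np.exp(2j * np.pi * z * kz), 0.0)


def field_to_spectrum(plane: ComplexField) -> Spectrum2D:
    """Plane-wave spectrum of a single measured plane.

    The 2D DFT of the plane is multiplied by ``exp(-j 2 pi z k_z)`` so the
    result is the sphere-referred spectrum, and the aperture/evanescent
    cutoffs are applied.  Inverted by :func:`spectrum_to_field` at the same
    z up to the cutoff losses.
    """
    u_hat = fft2c(plane.values)
    values = u_hat * _phase(plane.config, -plane.z)
    return Spectrum2D(values, plane.config, reference_z=plane.z)


def spectrum_to_field(spec: Spectrum2D, z: float) -> ComplexField:
    """Complex amplitude in the parallel plane at axial position ``z``."""
    u = ifft2c(spec.values * _phase(spec.config, z))
    return ComplexField(u, z, spec.config)


def propagate(plane: ComplexField, z: float) -> ComplexField:
    """Propagate a plane to absolute axial position ``z`` (band-limited)."""
    return spectrum_to_field(field_to_spectrum(plane), z)


def reconstruct_volume(plane: ComplexField, z_values) -> FieldVolume:
    """Reconstruct the 3D field from one plane over a z grid.

    One spectrum is computed from the input plane; each output plane is a
    phase-propagated inverse transform of that shared spectrum, so the
    planes are mutually consistent by construction.
    """
    z_values = np.asarray(z_values, dtype=float)
    if z_values.size == 0:
        raise ValueError("no reconstruction requested: z_values is empty")
    if np.any(np.diff(z_values) <= 0):
        raise ValueError("z_values must be strictly increasing")
    spec = field_to_spectrum(plane)
    planes = [spectrum_to_field(spec, float(z)) for z in z_values]
    return FieldVolume(planes, z_values, plane.config)
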