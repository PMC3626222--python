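"""Synthetic microorganism fields and simulated off-axis holograms.

Emulates a transmission holographic-microscopy experiment on two classes
of rod-shaped scatterers (E. coli-like targets and slightly smaller
Pantoea-like distractors) suspended at random 3D positions and in-plane
orientations in a flow cell.  A rod is a weak amplitude/phase object — a
smoothed capsule (rounded rectangle) of complex transmittance on a unit
background — and multiple rods compose in first-Born fashion: each rod's
scattered perturbation is propagated to the focal plane and summed on the
unit background, consistent with the single-scattering assumption of
linear holographic reconstruction.

The rod dimensions and optical contrast are synthetic defaults (in-class
2.0 x 0.8 um, out-of-class 1.4 x 0.7 um, amplitude transmittance 0.95,
phase shift 0.5 rad for both classes) chosen to be biologically plausible;
they are exposed on :class:`RodSpec` and stamped into generated metadata.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .optics import (
    ComplexField,
    OpticalConfig,
    band_mask,
    fft2c,
    ifft2c,
    propagate,
    reconstruct_volume,
)
from .training import TrainingSet, desired_output_for

__all__ = [
    "RodSpec",
    "ScenePlacement",
    "IN_CLASS_ROD",
    "OUT_CLASS_ROD",
    "render_rod",
    "render_scene",
    "simulate_hologram",
    "demodulate_hologram",
    "random_scene",
    "build_training_set",
]


@dataclass(frozen=True)
class RodSpec:
    """Geometry and optical contrast of one rod-shaped scatterer."""

    length: float  # um, tip to tip
    width: float  # um
    orientation: float = 0.0  # degrees, in-plane
    amplitude_transmittance: float = 0.95
    phase_shift: float = 0.5  # radians
    in_class: bool = True

    def __post_init__(self) -> None:
        if not (self.length >= self.width > 0):
            raise ValueError("rod requires length >= width > 0")
        if not (0 <= self.amplitude_transmittance <= 1):
            raise ValueError("amplitude_transmittance must lie in [0, 1]")

    def bounding_radius(self) -> float:
        return self.length / 2


#: default target (E. coli-like) and distractor (Pantoea-like) rods
IN_CLASS_ROD = RodSpec(length=2.0, width=0.8, in_class=True)
OUT_CLASS_ROD = RodSpec(length=1.4, width=0.7, in_class=False)


@dataclass
class ScenePlacement:
    """Rods with 3D positions inside a bounded field of view."""

    rods: list[tuple[RodSpec, tuple[float, float, float]]]
    config: OpticalConfig
    field_extent: tuple[float, float] = (72.0, 72.0)  # um x um
    z_range: tuple[float, float] = (-8.0, 8.0)
    #: rods closer than this in z may overlap in x-y without conflict
    min_z_clearance: float = 2.0

    def __post_init__(self) -> None:
        ex, ey = self.field_extent
        for spec, (x, y, z) in self.rods:
            r = spec.bounding_radius()
            if abs(x) + r > ex / 2 or abs(y) + r > ey / 2:
                raise ValueError(f"rod at ({x}, {y}) leaves the field extent")
            if not (self.z_range[0] <= z <= self.z_range[1]):
                raise ValueError(f"rod z={z} outside z range {self.z_range}")
        for i in range(len(self.rods)):
            for j in range(i + 1, len(self.rods)):
                si, (xi, yi, zi) = self.rods[i]
                sj, (xj, yj, zj) = self.rods[j]
                if abs(zi - zj) >= self.min_z_clearance:
                    continue
                if math.hypot(xi - xj, yi - yj) < si.bounding_radius() + sj.bounding_radius():
                    raise ValueError(f"rods {i} and {j} overlap")


def render_rod(
    spec: RodSpec, config: OpticalConfig, center: tuple[float, float] = (0.0, 0.0)
) -> np.ndarray:
    """Complex object (transmittance) function of one rod.

    An anti-aliased capsule — points within ``width/2`` of the central
    segment of length ``length - width`` — rotated to ``orientation``,
    with transmittance ``A exp(j phi)`` inside and 1 outside (transmission
    mode).  The anti-aliasing is a one-pixel linear ramp on the signed
    distance to the capsule boundary.
    """
    if spec.length > min(config.nx, config.ny) * config.pixel_pitch:
        raise ValueError("rod larger than the grid")
    x = config.x()[None, :] - center[0]
    y = config.y()[:, None] - center[1]
    th = math.radians(spec.orientation)
    xr = math.cos(th) * x + math.sin(th) * y
    yr = -math.sin(th) * x + math.cos(th) * y
    half_seg = max(spec.length - spec.width, 0.0) / 2
    dist = np.hypot(xr - np.clip(xr, -half_seg, half_seg), yr)
    signed = spec.width / 2 - dist  # >0 inside
    support = np.clip(signed / config.pixel_pitch + 0.5, 0.0, 1.0)
    t_inside = spec.amplitude_transmittance * np.exp(1j * spec.phase_shift)
    return 1.0 + (t_inside - 1.0) * support


def render_scene(placement: ScenePlacement) -> ComplexField:
    """Complex amplitude in the focal plane (z = 0) of the whole scene.

    Each rod's object function is imprinted on a unit plane wave at its own
    z, its scattered perturbation propagated to z = 0, and the
    perturbations summed on the unit background (first Born).
    """
    cfg = placement.config
    total = np.zeros(cfg.shape, dtype=np.complex128)
    for spec, (x, y, z) in placement.rods:
        obj = render_rod(spec, cfg, center=(x, y))
        pert = ComplexField(obj - 1.0, z, cfg)
        total += propagate(pert, 0.0).values
    return ComplexField(1.0 + total, 0.0, cfg)


def _check_carrier(config: OpticalConfig, carrier: tuple[float, float]) -> None:
    fx, fy = carrier
    bandlim = config.numerical_aperture / config.wavelength
    nyq = 1.0 / (2 * config.pixel_pitch)
    if math.hypot(fx, fy) <= 2 * bandlim:
        raise ValueError(
            f"carrier |f|={math.hypot(fx, fy):.3g} not separable from the object band "
            f"(needs > 2 NA/lambda = {2 * bandlim:.3g} cycles/um)"
        )
    if max(abs(fx), abs(fy)) + bandlim > nyq:
        raise ValueError("carrier plus object band exceeds the Nyquist limit")


def simulate_hologram(
    field_plane: ComplexField,
    carrier: tuple[float, float],
    reference_amplitude: float = 1.0,
    noise_std: float = 0.0,
    shot_noise: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Off-axis interferogram ``|u + r exp(j 2 pi (fx x + fy y))|**2``.

    ``carrier`` is the reference-beam tilt in cycles/um; it must clear the
    object band (``|f| > 2 NA/lambda``) and stay within Nyquist.  Optional
    additive Gaussian intensity noise and Poisson shot noise (defaults
    off).
    """
    cfg = field_plane.config
    _check_carrier(cfg, carrier)
    fx, fy = carrier
    x = cfg.x()[None, :]
    y = cfg.y()[:, None]
    ref = reference_amplitude * np.exp(2j * np.pi * (fx * x + fy * y))
    intensity = np.abs(field_plane.values + ref) ** 2
    if shot_noise or noise_std > 0:
        if rng is None:
            rng = np.random.default_rng()
        if shot_noise:
            intensity = rng.poisson(np.maximum(intensity, 0) * 1e4) / 1e4
        if noise_std > 0:
            intensity = intensity + rng.normal(0.0, noise_std, intensity.shape)
    return intensity


def demodulate_hologram(
    interferogram: np.ndarray,
    carrier: tuple[float, float],
    config: OpticalConfig,
    reference_amplitude: float = 1.0,
) -> ComplexField:
    """Recover the complex field from an off-axis interferogram.

    Fourier side-band extraction: the interferogram is mixed down by the
    conjugate carrier wave (which translates the +1 order to DC), low-pass
    filtered to the NA band, and divided by the reference amplitude.
    Exact (to rounding) whenever the carrier satisfies the separability
    check and the self-interference term ``|u|^2`` clears the band.
    """
    _check_carrier(config, carrier)
    fx, fy = carrier
    x = config.x()[None, :]
    y = config.y()[:, None]
    mixed = np.asarray(interferogram, dtype=np.complex128) * np.exp(
        2j * np.pi * (fx * x + fy * y)
    )
    spec = fft2c(mixed)
    spec[~band_mask(config)] = 0.0
    u = ifft2c(spec) / reference_amplitude
    return ComplexField(u, 0.0, config)


def random_scene(
    config: OpticalConfig,
    n_inclass: int,
    n_outclass: int,
    field_extent: tuple[float, float],
    z_range: tuple[float, float],
    rng: np.random.Generator,
    max_tries: int = 2000,
) -> ScenePlacement:
    """Rejection-sample non-overlapping rods at random positions/orientations."""
    specs = [replace(IN_CLASS_ROD, orientation=0.0)] * n_inclass + [
        replace(OUT_CLASS_ROD, orientation=0.0)
    ] * n_outclass
    placed: list[tuple[RodSpec, tuple[float, float, float]]] = []
    ex, ey = field_extent
    for base in specs:
        spec = replace(base, orientation=float(rng.uniform(0.0, 180.0)))
        r = spec.bounding_radius()
        for _ in range(max_tries):
            x = float(rng.uniform(-(ex / 2 - r), ex / 2 - r))
            y = float(rng.uniform(-(ey / 2 - r), ey / 2 - r))
            z = float(rng.uniform(*z_range))
            ok = all(
                abs(z - pz) >= 2.0
                or math.hypot(x - px, y - py) >= r + ps.bounding_radius() + 1.0
                for ps, (px, py, pz) in placed
            )
            if ok:
                placed.append((spec, (x, y, z)))
                break
        else:
            raise RuntimeError("could not place all rods without overlap")
    return ScenePlacement(placed, config, field_extent, z_range)


def build_training_set(
    n_inclass: int = 25,
    n_outclass: int = 17,
    volume_shape: tuple[int, int, int] = (32, 32, 16),
    rotations: int = 8,
    rng_seed: int = 0,
    config: OpticalConfig | None = None,
    dz: float = 0.5,
    size_jitter: float = 0.0,
) -> TrainingSet:
    """Reference volumes of rotated rods of the two size classes.

    Each reference is a single rod, centred and in focus at the first plane
    of a ``volume_shape = (nx, ny, nz)`` reconstruction (z grid ``0, dz,
    ..., (nz-1) dz``), at an orientation cycling through ``rotations``
    steps of ``180/rotations`` degrees; a uniform ``+-size_jitter``
    relative size perturbation (off by default) can emulate natural size
    variation.
    References are the background-subtracted scattered fields; desired
    outputs are attached per class.
    """
    if n_inclass < 1 or n_outclass < 1:
        raise ValueError("counts must be >= 1")
    nx, ny, nz = volume_shape
    if config is None:
        config = OpticalConfig(wavelength=0.633, pixel_pitch=0.25, nx=nx, ny=ny)
    if config.nx != nx or config.ny != ny:
        raise ValueError("config grid does not match volume_shape")
    if IN_CLASS_ROD.length > min(nx, ny) * config.pixel_pitch:
        raise ValueError("volume_shape too small for the rods")
    rng = np.random.default_rng(rng_seed)
    z_values = np.arange(nz) * dz
    shape = (nz, ny, nx)

    references, labels, desired = [], [], []
    step = 180.0 / rotations
    for in_class, count, base in (
        (True, n_inclass, IN_CLASS_ROD),
        (False, n_outclass, OUT_CLASS_ROD),
    ):
        for i in range(count):
            scale = 1.0 + float(rng.uniform(-size_jitter, size_jitter))
            spec = replace(
                base,
                orientation=(i % rotations) * step,
                length=base.length * scale,
                width=base.width * scale,
                in_class=in_class,
            )
            obj = render_rod(spec, config)
            plane = ComplexField(obj - 1.0, 0.0, config)
            references.append(reconstruct_volume(plane, z_values))
            labels.append(in_class)
            desired.append(desired_output_for(in_class, shape))
    return TrainingSet(references, labels, desired)
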