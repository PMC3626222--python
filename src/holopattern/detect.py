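"""Peak detection and the end-to-end recognition pipeline.

The trained filter turns a reconstructed volume into a real nonnegative
output volume in which targets appear as correlation peaks.  This module
finds those peaks (local maxima above a threshold, greedily pruned to a
minimum separation), converts them to physical coordinates, and provides
the max-intensity projection used to present the volume on a plane.

Detection operates on the *recentred* output volume (zero lag moved to the
array centre), in which a target at scene pixel ``(iy, ix)`` produces its
peak at exactly that pixel, so voxel indices map linearly to microns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .correlation import recenter
from .filters import FilterModel, apply_filter
from .optics import ComplexField, OpticalConfig, reconstruct_volume
from .scenes import ScenePlacement, demodulate_hologram, render_scene, simulate_hologram

__all__ = [
    "Detection",
    "DetectionReport",
    "project_output",
    "find_peaks",
    "run_pipeline",
    "default_threshold",
    "calibrate_threshold",
]


@dataclass(frozen=True)
class Detection:
    """One correlation peak in physical coordinates."""

    x: float  # um
    y: float  # um
    z: float  # um
    score: float  # filter-output intensity at the peak


@dataclass
class DetectionReport:
    """Detections sorted by descending score, plus the parameters used."""

    detections: list[Detection]
    threshold: float
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        scores = [d.score for d in self.detections]
        if any(b > a for a, b in zip(scores, scores[1:])):
            raise ValueError("detections must be sorted by descending score")

    def __len__(self) -> int:
        return len(self.detections)


def project_output(volume: np.ndarray) -> np.ndarray:
    """Per-pixel maximum over z (max-intensity projection)."""
    volume = np.asarray(volume)
    if volume.ndim != 3 or volume.shape[0] == 0:
        raise ValueError("expected a nonempty (nz, ny, nx) volume")
    return volume.max(axis=0)


def find_peaks(
    volume: np.ndarray,
    threshold: float,
    min_separation: int,
    config: OpticalConfig,
    z_values: np.ndarray,
    params: dict | None = None,
) -> DetectionReport:
    """Local maxima above ``threshold``, pruned to ``min_separation`` voxels.

    A voxel is a candidate if it is >= all neighbours in its 3x3x3
    neighbourhood (circular in x and y, clipped in z) and exceeds the
    threshold.  Candidates are ranked by (score desc, lexicographic voxel
    index) and accepted greedily: a candidate within transverse Euclidean
    distance ``min_separation`` (in voxels, measured in the x-y plane) of
    an already-accepted one is dropped, so of two equal nearby peaks the
    lexicographically first survives.  Separation is transverse because a
    defocused target produces secondary maxima along its whole axial
    column (the axial response is far broader than the transverse one);
    distinct objects are resolved in x-y, not in z.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if min_separation <= 0:
        raise ValueError("min_separation must be positive")
    volume = np.asarray(volume, dtype=float)
    z_values = np.asarray(z_values, dtype=float)
    if volume.ndim != 3 or volume.shape[0] != len(z_values):
        raise ValueError("volume/z_values mismatch")

    local_max = volume >= ndimage.maximum_filter(
        volume, size=3, mode=("nearest", "wrap", "wrap")
    )
    cand = np.argwhere(local_max & (volume > threshold))
    order = np.lexsort(
        (cand[:, 2], cand[:, 1], cand[:, 0], -volume[tuple(cand.T)])
    ) if len(cand) else []
    accepted: list[tuple[int, int, int]] = []
    for idx in order:
        iz, iy, ix = map(int, cand[idx])
        if all(
            math.hypot(iy - ay, ix - ax) >= min_separation for _, ay, ax in accepted
        ):
            accepted.append((iz, iy, ix))

    dets = [
        Detection(
            x=(ix - config.nx // 2) * config.pixel_pitch,
            y=(iy - config.ny // 2) * config.pixel_pitch,
            z=float(z_values[iz]),
            score=float(volume[iz, iy, ix]),
        )
        for iz, iy, ix in accepted
    ]
    dets.sort(key=lambda d: (-d.score, d.z, d.y, d.x))
    return DetectionReport(dets, threshold, params or {})


def run_pipeline(
    scene: ScenePlacement,
    model: FilterModel,
    z_values,
    threshold: float | None = None,
    min_separation: int = 3,
    carrier: tuple[float, float] | None = None,
    reference_amplitude: float = 1.0,
) -> tuple[DetectionReport, dict]:
    """Render -> (hologram -> demodulate) -> reconstruct -> filter -> detect.

    When ``carrier`` is given the scene is first recorded as an off-axis
    interferogram and demodulated, exercising the full acquisition path.
    ``threshold`` defaults to the rule stored with the trained model
    (geometric mean of the training min in-class peak and max out-of-class
    output).  Returns the report and a dict of intermediate artifacts
    (field, volume, raw and recentred outputs, projection), so reruns from
    saved intermediates are possible.
    """
    cfg = scene.config
    z_values = np.asarray(z_values, dtype=float)
    field_plane = render_scene(scene)
    artifacts: dict = {"field": field_plane}
    if carrier is not None:
        holo = simulate_hologram(field_plane, carrier, reference_amplitude)
        field_plane = demodulate_hologram(holo, carrier, cfg, reference_amplitude)
        artifacts["interferogram"] = holo
        artifacts["demodulated"] = field_plane

    # remove the propagation-invariant background so correlations see only
    # the scattered perturbation (the training normalisation)
    pert = ComplexField(field_plane.values - field_plane.values.mean(), 0.0, cfg)
    volume = reconstruct_volume(pert, z_values)
    artifacts["volume"] = volume

    output = apply_filter(model, volume)
    centred = recenter(output)
    artifacts["output"] = output
    artifacts["output_recentred"] = centred
    artifacts["projection"] = project_output(centred)

    if threshold is None:
        threshold = model.stats.get("detection_threshold")
        if threshold is None:
            raise ValueError("no threshold given and none stored with the model")
    params = {
        "threshold": float(threshold),
        "min_separation": int(min_separation),
        "z_values": z_values.tolist(),
        "carrier": None if carrier is None else list(carrier),
        "n_rods": len(scene.rods),
    }
    report = find_peaks(centred, float(threshold), min_separation, cfg, z_values, params)
    return report, artifacts


def default_threshold(stats: dict) -> float:
    """Detection threshold rule from model statistics.

    Geometric mean of the minimum in-class response and the maximum
    out-of-class response; a quarter of the minimum in-class response when
    the out-of-class side is zero.  Deployment-calibration maxima (see
    :func:`calibrate_threshold`) are preferred over raw training-set peaks
    when present, because training volumes cover only above-focus planes
    while deployment volumes straddle each target's focus.
    """
    in_vals = stats.get("calibration_in_maxima") or stats.get("in_class_peaks") or []
    out_vals = stats.get("calibration_out_maxima") or stats.get("out_class_maxima") or []
    if not in_vals:
        raise ValueError("stats carry no in-class responses")
    lo = min(in_vals)
    hi = max(out_vals) if out_vals else 0.0
    return math.sqrt(lo * hi) if hi > 0 else lo / 4.0


def calibrate_threshold(
    model: FilterModel,
    orientations: int = 8,
    z_half: float = 4.0,
    dz: float = 0.5,
    grid: int = 32,
) -> tuple[float, dict]:
    """Deployment-representative threshold calibration.

    Renders single rods of both classes at ``orientations`` in-plane angles
    (offset half a step from the canonical training angles, probing the
    orientation gaps), reconstructs each over a defocus range symmetric
    about the rod's focal plane — as a field-of-view scan around an object
    of unknown depth does — and runs the filter.  Records the maximum
    output per volume and returns ``default_threshold`` over those maxima
    together with the stats dict to store on the model.
    """
    from .scenes import IN_CLASS_ROD, OUT_CLASS_ROD, render_rod
    from dataclasses import replace

    cfg = OpticalConfig(
        wavelength=model.config.wavelength,
        pixel_pitch=model.config.pixel_pitch,
        nx=grid,
        ny=grid,
        numerical_aperture=model.config.numerical_aperture,
        medium_index=model.config.medium_index,
    )
    z_values = np.arange(-z_half, z_half + dz / 2, dz)
    step = 180.0 / orientations
    stats = {"calibration_in_maxima": [], "calibration_out_maxima": []}
    for base, key in (
        (IN_CLASS_ROD, "calibration_in_maxima"),
        (OUT_CLASS_ROD, "calibration_out_maxima"),
    ):
        for k in range(orientations):
            rod = replace(base, orientation=(k + 0.5) * step)
            plane = ComplexField(render_rod(rod, cfg) - 1.0, 0.0, cfg)
            out = apply_filter(model, reconstruct_volume(plane, z_values))
            stats[key].append(float(out.max()))
    return default_threshold(stats), stats
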