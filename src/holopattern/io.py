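"""File formats: complex fields (TIFF/HDF5), kernels, models, configs, reports.

Complex planes travel as paired real/imaginary float32 arrays — a two-page
TIFF (page 0 real, page 1 imaginary) or an HDF5 file with ``/real`` and
``/imag`` datasets; the optical configuration rides along as attributes
(``wavelength_um``, ``pitch_um``, ``na``, ``medium_index``, ``z_um``).
Both round-trip float32 data bit-exactly.  Trained filter models are a
single HDF5 file with one group per layer (kernel support as real/imag
float64, the four complex threshold coefficients as 8 reals) and a
versioned attribute schema.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import h5py
import numpy as np
import tifffile
import yaml

from .detect import Detection, DetectionReport
from .filters import FilterLayer, FilterModel, ThresholdCoeffs
from .optics import ComplexField, FieldVolume, OpticalConfig
from .correlation import SpectralKernel

__all__ = [
    "load_optical_config",
    "write_field_tiff",
    "read_field_tiff",
    "write_field_h5",
    "read_field_h5",
    "write_volume_h5",
    "read_volume_h5",
    "write_kernel_h5",
    "read_kernel_h5",
    "write_model_h5",
    "read_model_h5",
    "write_report",
    "read_report_json",
    "write_trace_csv",
    "write_image_tiff",
    "read_image_tiff",
    "write_output_volume_h5",
    "read_output_volume_h5",
    "write_scene_json",
    "read_scene_json",
]

_MODEL_SCHEMA_VERSION = 1


# ---------------------------------------------------------------------------
# configs


def load_optical_config(path: str | Path, **overrides) -> OpticalConfig:
    """Read an OpticalConfig from YAML or JSON (by extension)."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    data = {**data, **overrides}
    return OpticalConfig(
        wavelength=float(data.get("wavelength_um", 0.633)),
        pixel_pitch=float(data["pitch_um"]),
        nx=int(data["nx"]),
        ny=int(data["ny"]),
        numerical_aperture=float(data.get("na", 1.25)),
        medium_index=float(data.get("medium_index", 1.33)),
    )


def _config_attrs(config: OpticalConfig) -> dict:
    return {
        "wavelength_um": config.wavelength,
        "pitch_um": config.pixel_pitch,
        "nx": config.nx,
        "ny": config.ny,
        "na": config.numerical_aperture,
        "medium_index": config.medium_index,
    }


def _config_from_attrs(attrs) -> OpticalConfig:
    return OpticalConfig(
        wavelength=float(attrs["wavelength_um"]),
        pixel_pitch=float(attrs["pitch_um"]),
        nx=int(attrs["nx"]),
        ny=int(attrs["ny"]),
        numerical_aperture=float(attrs["na"]),
        medium_index=float(attrs["medium_index"]),
    )


# ---------------------------------------------------------------------------
# complex planes


def write_field_tiff(path: str | Path, plane: ComplexField) -> None:
    """Two-page float32 TIFF: page 0 real, page 1 imaginary."""
    meta = {**_config_attrs(plane.config), "z_um": plane.z}
    data = np.stack(
        [plane.values.real.astype(np.float32), plane.values.imag.astype(np.float32)]
    )
    tifffile.imwrite(path, data, description=json.dumps(meta))


def read_field_tiff(path: str | Path) -> ComplexField:
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta = json.loads(tif.pages[0].description)
    values = data[0].astype(np.complex128) + 1j * data[1].astype(np.float64)
    return ComplexField(values, float(meta["z_um"]), _config_from_attrs(meta))


def write_field_h5(path: str | Path, plane: ComplexField) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("real", data=plane.values.real.astype(np.float32))
        f.create_dataset("imag", data=plane.values.imag.astype(np.float32))
        for k, v in _config_attrs(plane.config).items():
            f.attrs[k] = v
        f.attrs["z_um"] = plane.z


def read_field_h5(path: str | Path) -> ComplexField:
    with h5py.File(path, "r") as f:
        values = f["real"][()].astype(np.complex128) + 1j * f["imag"][()].astype(np.float64)
        return ComplexField(values, float(f.attrs["z_um"]), _config_from_attrs(f.attrs))


# ---------------------------------------------------------------------------
# volumes


def write_volume_h5(path: str | Path, volume: FieldVolume) -> None:
    stack = volume.stack()
    with h5py.File(path, "w") as f:
        f.create_dataset("real", data=stack.real.astype(np.float32))
        f.create_dataset("imag", data=stack.imag.astype(np.float32))
        f.create_dataset("z_values", data=np.asarray(volume.z_values, dtype=np.float64))
        for k, v in _config_attrs(volume.config).items():
            f.attrs[k] = v


def read_volume_h5(path: str | Path) -> FieldVolume:
    with h5py.File(path, "r") as f:
        stack = f["real"][()].astype(np.complex128) + 1j * f["imag"][()].astype(np.float64)
        z_values = f["z_values"][()]
        config = _config_from_attrs(f.attrs)
    planes = [ComplexField(stack[i], float(z), config) for i, z in enumerate(z_values)]
    return FieldVolume(planes, z_values, config)


def write_output_volume_h5(
    path: str | Path, volume: np.ndarray, z_values: np.ndarray, config: OpticalConfig
) -> None:
    """Real filter-output volume (intensity), float32."""
    with h5py.File(path, "w") as f:
        f.create_dataset("output", data=np.asarray(volume, dtype=np.float32))
        f.create_dataset("z_values", data=np.asarray(z_values, dtype=np.float64))
        for k, v in _config_attrs(config).items():
            f.attrs[k] = v


def read_output_volume_h5(path: str | Path):
    with h5py.File(path, "r") as f:
        return (
            f["output"][()].astype(np.float64),
            f["z_values"][()],
            _config_from_attrs(f.attrs),
        )


# ---------------------------------------------------------------------------
# kernels and models


def write_kernel_h5(path: str | Path, kernel: SpectralKernel) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("real", data=kernel.values.real)
        f.create_dataset("imag", data=kernel.values.imag)
        for k, v in _config_attrs(kernel.config).items():
            f.attrs[k] = v


def read_kernel_h5(path: str | Path) -> SpectralKernel:
    with h5py.File(path, "r") as f:
        values = f["real"][()] + 1j * f["imag"][()]
        return SpectralKernel(values, _config_from_attrs(f.attrs))


def write_model_h5(path: str | Path, model: FilterModel) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = _MODEL_SCHEMA_VERSION
        f.attrs["n_layers"] = len(model.layers)
        f.attrs["stats_json"] = json.dumps(model.stats)
        for k, v in _config_attrs(model.config).items():
            f.attrs[k] = v
        for i, layer in enumerate(model.layers):
            g = f.create_group(f"layer_{i}")
            g.create_dataset("kernel_real", data=layer.support.real)
            g.create_dataset("kernel_imag", data=layer.support.imag)
            coeffs = layer.coeffs.as_array()
            g.create_dataset(
                "coeffs", data=np.concatenate([coeffs.real, coeffs.imag])
            )


def read_model_h5(path: str | Path) -> FilterModel:
    with h5py.File(path, "r") as f:
        version = int(f.attrs["schema_version"])
        if version != _MODEL_SCHEMA_VERSION:
            raise ValueError(f"unsupported model schema version {version}")
        config = _config_from_attrs(f.attrs)
        stats = json.loads(f.attrs.get("stats_json", "{}"))
        layers = []
        for i in range(int(f.attrs["n_layers"])):
            g = f[f"layer_{i}"]
            support = g["kernel_real"][()] + 1j * g["kernel_imag"][()]
            c = g["coeffs"][()]
            coeffs = ThresholdCoeffs(*(c[:4] + 1j * c[4:]))
            layers.append(FilterLayer(support, coeffs))
    return FilterModel(layers, config, stats)


# ---------------------------------------------------------------------------
# reports, traces, plain images


def write_report(path_base: str | Path, report: DetectionReport) -> None:
    """Write a detection report as both JSON and TSV (x_um, y_um, z_um, score)."""
    base = Path(path_base)
    payload = {
        "threshold": report.threshold,
        "params": report.params,
        "detections": [
            {"x_um": d.x, "y_um": d.y, "z_um": d.z, "score": d.score}
            for d in report.detections
        ],
    }
    base.with_suffix(".json").write_text(json.dumps(payload, indent=2))
    with open(base.with_suffix(".tsv"), "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["x_um", "y_um", "z_um", "score"])
        for d in report.detections:
            w.writerow([d.x, d.y, d.z, d.score])


def read_report_json(path: str | Path) -> DetectionReport:
    data = json.loads(Path(path).read_text())
    dets = [
        Detection(d["x_um"], d["y_um"], d["z_um"], d["score"]) for d in data["detections"]
    ]
    return DetectionReport(dets, data["threshold"], data.get("params", {}))


def write_trace_csv(path: str | Path, trace: list[dict]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.DictWriter(fh, fieldnames=["step", "temperature", "current_E", "best_E"])
        w.writeheader()
        for row in trace:
            w.writerow(row)


def write_scene_json(path: str | Path, scene) -> None:
    """Scene description: list of rods with class, size, position, orientation."""
    from .scenes import ScenePlacement  # noqa: F401  (type reference)

    payload = {
        "field_extent": list(scene.field_extent),
        "z_range": list(scene.z_range),
        "rods": [
            {
                "class": "in" if spec.in_class else "out",
                "length_um": spec.length,
                "width_um": spec.width,
                "orientation_deg": spec.orientation,
                "amplitude_transmittance": spec.amplitude_transmittance,
                "phase_shift_rad": spec.phase_shift,
                "position_um": list(pos),
            }
            for spec, pos in scene.rods
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_scene_json(path: str | Path, config: OpticalConfig):
    from .scenes import RodSpec, ScenePlacement

    data = json.loads(Path(path).read_text())
    rods = [
        (
            RodSpec(
                length=r["length_um"],
                width=r["width_um"],
                orientation=r.get("orientation_deg", 0.0),
                amplitude_transmittance=r.get("amplitude_transmittance", 0.95),
                phase_shift=r.get("phase_shift_rad", 0.5),
                in_class=r.get("class", "in") == "in",
            ),
            tuple(r["position_um"]),
        )
        for r in data["rods"]
    ]
    return ScenePlacement(
        rods,
        config,
        tuple(data.get("field_extent", (72.0, 72.0))),
        tuple(data.get("z_range", (-8.0, 8.0))),
    )


def write_image_tiff(path: str | Path, image: np.ndarray, meta: dict | None = None) -> None:
    """Single-page float32 TIFF (interferograms, projections)."""
    tifffile.imwrite(
        path, np.asarray(image, dtype=np.float32), description=json.dumps(meta or {})
    )


def read_image_tiff(path: str | Path) -> np.ndarray:
    return tifffile.imread(path)
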