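"""Filter training by simulated annealing of a weighted squared error.

The filter is asked to produce a delta function (unit value at the
designated peak element, zero elsewhere) for every in-class reference
volume and an all-zero output for every out-of-class reference.  The
objective is

    E = sum_ij (R_ij - O_ij)^2  +  n * sum_j (R_pj - O_pj)^2

where ``R_ij`` is voxel ``i`` of the filter output for reference ``j``,
``O`` the desired outputs, ``p`` the designated peak element (flat index 0,
the zero-lag voxel) and ``n`` the number of voxels per volume — the peak
term is weighted by ``n`` so the unit peaks are not swamped by the sidelobe
term.

The free parameters are the in-band entries of each layer's spectral
support plus (optionally) the four complex threshold coefficients per
layer.  E is a high-dimensional non-convex function of these, so a
Metropolis simulated-annealing search with a geometric cooling schedule is
used, warm-started from the analytic matched filter (the cascade's linear
limit).
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import numpy as np

from .filters import (
    FilterLayer,
    FilterModel,
    ThresholdCoeffs,
    apply_filter,
    apply_threshold,
    pad_kernel,
    trainable_mask,
    unpad_kernel,
)
from .optics import FieldVolume, OpticalConfig, field_to_spectrum

__all__ = [
    "TrainingSet",
    "AnnealSchedule",
    "desired_output_for",
    "objective",
    "matched_filter_model",
    "anneal",
    "evaluate",
]


@dataclass
class TrainingSet:
    """Reference volumes with class labels and desired output volumes."""

    references: list[FieldVolume]
    labels: list[bool]  # True = in-class
    desired: list[np.ndarray]

    def __post_init__(self) -> None:
        if not (len(self.references) == len(self.labels) == len(self.desired)):
            raise ValueError("references, labels and desired must have equal lengths")
        if len(self.references) == 0:
            raise ValueError("empty training set")
        for lab, o in zip(self.labels, self.desired):
            nz = np.count_nonzero(o)
            if lab and not (nz == 1 and np.isclose(o.max(), 1.0)):
                raise ValueError("in-class desired output must be a single unit element")
            if not lab and nz != 0:
                raise ValueError("out-of-class desired output must be all zero")

    @property
    def config(self) -> OpticalConfig:
        return self.references[0].config

    def volume_shape(self) -> tuple[int, int, int]:
        r = self.references[0]
        return (len(r), r.config.ny, r.config.nx)


@dataclass
class AnnealSchedule:
    """Geometric cooling schedule for the Metropolis search.

    Temperatures run from ``t_initial`` down to ``t_final`` by repeated
    multiplication with ``cooling_factor``; ``steps_per_temperature`` moves
    are proposed at each temperature.  ``step_scale`` sets the proposal
    standard deviation relative to the temperature and the parameter scale.
    """

    t_initial: float = 0.3
    t_final: float = 1e-3
    cooling_factor: float = 0.92
    steps_per_temperature: int = 150
    step_scale: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t_initial <= 0 or self.t_final <= 0:
            raise ValueError("temperatures must be positive")
        if self.t_final > self.t_initial:
            raise ValueError("t_final must not exceed t_initial")
        if not (0 < self.cooling_factor < 1):
            raise ValueError("cooling_factor must lie in (0, 1)")
        if self.steps_per_temperature < 0 or self.step_scale <= 0:
            raise ValueError("steps_per_temperature must be >= 0, step_scale positive")

    def temperatures(self) -> np.ndarray:
        temps = [self.t_initial]
        while temps[-1] * self.cooling_factor >= self.t_final:
            temps.append(temps[-1] * self.cooling_factor)
        return np.asarray(temps)


def desired_output_for(in_class: bool, shape: tuple[int, int, int]) -> np.ndarray:
    """Desired output volume for a reference of the given class.

    In-class: zero everywhere except a unit value at the first
    lexicographic element (the zero-lag voxel).  Out-of-class: all zero.
    """
    out = np.zeros(shape, dtype=float)
    if in_class:
        out.flat[0] = 1.0
    return out


def objective(R: list[np.ndarray], O: list[np.ndarray]) -> float:
    """Weighted squared-error objective over all references.

    ``sum_ij (R_ij - O_ij)^2 + n * sum_j (peak_j - desired_peak_j)^2`` with
    ``n`` the voxels per volume and the peak at flat index 0.
    """
    if len(R) != len(O):
        raise ValueError("R and O lengths differ")
    e = 0.0
    for r, o in zip(R, O):
        if r.shape != o.shape:
            raise ValueError("output/desired shape mismatch")
        d = r - o
        e += float(np.sum(d * d))
        e += d.size * float(d.flat[0] ** 2)
    return e


# ---------------------------------------------------------------------------
# fast objective evaluation on precomputed reference spectra


class _Forward:
    """Vectorised cascade evaluation over the whole training set.

    The per-plane FFTs of the (corner-convention) reference volumes never
    change during annealing, so they are computed once; each objective
    evaluation is then a few broadcast multiplies and batched FFTs.
    """

    def __init__(self, ts: TrainingSet):
        self.config = ts.config
        self.n_grid = self.config.nx * self.config.ny
        stacks = np.stack(
            [np.fft.ifftshift(r.stack(), axes=(-2, -1)) for r in ts.references]
        )  # (m, nz, ny, nx)
        self.x_hat = np.fft.fft2(stacks, norm="ortho")
        self.O = np.stack(ts.desired)
        self.n_vox = int(np.prod(ts.volume_shape()))

    def outputs(self, model: FilterModel) -> np.ndarray:
        cur_hat = self.x_hat
        cur = None
        for li, layer in enumerate(model.layers):
            if li > 0:
                cur_hat = np.fft.fft2(cur, norm="ortho")
            kern = pad_kernel(layer.support, self.config.shape, self.config)
            k_corner = np.conj(np.fft.ifftshift(kern.values))
            cur = np.sqrt(self.n_grid) * np.fft.ifft2(cur_hat * k_corner, norm="ortho")
            cur = apply_threshold(cur, layer.coeffs)
        return np.abs(cur) ** 2

    def objective(self, model: FilterModel) -> float:
        R = self.outputs(model)
        d = R - self.O
        e = float(np.sum(d * d))
        e += self.n_vox * float(np.sum(d[:, 0, 0, 0] ** 2))
        return e


def matched_filter_model(
    ts: TrainingSet,
    kernel_extent: tuple[int, int] = (16, 16),
    n_layers: int = 1,
) -> FilterModel:
    """Analytic matched-filter warm start (the cascade's linear limit).

    Layer-one support is the central block of the mean in-class reference
    spectrum, scaled so the mean in-class output peak is unity; additional
    layers start as identity (delta kernel, identity threshold).  With one
    layer and identity threshold this model *is* the classical matched
    filter, used both as the annealing start and as the closed-form oracle
    baseline in tests.
    """
    cfg = ts.config
    specs = [
        field_to_spectrum(r.planes[0]).values
        for r, lab in zip(ts.references, ts.labels)
        if lab
    ]
    if not specs:
        raise ValueError("no in-class references")
    mean_spec = np.mean(specs, axis=0)
    # scale so <U_j, H> averages to 1 over the in-class set -> unit peaks
    inner = np.mean([np.real(np.sum(s * np.conj(mean_spec))) for s in specs])
    if inner <= 0:
        raise ValueError("degenerate in-class spectra")
    full = mean_spec / inner
    ey, ex = kernel_extent
    y0, x0 = cfg.ny // 2 - ey // 2, cfg.nx // 2 - ex // 2
    block = full[y0 : y0 + ey, x0 : x0 + ex]
    # round-trip through pad_kernel to apply the band cutoffs to the support
    support = unpad_kernel(pad_kernel(block, cfg.shape, cfg), kernel_extent)
    layers = [FilterLayer(support, ThresholdCoeffs.identity())]
    for _ in range(n_layers - 1):
        delta = _delta_support(kernel_extent, cfg)
        layers.append(FilterLayer(delta, ThresholdCoeffs.identity()))
    return FilterModel(layers, cfg)


def _delta_support(extent: tuple[int, int], cfg: OpticalConfig) -> np.ndarray:
    """Spectral support acting as an identity (delta) correlation kernel.

    A flat in-band spectrum of height ``1/sqrt(nx*ny)`` correlates to the
    band-limited identity on the support band.
    """
    sup = np.full(extent, 1.0 / np.sqrt(cfg.nx * cfg.ny), dtype=np.complex128)
    sup[~trainable_mask(extent, cfg)] = 0.0
    return sup


def anneal(
    model0: FilterModel,
    ts: TrainingSet,
    schedule: AnnealSchedule,
    train_thresholds: bool = True,
) -> tuple[FilterModel, list[dict]]:
    """Metropolis simulated annealing of the filter parameters.

    One randomly chosen complex parameter (an in-band support entry, or a
    threshold coefficient when ``train_thresholds``) is perturbed per step
    with a complex Gaussian of standard deviation
    ``step_scale * temperature * parameter_scale``.  Moves that lower the
    objective are always accepted; uphill moves with probability
    ``exp(-dE / T)``.  Returns the best model ever visited and a trace of
    ``(step, temperature, current_E, best_E)`` rows; the best-so-far error
    is non-increasing by construction and the whole run is reproducible
    from ``schedule.seed``.
    """
    if len(ts.references) == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(schedule.seed)
    fwd = _Forward(ts)

    current = copy.deepcopy(model0)
    masks = [trainable_mask(l.support.shape, ts.config) for l in current.layers]
    sup_idx = [np.argwhere(m) for m in masks]
    # proposal scale anchors: rms of the live warm-start support per layer
    anchors = []
    for l, m in zip(current.layers, masks):
        live = np.abs(l.support[m])
        anchors.append(float(np.sqrt(np.mean(live**2))) if live.size and live.max() > 0 else 1.0)

    e_cur = fwd.objective(current)
    best = copy.deepcopy(current)
    e_best = e_cur
    trace: list[dict] = [
        {"step": 0, "temperature": schedule.t_initial, "current_E": e_cur, "best_E": e_best}
    ]

    step = 0
    for t in schedule.temperatures():
        for _ in range(schedule.steps_per_temperature):
            step += 1
            li = int(rng.integers(len(current.layers)))
            layer = current.layers[li]
            n_sup = len(sup_idx[li])
            n_par = n_sup + (4 if train_thresholds else 0)
            pi = int(rng.integers(n_par))
            g = (rng.standard_normal() + 1j * rng.standard_normal()) / np.sqrt(2)
            if pi < n_sup:
                iy, ix = sup_idx[li][pi]
                old = layer.support[iy, ix]
                layer.support[iy, ix] = old + g * schedule.step_scale * t * anchors[li]
                undo = ("support", li, iy, ix, old)
            else:
                arr = layer.coeffs.as_array()
                ci = pi - n_sup
                old_arr = arr.copy()
                arr[ci] = arr[ci] + g * schedule.step_scale * t
                layer.coeffs = ThresholdCoeffs(*arr)
                undo = ("coeffs", li, old_arr)

            e_new = fwd.objective(current)
            de = e_new - e_cur
            if de <= 0 or rng.random() < math.exp(-de / t):
                e_cur = e_new
                if e_cur < e_best:
                    e_best = e_cur
                    best = copy.deepcopy(current)
            else:
                if undo[0] == "support":
                    _, li, iy, ix, old = undo
                    current.layers[li].support[iy, ix] = old
                else:
                    _, li, old_arr = undo
                    current.layers[li].coeffs = ThresholdCoeffs(*old_arr)
            trace.append(
                {"step": step, "temperature": t, "current_E": e_cur, "best_E": e_best}
            )
    return best, trace


def evaluate(model: FilterModel, ts: TrainingSet) -> dict:
    """Peak/sidelobe statistics of a model on a training set.

    Returns the per-reference in-class peak values (output at the
    designated peak voxel), the out-of-class maximum outputs, and the
    discrimination ratio min(in-class peaks) / max(out-of-class outputs)
    (``inf`` when every out-of-class output is exactly zero).
    """
    in_peaks, out_maxima = [], []
    for ref, lab in zip(ts.references, ts.labels):
        out = apply_filter(model, ref)
        if lab:
            in_peaks.append(float(out.flat[0]))
        else:
            out_maxima.append(float(out.max()))
    stats = {"in_class_peaks": in_peaks, "out_class_maxima": out_maxima}
    if in_peaks:
        mx = max(out_maxima) if out_maxima else 0.0
        stats["discrimination_ratio"] = math.inf if mx == 0 else min(in_peaks) / mx
    return stats
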