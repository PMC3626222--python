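# Methods

## Field model and propagation

A monochromatic scalar field in a uniform dielectric satisfies the
Helmholtz equation; neglecting evanescent components, it is a
superposition of plane waves on the Ewald sphere `|k| = n/λ` (wavenumber
convention `k = 1/λ`; all spatial frequencies in cycles per micron, all
lengths in microns). The package therefore represents a field by one
sampled complex plane plus an `OpticalConfig` (wavelength, pixel pitch,
grid size, NA, medium index), and derives every other plane by
angular-spectrum propagation: forward DFT with kernel `exp(−j2πk·r)`,
multiplication by `exp(+j2πz·k_z)` with the positive root
`k_z = √((n/λ)² − k_x² − k_y²)`, inverse DFT.

Numerical conventions, fixed package-wide:

* centred grids (DC and the spatial origin at index `n//2`), unitary
  (`norm="ortho"`) transforms so Parseval holds exactly;
* arrays are indexed `[z, y, x]`, x fastest; z increases away from the
  objective;
* two hard spectral cutoffs: the propagating band `k_t ≤ n/λ` (evanescent
  components zeroed, not decay-modelled) and the aperture band
  `k_t ≤ NA/λ` (the objective's collection limit). Defaults: He-Ne
  `λ = 0.633`, `NA = 1.25`, aqueous medium `n = 1.33`, pitch `0.25 µm`
  (just inside the NA Nyquist pitch `λ/2NA ≈ 0.253 µm`; a coarser pitch
  triggers a warning, not an error);
* circular (FFT-native) boundaries everywhere; zero-padding for linear
  behaviour is the caller's job and is built into the filter-kernel
  handling (below).

In-band energy is conserved under propagation to 1e−10 (measured ~1e−16),
propagation composes as a group, and the 3D DFT of a reconstructed volume
concentrates, per transverse mode, at the axial bin nearest
`k_z(k_x,k_y)` — the discrete Ewald shell. All three are asserted in the
test suite against brute-force DFT oracles.

## Plane-wise 2D filtering = 3D correlation

Because the field's 3D spectrum lives on the shell, a 3D correlation
filter only sees the restriction `H(k_x,k_y)` of its transfer function to
the shell, and one plane of the 3D correlation output is

    R_z(r) = Σ_v u_z(v) · conj(h_0(v − r))        (circular in x, y)

with `h_0 = IFT(H)` the kernel's reference-plane impulse response and
`u_z` the reconstructed field in that plane. `correlate_plane` /
`correlate_volume` implement the spectral form
`√N · IFT[U · H* · exp(+j2πz k_z)]`, normalised so the output equals the
literal correlation sum (a matched kernel's zero-lag peak is then exactly
the template's in-band energy). Zero lag sits at array index (0,0);
`recenter` moves it to the centre for display.

The independent oracle `brute_force_correlate3d` evaluates the defining 3D
sum directly: the 3D impulse response is the propagating stack
`h_z = IFT(H · exp(+j2πz k_z))`, and the axial shift in the correlation
sum is realised by evaluating that propagation at the lag `z_m − z_p`
rather than by circularly wrapping a sampled stack — a propagating kernel
is defined at every z, and an artificial axial period would break the
equivalence that holds in the continuous axial integral. With that
discretisation the triple sum equals exactly `n_z` times the plane-wise
result (divided out), and the two routes agree to machine precision
(asserted at 1e−8 of the peak on 8×8×4 and 16×16×8 random band-limited
fields).

## The nonlinear filter cascade

`FilterModel` is an ordered list of layers, each a trainable 2D spectral
support (default 16×16 complex samples of the central spectral bins) plus
four complex cubic-threshold coefficients. Applying the cascade to a
volume: per layer, every plane is circularly correlated with the layer
kernel's reference-plane impulse response, then the pointwise threshold
`a x³ + b x² + c x + d` is applied to the complex values; after the last
layer the squared modulus produces the real, nonnegative output volume.
For a propagating input volume the first layer is exactly a 3D
correlation (the equivalence above); deeper layers act on post-threshold
volumes, which are no longer propagating fields, and there the per-plane
rule is the definition of the cascade (sequential 2D filtering of the
plane-by-plane reconstruction). Thresholds act on complex values with
complex coefficients — the cascade stays complex until the final modulus,
preserving inter-layer phase; a modulus between layers would discard the
very information the complex reconstruction provides.

Kernels are stored as their small spectral support and zero-padded to the
processing grid: within one grid by centred embedding of the support
(entries outside the spectral cutoffs are dead and excluded from
training); across grids (training patch → full scene) by zero-padding the
*spatial* impulse response and re-transforming, which preserves the
literal correlation values exactly and is the standard way a small kernel
is applied to a large image while avoiding wrap-around edge effects.

## Training

References are background-subtracted scattered fields of single rods
(the unit background is propagation-invariant and class-blind; left in,
its DC response dominates every correlation). Each reference volume has
the rod in focus at its first plane, because the desired output for an
in-class reference is a unit delta at the first lexicographic voxel —
the zero-lag, in-focus peak position — and the cascade cannot shift
output axially (kernels are 2D; z enters only through the input's
propagation). Out-of-class desired outputs are zero.

The objective is the weighted squared error
`E = Σ_ij (R_ij − O_ij)² + n Σ_j (R_pj − O_pj)²` with `n` the voxels per
volume; the n-weighted peak term keeps the unit peaks from being swamped
by the sidelobe term. `E` is non-convex in the ~500 real parameters, so a
Metropolis simulated-annealing search is used: one randomly chosen
complex parameter per step, complex-Gaussian proposal of scale
`step_scale · T · (parameter anchor)`, geometric cooling. Defaults
(`t0 = 0.3`, `t_final = 1e−3`, factor 0.92, 150 steps per temperature,
step scale 0.5) were calibrated for convergence quality on the scaled
training problem; the run takes ~15 s on one CPU. The search is
warm-started at the analytic matched filter (mean in-class spectrum,
scaled to unit mean peak) with identity thresholds — the cascade's linear
limit — and the best-ever model is returned, so the best-so-far error is
non-increasing and never worse than the matched-filter baseline. Fixed
seeds make runs bit-reproducible.

Two regimes of the optimisation are worth knowing about. Deep
minimisation of `E` with a *fixed linear* threshold drives the kernel
toward a whitening filter (delta-like in-class outputs require a
flattened product spectrum), far from the matched filter, and plateaus at
a modest class separation. With the threshold coefficients trainable, the
search immediately finds a cubic-dominant threshold: an approximate
power law `|x|⁶` that crushes sidelobes and separates the classes
(discrimination ratio 2.5–3 on the scaled problem) while the kernel stays
close to the matched filter (normalised overlap ≈ 0.93). That
nonlinearity is the design's reason for existing: a linear filter tuned
to the focal plane does not discriminate well across defocus.

## Synthetic scenes and holography

A rod is an anti-aliased capsule (one-pixel linear edge ramp) of complex
transmittance `A·exp(jφ)` on a unit background. Defaults — in-class
(target) 2.0 × 0.8 µm, out-of-class (distractor) 1.4 × 0.7 µm, `A = 0.95`,
`φ = 0.5 rad` for both classes — are synthetic stand-ins chosen to be
biologically plausible weak phase objects; only the size separates the
classes, matching the premise of two similar rod-shaped species. Scenes
compose multiple rods in first-Born fashion: each rod's perturbation
(object − 1) is propagated from its own depth to the focal plane and
summed on the unit background, consistent with single weak scattering.
Placements reject transverse overlaps closer than the bounding radii
unless the rods are ≥ 2 µm apart axially.

Off-axis holograms are `|u + r·exp(j2π(f_x x + f_y y))|²` with a carrier
that must exceed twice the object band (`|f| > 2·NA/λ`) and fit inside
Nyquist together with the band. Demodulation mixes the interferogram
down by the conjugate carrier and low-passes to the NA band; for
admissible carriers (in practice `|f| ≥ 3·NA/λ` so the self-interference
term also clears the band) the complex field is recovered within the band
to machine precision. Optional Gaussian/shot noise on interferograms is
off by default; the emulated instrument is noiseless, so passing tests
bound discretisation and algorithmic error, not robustness to detector
noise, and say nothing about aberrations, partial coherence or strong
scattering in real recordings.

## Detection

The filter output volume is recentred so a target at scene pixel (y, x)
peaks at that pixel. Detections are 3×3×3 local maxima above a threshold,
greedily pruned so no two survive within a transverse separation
(Euclidean in x–y voxels; the axial response of a defocused target is far
broader than the transverse one, so 3D separation would keep per-target
duplicates along z; two objects overlapping transversely at well separated
depths are consequently merged — a known limitation). Ties resolve to the
lexicographically first voxel; reports are sorted by descending score and
serialise to JSON/TSV.

The detection threshold (the source experiment reports none) defaults to
a deployment calibration: single rods of both classes, at orientations
offset half a step from the training angles (probing the orientation
gaps), are each run through the filter over a defocus range symmetric
about their focus, and the threshold is the geometric mean of the minimum
in-class and maximum out-of-class volume maxima. Calibrating on symmetric
defocus matters: training volumes cover only above-focus planes (see
Training), so training-set statistics underestimate below-focus
responses. On the fixed-seed synthetic scene (6 targets + 4 distractors,
128×128, z ∈ ±3 µm) the pipeline reaches recall 1.0 with zero false
alarms and sub-pixel transverse localization. Across other seeds recall
0.83–1.0 with 0–2 false alarms was observed: in crowded scenes the cubic
nonlinearity amplifies neighbour crosstalk (output ≈ amplitude⁶), pushing
occasional distractors past the isolated-rod calibration. Calibrating on
held-out synthetic *scenes* rather than isolated rods would tighten this
and is the natural next step.

## Scaled problem sizes

The shipped tests and the acceptance script run scaled-down instances
chosen as the package's standard working set: training volumes 16×16×8
(full-grid 16×16 kernel support), 6 + 6 references at 4 orientations,
~10⁴ annealing steps; detection scenes 128×128 × 17 planes. The
full-size configuration of the emulated experiment (32×32×16 patches,
16×16 supports, 25 + 17 references at 8 orientations) is the
`build_training_set` default and runs in a few minutes.
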