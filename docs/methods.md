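# Methods

## Model and assumptions

`conefdk` implements circular-orbit cone-beam filtered backprojection (the
Feldkamp–Davis–Kress algorithm) for a flat detector. The model assumes a
point X-ray source, a monochromatic beam (projection values are pure line
integrals of an attenuation field), a rigid circular source orbit in the
plane `z = 0`, and a flat detector perpendicular to the central ray whose
vertical axis stays parallel to the rotation axis. FDK is exact in the
source plane and approximate away from it; the approximation error grows
with cone angle and appears as mild axial blurring/intensity drop for
structures far from `z = 0`.

## Coordinate convention

Conventions differ between implementations and flip images left/right, so
this package fixes one and uses it everywhere:

- World frame: right-handed, rotation axis `z`, orbit center at the origin.
- At view angle `θ = 0` the source is at `(−d_so, 0, 0)` looking along `+x`;
  angles increase counter-clockwise seen from `+z`.
- For a point `(x, y, z)`: `s = −(x cos θ + y sin θ)` is its signed distance
  toward the source and `t = −x sin θ + y cos θ` its transverse coordinate;
  `u = d_sd·t/(d_so−s)`, `v = d_sd·z/(d_so−s)` are *physical* detector
  coordinates relative to the central ray.
- Detector pixel centers: `index = (coord − offset)/spacing + (N−1)/2`, so
  an odd-sized detector with zero offsets has a pixel exactly on the central
  ray.
- A full 360° scan samples `θ_n = n·2π/K`, endpoint excluded.

## Scale normalization

The inversion formula is usually written on the virtual detector through the
rotation axis. This package filters in physical detector coordinates
(`H(f) = |f|` in cycles per length unit of the detector pitch), and the ramp
kernel scales quadratically under coordinate magnification; transporting the
convolution from the virtual to the physical plane therefore multiplies the
result by the magnification `M = d_sd/d_so`. The complete per-view constant
applied during accumulation is

    scale = (Δθ / 2) · (d_sd / d_so),     Δθ = arc / K,

and no other normalization exists anywhere in the pipeline. The constant is
pinned by an absolute test: a centered uniform sphere of density 1 (radius
25 % of the field of view, full orbit) reconstructs to 0.993 at the center
with background below 0.031 at the canonical problem size.

## Synthetic data

Phantoms are unions of ellipsoids with additive densities (rotations
restricted to the `z` axis, as in the classic head-phantom definitions), so
cone-beam projections have closed forms: each ray contributes
`Σ density · chord`, with the chord obtained by mapping the ray into the
frame where the ellipsoid is a unit sphere and solving the quadratic. The
default object is a ten-ellipsoid 3-D Shepp–Logan-style head phantom with
densities in [0, 2], scaled to half-extent 26 length units so it fills the
canonical 64×60×50-voxel field of view (1 unit/voxel) without truncation.
It is a documented stand-in for "a synthetic head-like object", not a copy
of any particular scanner dataset.

The canonical scan geometry is `d_so = 250`, `d_sd = 500` (magnification 2),
a 64×60 detector with 2-unit pixels (so 1-unit sampling on the central
plane) and 72 uniformly spaced views — small enough that the full pipeline
runs in seconds on one CPU, large enough that filtering and cone-beam
weighting behave as at clinical scale.

What the generator does **not** emulate: photon statistics (the optional
noise model is additive Gaussian, not Poisson), beam hardening, scatter,
detector blur and afterglow, gantry wobble, or detector-footprint
integration (one ray per pixel center). Passing tests therefore demonstrate
the correctness of the reconstruction operator on ideal line integrals, not
robustness to the physics of real scanners.

## Numerical choices

- **FFT filtering.** Rows are zero-padded to the next power of two
  ≥ 4×detector width. Padding ≥ 2× is required for linear (non-circular)
  convolution; the extra factor of two suppresses the low-frequency bias of
  the frequency-sampled ramp (the DFT grid under-resolves `|f|` near 0),
  which at minimal padding costs ~2–3 % of absolute density and visible
  background haze. `H(0) = 0` exactly, so the filter has zero DC gain on the
  padded window. Note that a *finite* constant row is a rect signal whose
  ramp response is a genuine pair of edge spikes — only a constant periodic
  signal is annihilated outright.
- **Interpolation.** Bilinear sampling of the filtered projection at
  fractional pixel indices, with zero contribution outside the detector (no
  clamping); nearest-neighbor is available for oracle cross-checks. Voxels
  at or behind the source are skipped and counted.
- **Determinism.** Accumulation order is fixed (ascending view index,
  vectorized over voxels), so repeated runs are bitwise identical. The
  backprojector is vectorized numpy; no thread-count knob is exposed because
  there is nothing it would change.
- **Precision.** `single` casts the projections and accumulates in float32
  end-to-end (the filter core computes in float64 and rounds back, mirroring
  how GPU pipelines use higher-precision FFT libraries); `double` is the
  reference. On the canonical phantom the two differ by ≲ 1e-6 max-abs.
- **Short scans.** Arcs < 360° are accepted but emit a loud warning: no
  Parker-style redundancy weighting is implemented, so expect shading.
- **Degenerate inputs.** Non-finite projections abort with the offending
  view index named; tangent rays yield zero chords; empty phantoms produce
  exactly zero stacks.

## Validation strategy

Every stage is checked against an independent reference implemented from
first principles in the test suite: a hand-assembled projective mapping for
the geometry, trapezoid quadrature of the inside-indicator for chords, the
Ramachandran–Lakshminarayanan closed form and direct time-domain convolution
for the filter, a literal triple-loop accumulator for backprojection, and
scikit-image's parallel-beam `iradon` for the large-`d_so` limit of the
central slice. One physical identity deserves note: opposing cone-beam views
do **not** mirror each other (divergent rays coincide only for the central
ray); the correct statement, which the projector satisfies to 1e-9, is the
fan-beam conjugate `(θ, u) ↔ (θ + π + 2γ, −u)` with `γ = atan(u/d_sd)` in
the source plane.

## Limitations

- FDK is approximate off the source plane; no cone-angle correction
  (e.g. Grangeat-type) is provided.
- Circular orbits and flat detectors only; no helical scanning, tilted or
  cylindrical detectors, or projection-matrix calibration input.
- No truncated-projection (interior tomography) handling: objects must fit
  the detector in `u` at every view.
- Everything is held in memory; stacks larger than RAM would need streaming.
- The Gaussian noise model is a convenience for robustness experiments, not
  a physical detector model.
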