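# Methods

## The solver

`hasim` computes steady-state (single-frequency) acoustic pressure in a
voxelized heterogeneous medium with the hybrid angular spectrum (HAS)
method: a slice-marching scheme that alternates between the space domain
and the spatial-frequency domain along the propagation axis (+z).

For each slab of thickness Δz the field on the entering plane is first
multiplied voxel-wise by `exp(jΔb(x,y)Δz)·exp(−a(x,y)Δz)`, where
`Δb = 2πf/c(x,y) − b′` is the deviation of the local propagation constant
from the slice average `b′` (arithmetic mean over the plane) and `a` is the
absorption in Np/m. The result is Fourier-transformed and each plane-wave
component advanced by the exact homogeneous transfer function
`exp(j b′ √(1−α²−β²) Δz)` with directional cosines `α = λf_x`, `β = λf_y`
and `λ = 2π/b′`. The inverse transform gives the field at the next plane.
The split captures refraction and absorption voxel-by-voxel while the
diffraction step stays a pair of FFTs, which is what makes per-element
3D simulation of a whole phased array affordable.

Assumptions and limits: linear acoustics, no shear-wave conversion, no
volumetric scattering, one-way propagation. Backscatter is never
generated; with the optional `reflections` flag the forward wave is
multiplied by the plane-wave pressure transmission factor `2Z₂/(Z₁+Z₂)`
at impedance steps between slices (amplitude bookkeeping only). The
oblique and perpendicular step distances are both taken as Δz (paraxial
policy); steep plane-wave components therefore accumulate slightly too
little heterogeneity phase, an accepted approximation of this scheme.

### Numerical choices

* **Sign convention** (fixed project-wide, `hasim.units`): time dependence
  `e^{−jωt}`, forward propagation `e^{+jkz}`. A sign error here inverts
  every correction, so it is asserted by the plane-wave and
  slow-voxel-phase unit tests.
* **Evanescent components** (`α²+β² > 1`): zeroed by default (prevents any
  spurious growth); optional `decay` mode applies the physical
  `exp(−b′√(α²+β²−1)Δz)` for near-field work.
* **Radiating boundaries**: the FFT lattice is periodic, so each slice is
  zero-padded laterally (factor 2 by default, rounded up to fast FFT
  sizes) and multiplied by a raised-cosine amplitude taper (10 voxels)
  near the padded edges. Energy walking off the grid is absorbed instead
  of wrapping. Padding voxels carry the slice-mean speed and zero
  absorption.
* **Degenerate inputs**: non-finite sources are rejected at construction;
  a non-finite field mid-march raises a numerical error naming the slice.
* **Step size**: Δz defaults to the grid dz. In homogeneous media the
  transfer function is exact in Δz; heterogeneity sampling is the only
  refinement concern (the bowl-in-water test shows <1 % change when dz is
  halved).

Accuracy evidence computed by the test suite: plane-wave phase and
attenuation reproduced to 1e-6/1e-9; spectral energy over propagating
components conserved to ~1e-14; on-axis pressure of the full 14.5 cm /
13 cm focused bowl within 5 % (measured ≈2.4 %) of the O'Neil closed-form
solution; reciprocity across a uniform slab to <1 %.

## Source model

Elements live on a spherical cap (apex at the origin, center of curvature
= geometric focus at `(0,0,F)`). The default layout is a Fermat/sunflower
spiral in equal cap-area rings — deterministic, near-uniform, and a
reasonable stand-in for proprietary layouts, which can be loaded verbatim
from CSV. Each element's field on the solver entry plane is a
Rayleigh–Sommerfeld sum over equal-area point sub-sources on the element's
geodesic disk of the cap, at ≤ λ/2 spacing by default; for a single
full-cap element this reduces exactly to a focused-bowl radiator, which is
how the O'Neil comparison is run. Sub-source discreteness breaks exact
(x,y) → (−x,−y) symmetry at the 1 % level at λ/2 spacing and converges
away with refinement.

Geometric (water-path) steering phases are
`φ_i = −k_ref(|c_i − target| − F)`, so that with drives `e^{+jφ}` and the
`e^{+jkz}` convention all contributions arrive in phase at the target
through water; at the geometric focus all phases are zero. These are the
"uncorrected" baseline of the steering-improvement analysis.

## Correction

Each element is propagated once at unit amplitude and zero phase; the
complex fields over a declared treatment region (an axis-aligned voxel
box; full volume optional) form the element bank. Conjugate phases are
`φ_i = −arg p_i(target)`, wrapped to (−π, π]. Off-grid targets are handled
by trilinear interpolation of the complex field — interpolating the phasor
rather than the angle avoids phase-unwrapping artifacts. A vanishing
element amplitude leaves its phase undefined: it is set to 0 with a logged
warning. Amplitudes are never modified (amplitude shading is out of
scope). For fixed amplitudes the conjugate set maximizes the on-target
coherent sum; the tests verify this against an exhaustive 256-level phase
search on 4 elements and confirm the corrected on-target magnitude equals
Σ|p_i| to 1e-6.

Bank simulations are embarrassingly parallel per element and are
checkpointed per element to HDF5; an interrupted run resumes from the
elements already stored. Checkpoint storage is complex64.

## Synthetic media

The generators define the study conditions for all seeded tests.

* **Aberrator plate** (`generate_aberrator`): flat entry face, random
  relief exit face. Relief = seeded uniform white noise, Gaussian-smoothed
  to a lateral feature scale (default 5 mm; the desk-scale suites use
  2–6 mm), then min–max rescaled to exactly [0, max_relief]. Defaults:
  7.5 mm base, 4 mm max relief, plastic at 2492 m/s and 4.72 dB/(cm·MHz) —
  the 4 mm relief spans 6.67 rad (>2π) of phase at 1 MHz, which is the
  design point of the physical device. Plate density defaults to
  1175 kg/m³ (typical acrylic photopolymer; it only matters when the
  reflection flag is on). Voxelization assigns plate properties to voxels
  whose center lies inside the plate.
* **Synthetic skull** (`generate_synthetic_skull`): a gently bowed slab of
  Hounsfield units with smoothly varying thickness (25 mm lateral
  correlation by default — an order of magnitude longer than the
  aberrator's relief) and seeded internal HU texture standing in for
  trabecular structure and CT noise. It emulates the geometry and
  statistics of a CT'd bone flap, **not** any specific skull: no sutures,
  no cortical/diploë layering, no beam-hardening artifacts. Tests passing
  on it show the pipeline's mechanics, not clinical accuracy on real CTs.
* **HU mapping** (`HUMappingConfig`): affine density
  (1000 + 1.0·HU kg/m³), monotone piecewise-linear speed and attenuation
  curves clamped at the end knots, water below a 300 HU bone threshold.
  The default curves are a documented structural stand-in (water bottom
  knot; 2740 m/s cortical-speed top knot at 2000 HU; 8 dB/(cm·MHz) top
  attenuation): calibrated curves from the literature should be supplied
  through the same knot lists for quantitative skull work.

## Treatment metrics

* **Steering-improvement map**: per steered target, the ratio of the
  focal-plane peak |p| with conjugate phases to that with water-path
  geometric phases. Water gives a flat map at 1 (verified to 1 %).
  Lattices default to 23×23 (the treatment-scale convention); the test
  suites run 3×3–5×5.
* **Misregistration map**: the model is translated laterally in
  whole-voxel steps (no interpolation — binary material boundaries are
  preserved) while the phase solution stays fixed; the focal-plane peak is
  normalized by the zero-shift value, so the origin is exactly 1.
* **Phase-length autocorrelation**: straight-ray accumulated phase
  `φ(x,y) = Σ_z b dz` (no refraction — deliberately a path integral, not a
  wave solve), optional Gaussian smoothing (σ in pixels, e.g. 2 for CT
  noise), converted to phasors `e^{jφ}` — correlating wrapped angles
  directly would alias. A circular patch the size of the beam footprint at
  the model entry (cone geometry: aperture radius × distance-to-focus /
  focal length, overridable) is complex-cross-correlated with the full
  map; the magnitude is normalized to a global max of 1 and contour areas
  reported in mm² at 25/50/75 %.

### A caveat on the misregistration metric at desk scale

With the scaled-down study conditions (16-element, 50 mm-aperture array;
64³-class grids) the focal-plane *maximum* is only moderately dominated by
the corrected focus. Translating the plate then changes two things at
once: the phase decorrelation the metric is meant to capture, and the
amount of absorbing plastic in the beam footprint. For shifts much smaller
than the relief feature scale the second effect can *raise* the focal-plane
maximum, so individual map cells may exceed 1 and the signed "loss at one
voxel" is instance-dependent. The loss reliably appears at shifts
comparable to the feature scale, which is what the unit test asserts, and
the acceptance script reports a sign-free RMS sensitivity over a ±1 mm
lattice. For the same reason the qualitative link "broader features ⇒
flatter misregistration map" is asserted on the suite's fixed seeded
instance, while the model-only half of that link (broader features ⇒
larger 50 % autocorrelation area) is robust across seeds. At
treatment scale (256 elements, 14.5 cm aperture) the focal dominance is
far stronger and the footprint averages over many features, so the maps
behave as loss maps.

## Problem sizes

The shipped suites use desk-scale problems chosen to exercise every code
path with meaningful physics: the analytic-oracle suite runs the full
treatment-geometry bowl (128×128×200 voxels, λ/4 axial steps); the
correction suite a 16-element array on 64×64×80 voxels at 0.5 mm; the
analysis suites 3×3–5×5 shift/target lattices. The bank checkpoint test
interrupts a 16-element bank mid-run and verifies lossless resumption;
the same mechanism scales unchanged to 256-element banks on
clinical-resolution grids, where per-element independence also permits
parallel execution.

## Known limitations

* One-way propagation: standing waves and multiple reverberation between
  skull tables are not modeled.
* Paraxial heterogeneity step: steep-angle aberration is underestimated.
* The default HU curves are structural defaults, not a calibrated skull
  model.
* Element sub-sources are flat-piston point samples; element directivity
  beyond that and electronics are out of scope.
* Ratio maps inherit the focal-plane-max metric's caveat above at small
  array counts.
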