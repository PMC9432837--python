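# Methods

This note documents the models, parameter choices and numerical
conventions behind `podomech`, and what the synthetic-data tests do and do
not demonstrate about real data.

## Coordinate and unit conventions

All lengths are microns, moduli and stresses kilopascals. Images use the
microscopy convention: origin at the top-left pixel center, x rightward
(columns), y downward (rows); every image carries its pixel size.
Intensities are floats in [0, 1] internally and 16-bit on TIFF export.

## Synthetic striated fibers

A fiber is a polyline decorated with periodic bands. Band profiles along
the fiber are Gaussian bumps (σ = band_width / 2.355, i.e. FWHM =
band_width) rather than square pulses: this approximates PSF-limited
microscopy and gives analytically well-defined peak positions. Lateral
falloff across the fiber is Gaussian with FWHM `fiber_width` (default
0.8 μm). Each channel has a phase offset as a fraction of the period; the
default two channels at phases 0 and 0.5 emulate synaptopodin/α-actinin 4
bands interleaving with myosin IIA. The ideal image is blurred by an
isotropic Gaussian PSF (default σ 0.15 μm) and corrupted by additive
Gaussian noise (default sd 0.02; no published noise statistics exist for
the source imagery, so these values are nominal). Band spacing must exceed
twice the pixel size (Nyquist), enforced at construction.

What the generator does **not** emulate: photobleaching, shot-noise
statistics, out-of-focus light, fiber crossings and curvature-dependent
width, background cells. Parameter-recovery results on this synthetic
imagery therefore demonstrate correctness of the measurement chain, not
robustness to every confound of real micrographs.

## Sarcomeric spacing measurement

Intensity is sampled every 0.05 μm along a user-supplied polyline by
bilinear interpolation, averaged across a perpendicular width (default
0.3 μm). Peaks are local maxima with prominence at least 0.2 of the
channel's intensity range (detection is therefore invariant to offset and
uniform rescaling) separated by at least 0.4 μm — below the smallest
spacing regime of interest (0.8 μm) but above noise scale. Endpoint maxima
that dominate their neighbour and clear the same prominence above the
profile minimum are admitted, since a band may fall exactly at the start
of a trace. Interior peaks are refined by a three-point parabolic fit
(spacing contrasts of 0.2 μm at 0.1 μm pixels require sub-pixel
localization).

Spacings are successive peak differences. Two summary conventions are
deliberately kept distinct, as both are standard: **pooled** statistics
count every spacing once (n = number of sarcomeres), while **per-fiber**
statistics average within each fiber first and only admit fibers at least
6 μm long with at least two peaks (n = number of fibers). The alternation
index is the fraction of consecutive same-channel peak intervals that
contain exactly one peak of the partner channel; 1.0 means strict
interleaving. It is undefined (None) below two reference peaks.

Automatic fiber tracing is out of scope; polylines come from the user, a
config file, or the generator.

## Strain mapping from microbeads

Bead pairing uses mutual nearest neighbours within `max_disp`; mutuality
guarantees one-to-one assignment, and ambiguous beads are dropped rather
than guessed. This is adequate when displacements are small compared with
the bead spacing; for denser or larger motions, supply the matched field
directly (`strain_pipeline(bead_field=...)`) — the synthetic generator
always provides the exact correspondence.

The deformation gradient is estimated on a Lagrangian (reference-frame)
grid, default 2 μm spacing: at each grid point a weighted least-squares
affine model x_def ≈ F·x_ref + t is fit over beads within a 5 μm window
with Gaussian weights (σ = window/2). The fit is exact on affine data, so
rigid motions produce exactly zero Green–Lagrange strain (objectivity).
Points with fewer than `min_neighbors` (default 4) or numerically
collinear neighbours are flagged undefined rather than extrapolated.
E = ½(FᵀF − I); e₁ is its largest eigenvalue. The analysis is strictly
two-dimensional (the adhesion plane); out-of-plane bead motion is ignored
and is a known limitation. The reference state is the pre-treatment frame,
so relaxation after actin depolymerisation reads as positive (extension)
strain.

## Contraction finite-element model

Geometry and materials follow the study conditions: a cell process shaped
as half a cylinder capped by a quarter sphere (radius 4 μm), isotropic
linear-elastic (1.0 kPa, ν 0.3), bonded to a 100 × 100 × 10 μm slab
(0.2–6.0 kPa, ν 0.3; base fixed, sides traction-free). Contractility is an
anisotropic stress-free eigenstrain in the cell volume only,
ε\* = level·(−10%, −8%, −2%) along (x, y, z), with level ∈ (0, 1]
(1.0 / 0.5 / 0.2 for the high / medium / low conditions). Stress in the
cell is C : (ε − ε\*). The length of the cylindrical portion is not
printed in the source; the default 16 μm gives a 20 μm footprint spanning
several radii.

Kinematics are geometrically linear despite the 10% contraction: the
reference model was a linear-elastic simulation with a prescribed
reference-configuration contraction, and linearity makes every output
exactly proportional to the contraction level — an exact, testable
property. A finite-strain mode is a possible extension, not implemented.

Discretisation is deliberately desk-scale (10³–10⁴ elements, seconds per
solve) rather than the 10⁵-element meshes of commercial solvers; accuracy
claims are convergence-trend based:

* Structured trilinear hexahedral grid, fine spacing h = radius /
  `mesh_resolution` (default 4) near the cell, geometrically graded
  (ratio 1.6) toward the remote substrate boundaries. Cell and substrate
  share interface nodes, so bonding is perfect by construction (no
  cohesive or slip law; none is stated for the reference system).
* The open end of the process (x = 0) and the fiber midplane (y = 0) are
  treated as mirror-symmetry planes, so a quarter model is solved. The
  x = 0 mirror represents the process continuing toward the cell body.
* **Cut cells:** elements straddling the curved cell surface carry
  stiffness and eigenstrain scaled by their cell-material volume fraction
  (4×4×4 subsampling), which removes the O(h) stair-casing error of plain
  voxel meshes. The free-floating uniform-eigenstrain patch test still
  passes to machine precision because the fraction scales stiffness and
  load identically.
* Assembly groups elements by unique box dimensions so each element
  stiffness is computed once; the reduced symmetric system is solved with
  a sparse direct factorisation. Equilibrium residual and net reaction
  force (which must vanish — eigenstrain is self-equilibrated) are stored
  on the solution.

**Stress reporting.** At a bonded bi-material contact line, linear
elasticity makes the pointwise stress weakly singular, so a raw "max
stress over elements" does not converge under refinement — it grows
without bound. All reported stress scalars are therefore evaluated at
fixed physical points with a fixed-width Gaussian mollifier (0.5 μm,
volume-weighted over element-center stresses, restricted to one material):
the interfacial shear σ_zx is sampled at 0.5 μm below the interface in the
substrate (above it in the cell for a rigid substrate), and the maximum
principal Cauchy stress over a fixed grid of cell-interior points eroded
0.4 μm from the surface. These measures are mesh-independent definitions
of "stress at measurement scale": doubling the default resolution changes
the peak interfacial shear by ~5% and the peak principal stress by ~7%.

The y → −y mirror symmetry makes σ_zx an even function of y (both of its
indices are unaffected by the reflection); the antisymmetric interfacial
component in y is σ_zy, while σ_zx is odd in x. Along a fixed-x line the
σ_zx profile is consequently rather flat in y; the peripheral dominance of
interfacial shear appears along the axis — the global |σ_zx| peak sits at
the distal footprint boundary, in the peripheral third of the footprint.
The profile's default line position is the mid-length of the cylindrical
portion (the reference figure only pictures its line).

A substrate entered as `"rigid"` (glass) fixes the footprint
displacements and omits the slab; it agrees with a 10⁴ kPa elastic
substrate to better than 0.1% and serves as its cross-check. Cell-width
change is twice the lateral displacement of the footprint-edge node at the
cylinder mid-length (negative = narrowing).

## Scoring and statistics

The phenotype vocabulary is frozen to four categories (SLSs central +
peripheral, peripheral only, loose striated pattern, no SLSs);
classification itself is manual or synthetic input. Mask-based cell length
is the maximum Feret diameter of the pixel region with pixels treated as
unit squares (a 10 × 2 μm rectangle reads √104 ≈ 10.198 μm); a
single-pixel mask reports one pixel size by convention, and a polyline
trace reports its arclength. Detachment series must be non-increasing in
attached count; fractions are 1 − attached/initial. Group comparisons
delegate entirely to standard routines: one-way ANOVA with Tukey's HSD
(spacing-versus-stiffness designs) and two-way ANOVA with Šídák-adjusted
pairwise contrasts of condition within time point (detachment designs).

## Problem sizes and determinism

The test suite and the acceptance script use 30 fibers per spacing regime
(noise sd 0.05), 1000-bead fields, 10⁴-cell populations, and FEM meshes of
~2.5 × 10³ elements at the default resolution (~8 × 10³ at the doubled
resolution used for the convergence check) — sizes chosen so the full
suite runs in well under a minute per stage on one CPU while leaving all
recovery margins comfortably inside their tolerances. Every stochastic
step takes an explicit seed; identical seeds give bit-identical outputs.

## Known limitations

* 2D strain analysis; no traction-force reconstruction or stored-energy
  estimate.
* Linear kinematics at 10% eigenstrain; finite-strain effects unmodelled.
* Voxel-based geometry (mitigated, not eliminated, by cut cells); no
  boundary-fitted or quadratic elements.
* Mutual-NN matching degrades when displacement approaches bead spacing.
* Synthetic imagery omits several real-microscopy confounds (see above),
  and automated fiber tracing / SLS classification are out of scope.
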