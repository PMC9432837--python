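# podomech

Analysis toolkit for podocyte mechanobiology ex vivo: quantification of
sarcomere-like structures (SLSs), hydrogel strain mapping from embedded
microbeads, and a finite-element model of cell-process contractility on
elastic substrates.

## Background

Podocytes are the glomerular epithelial cells whose interdigitating foot
processes form the kidney's filtration barrier. When primary podocytes are
injured and re-seeded on soft hydrogels mimicking the glomerular basement
membrane (GBM, ~0.7–2.4 kPa), they assemble striated actomyosin bundles —
sarcomere-like structures — in which myosin IIA bands alternate with bands
of synaptopodin and α-actinin 4 at a period of roughly 0.8–1.4 μm that
depends on substrate stiffness and myosin activity. This package provides
the computational side of such a study for researchers in cell
mechanobiology and kidney physiology:

* **`synthgen`** — seeded generators of striated-fiber images, bead clouds
  displaced by closed-form deformation maps, and phenotype populations,
  each carrying exact ground truth so that every downstream stage is
  verifiable by parameter recovery (no microscopy download required).
* **`sarcomere_quant`** — intensity profiles along traced fibers, peak
  detection with sub-sample parabolic refinement, sarcomeric spacing
  (pooled and per-fiber statistics, fibers ≥ 6 μm), and a two-channel
  alternation index.
* **`strain_map`** — matched microbead positions → local deformation
  gradient **F** by windowed weighted affine fits → Green–Lagrange strain
  **E** = ½(**F**ᵀ**F** − **I**) → first principal strain e₁ in the
  adhesion plane.
* **`contract_fem`** — small-strain linear elasticity with an anisotropic
  stress-free eigenstrain ε\* = level·(−0.10, −0.08, −0.02) prescribed in a
  cell process (half-cylinder capped by a quarter-sphere, radius 4 μm,
  E = 1.0 kPa, ν = 0.3) bonded to an elastic slab (100 × 100 × 10 μm,
  E = 0.2–6.0 kPa or rigid, base fixed). Reports the interfacial shear
  σ_zx, maximum principal Cauchy stress, and cell-width change across
  stiffness and contractility sweeps.
* **`scoring`** — four-category SLS phenotype counts, cell length (maximum
  Feret diameter or traced polyline), detachment-assay fractions, and thin
  wrappers over one-way ANOVA + Tukey and two-way ANOVA + Šídák.

## Worked example

```python
import numpy as np
from podomech import *

# 1) synthetic striated fiber, 1.0-um period, two half-period channels
spec = StriationSpec(spacing=1.0, fiber_polyline=[[1.0, 7.0], [13.0, 7.0]],
                     noise_sd=0.05, seed=42)
image, truth = generate_striation_image(spec)
profile = extract_profile(image, spec.fiber_polyline, width=0.3)
peaks = detect_peaks(profile, "synpo")
spacings = compute_spacings(peaks, profile.length)
print(f"recovered spacing: {spacings.per_fiber_mean:.3f} um "
      f"({len(spacings.spacings)} sarcomeres)")
alt = alternation_index(detect_peaks(profile, "synpo"),
                        detect_peaks(profile, "myosin"))
print(f"myosin/synaptopodin alternation index: {alt:.2f}")

# 2) strain mapping of a 5% radial contraction
spec = DeformationSpec("radial_contraction", {"fraction": 0.05},
                       domain=(0, 0, 50, 50))
beads = generate_bead_field(spec, n_beads=1000, seed=7)
field, summary = strain_pipeline(bead_field=beads, bounds=(10, 10, 40, 40))
print(f"mean first principal strain: {summary['mean_e1']:.5f} "
      f"(analytic {0.5 * (0.95**2 - 1):.5f})")

# 3) contraction FEM across substrate stiffness
table = stiffness_sweep([0.2, 0.9, 6.0], [1.0])
print(table[["substrate_modulus_kpa", "max_abs_sigma_zx_kpa",
             "max_principal_cauchy_kpa", "cell_width_change_um"]]
      .to_string(index=False))
```

Output:

```
recovered spacing: 1.000 um (12 sarcomeres)
myosin/synaptopodin alternation index: 1.00
mean first principal strain: -0.04875 (analytic -0.04875)
 substrate_modulus_kpa  max_abs_sigma_zx_kpa  max_principal_cauchy_kpa  cell_width_change_um
                   0.2              0.017038                  0.073993             -0.476872
                   0.9              0.029841                  0.115783             -0.269610
                   6.0              0.039066                  0.148471             -0.068857
```

The spacing and alternation recover the generator's ground truth exactly;
the strain pipeline reproduces the analytic first principal Green–Lagrange
strain of a 5% radial contraction (e₁ = ((1−0.05)² − 1)/2 = −0.04875); and
the contraction model shows the mechanosensitive signature: interfacial
shear and peak cell stress increase monotonically with substrate modulus,
while the cell narrows most on the softest (0.2 kPa) substrate.

A command-line interface mirrors the library
(`podomech synth|spacing|strain|fem|score|detach|stats --help`).

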