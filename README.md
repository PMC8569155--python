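# capsidkit

Geometry, assembly statistics and mass accounting for bacteriophage capsids
that switch between **prolate** and **isometric** architectures.

Some tailed phages of *Staphylococcus aureus* build elongated (prolate)
heads: two icosahedral end caps joined by a cylindrical midsection of
hexamers. Mobile "pirate" elements (SaPIs/PICIs) can hijack this pathway by
supplying a capsid-protein homolog that occupies the pentamer positions and
forces assembly into a small isometric shell too small for the helper
genome. `capsidkit` implements the desk-scale computations behind this
biology, for structural virologists and phage/SaPI researchers:

- **`capsidkit.lattice`** — Caspar–Klug accounting. An icosahedral shell with
  cap vector (h, k) has triangulation number `T = h² + hk + k²`, 60·T
  subunits, 12 pentamers and 10(T − 1) hexamers. A 5-fold prolate shell with
  cap vector (h₁, k₁) and midsection vector (h₂, k₂) has
  `Q = T_mid = h₁h₂ + h₁k₂ + h₂k₁ + k₁k₂` and 30·(T_end + Q) subunits; a
  portal at one 5-fold vertex replaces a pentamer (−5 subunits). Includes
  the inverse problem (which architectures explain an observed census).
- **`capsidkit.geometry`** — explicit 3D capsomer-center models: icosahedral
  nets projected on a sphere, prolate shells as caps + a rolled hexagonal
  tube; adjacency graphs, ring partitions, helical rise/twist, shortest
  pentamer-to-pentamer lattice walks, pentamer–hexamer dihedral angles,
  CSV/PDB export.
- **`capsidkit.assembly`** — a stochastic model of the pentamer-species
  decision: each pentamer site draws the homolog with probability
  ρ/(1 + ρ); a commitment rule (first-site, or unanimous first ring) maps
  draws to isometric/prolate/aberrant outcomes, with closed-form oracles and
  Wilson confidence intervals.
- **`capsidkit.masses`** — average-mass arithmetic for intact proteins,
  cleavage-site mapping from deconvoluted ESI-TOF masses (N-terminal
  scaffolding-domain removal), and SDS-PAGE apparent-MW calibration via a
  quadratic fit of marker distance against log₁₀(MW).
- **`capsidkit.superpose`** — sequence-guided Kabsch superposition of
  subunit Cα traces with iterative rigid-core extraction.
- **`capsidkit.synthetic`** — seeded generators (noisy capsomer clouds,
  planted-cleavage proteins, gel ladders, rigid-transformed structures)
  that always emit their ground truth.

## Worked example

The prolate helper-phage procapsid, cap vector (2,0), midsection vector
(7,0), portal at the bottom vertex:

```python
from capsidkit.lattice import LatticeVectors, architecture_counts
from capsidkit.geometry import (build_prolate_lattice, helical_params,
                                ring_partition, shortest_pentamer_path)

v = LatticeVectors(2, 0, 7, 0)
arch = architecture_counts(v, has_portal=True)
print(arch.t_end, arch.t_mid, arch.cp_equivalent_subunits,
      arch.hexamer_count, arch.pentamer_sites)
# 4 14 535 80 11

lat = build_prolate_lattice(v, portal=True)       # a = 110.85 Å default
print([len(r) for r in ring_partition(lat)])      # [10, 10, 10, 10, 10, 10]
h = helical_params(lat)
print(round(h.rise, 1), h.twist)                  # 96.0 18.0
walk = shortest_pentamer_path(lat)
print(walk.n_steps, walk.n_hexamers_between)      # 7 6
```

The shell has T_end = 4 caps and a T_mid = 14 midsection: 535 capsid-protein
copies in 80 hexamers and 11 pentamers (plus the portal). The midsection is
six rings of ten hexamers at 96 Å rise and 18° twist per ring; the shortest
lattice walk from a bottom-cap to a top-cap pentamer spans 7 steps, passing
6 hexamers. The analysis drivers under `analysis/` (numbered in order) run
the census, the 3D model report, the assembly sweep, the mass mapping and
the superposition benchmarks, writing tables to `results/`.

## Notes

The real capsid-protein sequences of this system are not bundled (they are
not printable from desk data); `capsidkit.masses` and
`analysis/04_mass_mapping.py` accept any user-supplied FASTA plus observed
masses to map real cleavage sites, and are validated on planted synthetic
ground truth. See `docs/methods.md` for model conventions, defaults and
limitations.
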