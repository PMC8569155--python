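# Methods

## Lattice accounting

A quasi-equivalent icosahedral shell is indexed by a cap vector (h, k) on
the hexagonal lattice; its triangulation number is T = h² + hk + k², and a
closed shell carries 60·T subunits as 12 pentamers and 10(T − 1) hexamers.
A 5-fold prolate shell adds a midsection vector (h₂, k₂) with
Q = h₁h₂ + h₁k₂ + h₂k₁ + k₁k₂ and carries 30·(T_end + Q) subunits; the
portal, when present, occupies one 5-fold vertex and contributes no
capsid-protein copies. All censuses follow from these two conservation
identities and are enforced as invariants throughout the package.

Two consequences of the algebra are worth stating because they are easy to
get wrong:

- The four-term Q formula factorises as Q = (h₁ + k₁)(h₂ + k₂). It reduces
  to T for equal **achiral** vectors (k = 0) but gives (h + k)² ≠ T for
  equal chiral vectors, so `architecture_counts` treats the equal-vector
  case explicitly as a plain 60·T shell. Likewise, every midsection vector
  with the same index sum h₂ + k₂ describes the same physical tube; the
  canonical representative is (e, 0).
- A T = 4 shell has 12 pentamers and **30** hexamers (60·4 = 5·12 + 6·30).
  A 12:20 pentamer:hexamer ratio sometimes quoted for T = 4 violates
  subunit conservation and is not used anywhere in this package.

`enumerate_architectures` solves the inverse problem by brute-force scan in
canonical orientation (h₁ ≥ k₁, midsection (e, 0)), component bound 20 by
default (configurable).

## 3D capsomer models

One point per capsomer. Isometric shells: the hexagonal lattice is laid
over the 20 faces of an icosahedron (face corners at lattice points 0,
(h,k), and (h,k) rotated 60°), and face points are projected radially onto
the circumscribed sphere; pentamers sit at the 12 vertices. Prolate shells
(achiral caps, k₁ = 0 — the only seam geometry implemented): each cap is
the five apex faces of the (h₁, 0) icosahedral net on a sphere, and the
midsection is the hexagonal lattice rolled into a tube of 5·h₁ sites per
ring. Consecutive rings are offset by half a site spacing, which makes the
ideal tube achiral with helical rise a·√3/2 and twist 360/(10·h₁) degrees
per ring (18° for h₁ = 2). Between the two junction pentamer rings there
are e − 1 hexamer rings, where e = h₂ + k₂; for (2,0)/(7,0) this yields six
rings of ten, 60 midsection hexamers, and 40 hexamers whose entire
neighbourhood is hexameric — the caps contribute ten hexamers each.

Conventions and defaults:

- Frame: 5-fold axis = +z, portal cap at −z; units Å.
- Lattice constant default 110.85 Å, chosen so the midsection rise
  a·√3/2 evaluates to 96 Å. This is a stated default, not a measurement.
- Cap points are projected onto the cap sphere and tube points onto the
  cylinder; no blending at the seam (the tube radius 10a/2π and the
  junction-ring radius of the cap sphere differ by ~7%, which is well
  inside the adjacency tolerance). Deterministic and testable.
- Adjacency: two capsomers are neighbours iff their centre distance is
  below 1.35·a — midway between the first (1.0·a) and second (√3·a)
  neighbour shells; the factor is configurable. This reproduces pentamer
  degree 5 and hexamer degree 6 on every shell tested (components ≤ 5).
- Capsomer ids are assigned by sorting on (z, azimuth, radius), so
  construction is deterministic and exports are bit-stable.
- Ring partition clusters midsection hexamers by axial coordinate with a
  0.25·rise gap tolerance (configurable); a ring of unexpected size is a
  hard error. Twist is the n-fold circular mean phase difference between
  consecutive rings, reported in [0, 360/n).

**Pentamer walk.** `shortest_pentamer_path` reports both the number of
graph edges (`n_steps`) and the hexamers strictly between the endpoint
pentamers (`n_steps − 1`). On the (2,0)/(7,0) shell the closest bottom/top
pentamer pair is 7 lattice steps apart with 6 hexamers between; on the
isometric T = 4 shell every pentamer pair is 2 steps apart with one hexamer
between. The two conventions differ by one; both are surfaced so either
phrasing found in the literature can be checked directly.

**Dihedrals.** The angle between two adjacent capsomer planes is computed
from the stored outward normals as 180° minus the angle between normals
(coplanar = 180°, sharper fold smaller). Normals are radial from the cap
sphere (caps) or the axis (tube). For the T = 1 shell the pentamer planes
are the faces of the dual dodecahedron, so adjacent planes meet at
arccos(−1/√5) ≈ 116.57°; note this is *not* the icosahedron face–face
dihedral (138.19°), which describes a different pair of planes.

## Assembly-decision model

The underlying biology is qualitative: assembly nucleates on the portal
with five capsid-protein hexamers, and the species that occupies the
pentamer positions — the phage protein or its pirate-element homolog —
decides between the prolate and the isometric pathway, with intermediates
essentially unobserved. The quantitative rules here are an explicit
modelling choice, not a measured mechanism, and nothing in the model
implies assembly from preformed capsomers:

- each pentamer site draws the homolog with probability q = ρ/(1 + ρ),
  independently; ρ ≥ 0 is a free propensity parameter with no asserted
  biological value;
- `first_site` (default): the first pentamer commits the pathway and all
  pentamers follow its species — this encodes the strict either/or
  character of the observed outcome distribution;
- `unanimous_ring`: the five first-ring sites draw independently; mixed
  rings stall as "aberrant" particles (rings_built = 1, composition of the
  nucleus plus the drawn ring).

Completed-capsid compositions come from the lattice censuses: isometric
(2,0) with portal = 55 homolog + 180 CP copies (60 homolog copies
portal-free — isometric nucleation without a portal is allowed), prolate
(2,0)/(7,0) with portal = 535 CP copies. One seeded generator per run,
draws consumed in site order, so runs are exactly reproducible.
Closed-form outcome probabilities (q, q⁵, (1−q)⁵ …) serve as the oracle;
`outcome_summary` adds Wilson 95% intervals.

## Mass tools

Average (not monoisotopic) masses throughout, matching deconvoluted
ESI-TOF intact-mass reporting; the residue table is derived from the
pyteomics element masses at import and pinned in one place, water
18.0153 Da, cysteines reduced, no modifications (no formylation,
disulfides or adducts). Cleavage matching scans contiguous fragments in
three modes (`n_truncation` retains the C terminus — the
scaffolding-domain case and the default — `c_truncation`,
`any_contiguous`) with a default ±2.0 Da tolerance, returns all matches
sorted by |error|, and labels sites by their flanking residues
("between K87 and Q88"). An N-terminal truncation match delimits the
delta domain as residues 1..start−1.

Gel calibration fits log₁₀(MW) as a quadratic in marker migration
distance (direct prediction; the inverse direction would need
root-finding and is not the default). Markers on an exact quadratic are
recovered to numerical precision; ≥3 markers with distinct distances
required, non-monotone ladders warn.

The real capsid-protein sequences of the motivating system are not
bundled; the mapping workflow is validated on synthetic proteins with
planted cleavages (including the 402/128 and 355/87 length/boundary
combinations) and accepts any user FASTA for real data.

## Superposition

Alpha-carbon representative atoms; correspondences from a global
BLOSUM62 alignment (gap open 11, extend 1 — community defaults) unless
given explicitly; identity is counted over aligned columns and is
denominator-sensitive. The rigid fit is the SVD Kabsch solution with
determinant correction (always a proper rotation); tests cross-check it
against an independent rotation-grid search and scipy. Core extraction
iteratively discards pairs deviating more than 3.8 Å (default) and
refits, dropping at most the worst quartile per round so that a grossly
displaced domain cannot empty the set in one sweep, then settles at the
fixed point where the core is exactly the pairs within the cutoff; both
core and all-pair RMSD are reported under the final transform. The
cutoff and iteration cap are defaults of this package, not a published
procedure.

## Synthetic data

Generators mimic the statistical structure of each measurement — noisy
capsomer point clouds, random proteins with planted cleavage sites,
marker ladders on a known quadratic, rigidly transformed Cα traces —
with isotropic Gaussian noise and uniform residue composition. They are
deterministic under a fixed seed and always return the ground truth.
They do not emulate cryo-EM images or maps, real protease specificity,
correlated gel distortions, or realistic sequence composition: passing
tests demonstrate the correctness of the algorithms under their stated
assumptions, not performance on raw experimental data.

## Problem sizes

The default test and analysis runs use shells up to a few hundred
capsomers, 10⁴–10⁵ assembly trials, proteins of 100–400 residues and
chains of ≤300 residues — the natural scales of the system being
modelled; all analyses complete in seconds.

## Known limitations

- Prolate construction requires achiral caps (k₁ = 0) and 5-fold axial
  symmetry; 3-fold/2-fold elongation and conical lattices are out of
  scope.
- Capsomer positions are idealised centers; no per-subunit atomic
  modelling, no fitting into density maps.
- The assembly model has no kinetics, thermodynamics or titer
  predictions.
- MS/MS peptide identification and spectral deconvolution are out of
  scope; the mass tools start from deconvoluted intact masses.
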