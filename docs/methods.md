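# Methods

## The dual-probe pocket model

The object of interest is the set of transient cavities in the ligand
monolayer of a coated nanoparticle. A cavity is operationally defined by
two solvent-excluded surfaces (SES) of the host structure (core + ligand
atoms; solvent, free ions and analytes are excluded from the surface by
default): a water-sized probe of radius 1.4 Å and a large probe of 3.0 Å.
The region enclosed by the large-probe SES but not by the small-probe SES
is the candidate pocket region; its connected components (26-connectivity
by default, 6/18 available) are volume-filtered at 100 Å³ — about the
molecular volume of salicylate, or three bulk water molecules — and the
survivors are the pockets. Every frame of a trajectory is analyzed
independently; no tracking or merging across frames is attempted.

Per pocket the package records: volume (voxel count × spacing³); center
(unweighted mean of voxel centers — the cavity itself, not its walls);
depth (distance of the center from the mass-weighted center of the
`core` atoms, reported in nm; `deep` means < 1.3 nm, ties are shallow);
wall atoms (atom i is a wall atom iff a pocket voxel center lies within
Rᵢ + margin + spacing of its center, margin defaulting to the small probe
radius: an atom "forms the wall" if the water-sized probe inside the
pocket can touch it); and the fragment fingerprint described below.

## Grid SES: the free-ball formulation

Each SES-enclosed region is computed on an axis-aligned voxel grid
(default spacing h = 0.5 Å; the grid covers all atom spheres plus a
padding of the large probe + 2 Å, and the padding contract is re-checked
at SES time). The implementation is built on the exact clearance field

    A(y) = min_i ( |y − c_i| − R_i ),

evaluated per atom at every voxel center and capped at 6 Å. A voxel x is
marked **outside** SES(r) iff some voxel center y satisfies

    A(y) > r         (a probe of radius r fits at y), and
    |x − y| < g(y),  g(y) = min( floor_δ(A(y)), cap ),  δ = h/2,

with y further restricted to the connected component (6-connectivity) of
{A > r} touching the grid boundary — the probe must be able to roll in
from bulk solvent, so sealed interior voids count as enclosed. The
enclosed region is the complement. Coverage is evaluated with one binary
Euclidean distance transform per occupied radius bin.

Why this formulation rather than the textbook dilate-then-erode closing
with two distance transforms:

* **Soundness.** If the condition holds, a probe of radius r provably fits
  inside the free ball B(y, A(y)) while covering x, so no truly enclosed
  point is ever marked outside. The error is one-sided: a sub-voxel
  fattening of the enclosed region at the surface, the same sidedness as
  any center-sampled discretization.
* **Exact vdW containment.** |x − y| ≥ A(y) − A(x) (A is 1-Lipschitz), so
  a point inside an atom sphere (A ≤ 0) is never covered; the vdW
  voxelization is inside SES(r) for every r, exactly.
* **Structural probe monotonicity.** g does not depend on r and the
  witness set {A > r} (and its bulk-connected part) only shrinks as r
  grows, so SES(r₁) ⊆ SES(r₂) holds voxel-wise for r₁ < r₂ on a shared
  grid. An erosion thresholded on a per-probe distance transform does not
  have this property: its discretization error is probe-dependent, and in
  testing it produced isolated voxels of SES(1.4) outside SES(3.0) even
  for a single sphere. Monotonicity is a theorem for the continuous
  object, and the discrete engine is built to inherit it rather than to
  approximate it.

With this construction the SES of an isolated sphere equals its vdW
voxelization exactly on the default (atom-aligned) grid, and the engine
agrees with the independent oracle (below) on ≥ 99.9% of off-surface
voxels in practice.

Reachability semantics: "enclosed" means unreachable by a probe rolling
in from bulk. A sealed hollow shell is therefore inside both surfaces
(zero pockets) even when a probe would statically fit in its void, and a
cavity behind a narrow mouth is a pocket even when its interior could
host the large probe. Probe-center connectivity is approximated at
6-adjacency of accessible voxel centers.

## The brute-force oracle

`fixtures.oracle_point_in_ses` implements the rolling-probe definition
directly: a point is outside SES(r) iff some candidate probe center on a
dense grid (resolution ≤ half the main grid spacing) clears every
inflated atom sphere (|c − cᵢ| ≥ Rᵢ + r) and lies within r of the point.
The point-wise version is a literal exhaustive search in a (2r)-box; the
batch version (`oracle_ses_mask`) evaluates the same definition with a
KD-tree over the accessible candidate centers, restricted to the
bulk-connected component. `oracle_pocket_volume` integrates the
dual-probe difference on a fine sample grid using only the oracle
machinery. Engine and oracle share no surface-computation code — distance
transforms and radius-binned coverage on one side, explicit
sphere-clearance tests and nearest-neighbor queries on the other — which
is what makes their voxel-wise agreement a meaningful correctness check.
The point-wise oracle has no connectivity notion; it is used only on
systems without sealed probe-sized voids (random clusters).

## Fingerprints, occupancy, aggregate statistics

Each coating ligand is split by the fragment map into three contiguous
blocks: Inner (hydrophobic alkyl/oxa-alkyl), Central (amide or urea) and
Outer (oligo-ethylene-glycol terminus). A pocket's fingerprint counts
fragment *instances*: a (ligand, class) pair is counted once if at least
one of its atoms is a wall atom, so the count is insensitive to how many
atoms of a fragment touch the pocket. Core (metal) wall atoms stay in the
wall list but never enter fingerprints. Fingerprints are aggregated by
abundance (default report depth 14, ties broken lexicographically), and
fragment-class occurrence is the percentage of each class among all
counted instances.

An analyte molecule is *in* a pocket iff ≥ 50% of its heavy atoms lie
within the pocket voxel region dilated by the small probe radius (the
dilation admits guests seated directly against the wall, where voxels are
excluded by vdW overlap; the threshold is config-exposed). Each analyte
is assigned to at most one pocket — the one containing most of its heavy
atoms, ties to the lower pocket id.

Aggregates over a pocket table: pockets per frame (zero-pocket frames
count as zero; the ± value is the population standard deviation, ddof=0,
so the mean is exactly total pockets / total frames); volume classes
below 150 / 150–300 / above 300 Å³ and deep/shallow fractions; backbone
dihedrals over every sliding 4-tuple of the declared heavy-atom chain,
angles in (−180°, 180°], trans iff |φ| ≥ 120° (ties trans — a standard
conformer partition); hydrogen bonds by the common geometric criterion
(donor–acceptor heavy-atom distance ≤ 3.5 Å and D–H···A angle ≥ 135°,
both config-exposed), counted as satisfying (donor-H, acceptor) pairs
with "maximum possible" = the number of donor hydrogens. Donor hydrogens
are taken from an explicit mapping or resolved within 1.25 Å of the donor
heavy atom; a donor without a resolvable hydrogen is an error unless the
lenient flag is set.

`delta_g_from_ratio` is R·T·ln(K_high/K_low) with
R = 8.314462618 J/(mol·K), default T = 298.15 K (no temperature is tied
to the literature binding constants, so the standard state is assumed),
reported in kJ/mol.

## Units, conventions, degenerate inputs

Lengths are Å internally everywhere (nm-based formats are converted on
read); depths are reported in nm to match the field's plotting
convention. A voxel belongs to a sphere iff its *center* is inside
(ties inside). Frames are 0-based; trajectories are assumed pre-imaged —
no periodic-boundary handling is performed. Pocket ids are assigned per
frame by volume descending, ties by lexicographic center. Empty pocket
tables are legal everywhere (header-only CSV, zeroed summaries with an
`empty` flag); an empty atom set, a probe larger than the coverage cap,
a negative depth, or a padding violation raise typed errors. Bondi vdW
radii are the default (C 1.70, N 1.55, O 1.52, S 1.80, H 1.20,
Au 1.66 Å), overridable per element and per atom; hydrogens are included
in the surface when present (a heavy-atom-only flag exists). Whether
hydrogens and solvent belong in the SES is genuinely open for these
systems; both choices are config-exposed and the defaults (hydrogens in,
solvent out) are documented rather than asserted.

## Synthetic fixtures: what they emulate and what they do not

No experimental or MD datasets ship with the package; the generators in
`nanopockets.fixtures` build bead (united-atom) systems whose pocket
structure is known by construction.

* **Cup**: beads on a spherical shell minus a polar cap. The mouth is
  sized so the water probe enters and the large probe is bridged — one
  cavity of analytically controlled size. The sealed variant (aperture
  0°) must yield zero pockets.
* **Coated nanoparticle**: a bead-sphere core wrapped in a dense crust of
  overlapping bead layers. A *ligand* is the radial bundle of crust beads
  in one spherical-Voronoi sector of the anchor directions, and the
  fragment classes are radial layers (Inner innermost). This bundle
  representation, rather than single-file bead chains, is deliberate: a
  shell of thin chains is never water-tight — the dual-probe difference
  over any bumpy closed bead surface is a connected film threading every
  inter-chain interstice, which buries the constructed signal under one
  particle-spanning shallow pocket. The crust seals the monolayer so that
  the intact particle has exactly zero pockets, which is what makes the
  carved wedges a ground truth. Each wedge ("flower opening") displaces
  the beads of a few neighboring ligands off a flask-shaped void — a
  buried ball plus a neck through the outer surface that admits the
  1.4 Å probe but not the 3 Å one — and the void-lining beads are owned
  by the splayed group: the bent ligands are the cavity walls by
  construction. Frames beyond the first add seeded Gaussian jitter
  (σ = 0.05 Å), geometry noise rather than dynamics.

Both generators are seed-deterministic and validate themselves (leaky
shells, exhausted ligand sets, buried beads are errors). What passing
tests on these fixtures shows: the engine finds exactly the constructed
cavities, measures their volumes to within the stated tolerances against
an independent oracle, and attributes their walls to the right ligands.
What they do not show: anything about force-field realism, pocket
lifetimes, solvent structure, or the statistics of real ~µs trajectories
— fixture pockets are static and clean, real monolayer pockets are
transient and ragged, and per-frame counts or occupancy fractions
measured on fixtures are properties of the construction, not predictions
for real nanoreceptors.

## Problem sizes and numerical tolerances

Default problem sizes are chosen so the full test suite and the
reproduction script each run in minutes on one CPU: cup fixtures of
~70–140 beads analyzed at 0.25–0.5 Å spacing, coated-particle fixtures of
~1500 beads at 0.5 Å over 1–3 frames, oracle cross-checks on ≤ 60-atom
clusters at 0.4 Å with 0.2 Å candidate resolution. Grid-convergence and
rigid-motion tolerances for volumes are 5%, engine-vs-oracle volume
agreement 15% at 0.25 Å, voxel-wise SES agreement ≥ 99% outside the
one-voxel surface shell; these are stand-ins for the unreported
resolution of mesh-based SES implementations and hold with large margins
in practice (measured: ≤ 3%, ≤ 1.3%, and ≥ 99.95% respectively on the
default fixtures).

## Known limitations

* Voxel SES only: no triangulated surface, no surface areas, and
  sub-voxel features (films thinner than ~h) are not resolved.
* Probe-center connectivity at 6-adjacency can, in principle, bridge or
  sever pathological sub-voxel necks; refining the grid resolves such
  cases.
* The volume filter is applied per connected component after labeling;
  no mouth/aperture descriptors, no pocket tracking across frames, no
  binding kinetics.
* The H-bond pair count can exceed the donor-H denominator in crowded
  geometries (a donor-H satisfying the criterion with two acceptors
  counts twice); the alternative denominator min(donors, acceptors) is
  exposed as an option in spirit by passing explicit selections.
* Fragment instances are keyed by (ligand, class); ligands with two
  disjoint blocks of the same class would merge them (moot for the
  three-block ligands the data model targets, which are validated to be
  contiguous).
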