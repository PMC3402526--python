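# Methods

This note records the models, conventions and numerical choices behind each
stage, what the synthetic generators do and do not emulate, and the known
limitations.

## Conservation model

A column of the family alignment is **fully conserved** when exactly one
residue type is present and no member is gapped; **conservatively
substituted** when all non-gap residues fall inside a single Clustal
"strong" group (STA, NEQK, NHQK, NDEQ, QHRK, MILV, MILF, HY, FYW — the
groups are a configurable argument); **non-conserved** otherwise. Columns
are 0-based; residue numbers are 1-based positions in each member's
ungapped sequence, and the two numbering systems are linked by per-member
maps that are exact inverses on non-gap positions.

Conservation relevant to a hypoallergen question is assessed over the
family *excluding* the candidate member (`exclude_ids`), because the
question is where the candidate deviates from an otherwise-invariant
family; the pipeline exposes this as `conserve_over_family_only` (default
on). An **exclusive difference** is a column where every non-candidate
member carries one identical residue (substitution) or a gap (insertion)
and the candidate deviates. Deletions in the candidate are not classified
(none occur in the motivating family); with `restrict_to_conserved` off,
non-candidate gaps are tolerated in substitution columns. Both directions
of a substitution are reported explicitly as family residue → candidate
residue rather than in compact mutation notation, which is ambiguous about
direction.

Pairwise identity divides identical pairs by mutually non-gap columns
(insertion-robust); the optional internal aligner is a global BLOSUM62
alignment with affine gaps (open 10, extend 0.5). A user-supplied alignment
is always the authoritative input — the internal aligner exists for
identity computations and synthetic tests.

## Structures

PDB input goes through gemmi with fixed read policies: first model,
highest-occupancy altloc (label order breaks ties), waters and non-standard
heteroatoms dropped. Hydrogens are neither required nor built; **all
surface and electrostatic computations are heavy-atom computations**, and
every report records this. Van-der-Waals radii default to a Chothia-style
protein set (N 1.65, O 1.40, S 1.85, carbonyl/aromatic/sp² C 1.76,
aliphatic C 1.87 Å); a Bondi-style set is selectable. The B-factor column
of written PDBs doubles as a numeric output channel (relative exposure,
surface potential) clamped to the field width, so any viewer can render the
results without bespoke formats.

## Superposition

Kabsch closed-form least squares with the SVD determinant correction, so a
reflection can never be returned (the guard is property-tested on mirrored
point sets). Collinear or coincident point sets are rejected rather than
silently under-determined. Cα pairing between homologs goes through the
alignment, not residue-number equality — a one-residue insertion shifts all
downstream numbering, and alignment-driven pairing is what keeps the
register correct. Worst-fit segments rank sliding-window (default 3) mean
deviations, greedily take non-overlapping top windows and grow each across
flanking residues deviating at least half the window mean, so a displaced
loop is reported as one segment; with zero deviation everywhere the ranking
is stable by position. Window 3 resolves three-residue segments, the
shortest structurally interesting case.

## Solvent accessibility

Shrake–Rupley: each heavy atom inflated by the probe radius (default 1.4 Å,
water) is covered with an `n_points` (default 960) generalized-spiral
(golden-angle) lattice; the accessible fraction times the inflated-sphere
area is the atom's SASA. Two deliberate choices:

- **Deterministic lattice, not random points** — identical inputs give
  bit-identical areas.
- **Lattice fixed in the molecule frame** — the lattice is expressed in the
  principal-axes frame of the atom centers (signs fixed deterministically),
  so rigid motions of the molecule move the lattice with it and leave every
  area unchanged to ~1e-6 relative. A seeded random-point mode remains for
  convergence experiments.

Neighbor culling uses a k-d tree (equivalent to cell lists for this query
pattern; no behavioral effect). Accuracy benchmarks: a single atom matches
4π(r+probe)² to < 0.5% at 960 points; two overlapping spheres match the
closed-form cap area to < 1%; a five-atom cluster matches a 10⁶-sample
Monte-Carlo rejection oracle to 2%; an independent implementation (biotite)
agrees to < 1% total at matched radii.

Relative exposure divides a residue's SASA by the same residue's SASA as X
in a programmatically generated extended Gly-X-Gly tripeptide (φ = ψ = ω =
180°, trans rotamer, same lattice parameters, cached per parameter set).
Generating the reference internally keeps the normalization self-consistent
with the engine instead of importing a table computed under unknown
conventions; absolute percentages can therefore shift a few points against
other software, which is why patch-level conclusions use the 30% exposure
threshold rather than exact percentages. Values above 100% (distorted
conformers) are flagged, never clipped.

## Patches

A patch is a set of residues in the numbering of the alignment's reference
member. Its **conserved area** is the summed per-residue SASA of the
members whose columns are fully conserved — the simplest auditable
definition; exposure-weighted variants were rejected as opaque. Members
absent from the structure are reported, never silently dropped. Patch
**status** for a candidate: substituted if an exclusive substitution falls
on a member column; insertion-adjacent if an exclusive insertion lies on
the patch or within the adjacency cutoff (default 8 Å, Cβ anchor with Cα
for glycine — a typical epitope-footprint radius, configurable); both
combine; otherwise conserved. **Contiguity** counts connected components of
the patch residue graph under the same neighbor rule — patches are expected
to be sequence-discontinuous but spatially connected, and the component
count is the sanity check.

## Electrostatics

Formal pH-7 charges: Asp/Glu −1 (split −0.5/−0.5 over the carboxylate
oxygens), Lys +1 on NZ, Arg +1 on CZ, His neutral, chain termini +1/−1
(C-terminal charge split over O/OXT when OXT exists). Missing tip atoms
fall back to Cβ then Cα with the fallback recorded. Formal charges, not a
force field: they make the loss of a lysine directly visible in the surface
potential, which is the comparison this analysis needs.

The default potential engine is the analytic screened Coulomb
(Debye–Hückel) superposition in kT/e, exact and linear in the charges, with
κ and the Bjerrum length from first-principles constants (at 298.15 K,
ε = 80, 0.15 M: l_B = 7.01 Å, λ_D = 7.93 Å). Evaluation points sit one
probe radius outside each solvent-exposed atom along its mean accessible
direction, tagged by residue, so potentials aggregate per residue for
homolog comparison (RMS difference, sign flips, largest shift).

The optional finite-difference solver honours the two-dielectric continuum
setup: linearized Poisson–Boltzmann on a 7-point Cartesian stencil,
harmonic-mean link dielectrics between ε_in = 4 (inside atom vdW spheres)
and ε_out = 80, ionic screening only outside atoms inflated by an
ion-exclusion shell (2 Å), cloud-in-cell charge spreading, and analytic
Debye–Hückel boundary values (which keep the box compact). The symmetric
positive-definite system is solved by conjugate gradients (tolerance 1e-8;
non-convergence raises with the residual; a direct sparse solve is
selectable). Verified limits: uniform-ε no-salt matches Coulomb within 5%
at 5–15 Å on a 1 Å grid; uniform-ε 0.15 M matches the screened Coulomb
within 7% at 8–15 Å; halving the grid spacing moves evaluated potentials
by < 10%. The mode is flagged experimental: grid dimensions are this
package's own defaults, and no claim is made of reproducing any particular
grid solver's energies. Display clamping (±5 kT/e for rendered PDBs) never
touches stored values.

## Synthetic generators

Peptides are built by natural-extension (NeRF) placement from ideal bond
lengths/angles (N–Cα 1.458, Cα–C 1.525, C–N 1.329, C=O 1.231 Å) with
uniform backbone dihedrals, and side chains from a compact per-residue
Z-matrix with a single trans default rotamer. This yields correct topology,
counts and charge sites and near-ideal geometry (extended Cα–Cα 3.80 Å;
helix rise ≈ 1.56 Å, i→i+4 Cα ≈ 6.4 Å) — sufficient for surface and charge
work. It does **not** emulate: real rotamer distributions, ring-closure
exactness for proline, Ramachandran variability, or packed tertiary
structure. Passing tests therefore demonstrate the correctness of the
*machinery* on known ground truth, not the realism of any particular fold;
conclusions about a real protein always require the user's own models.

Toy families plant conserved columns, within-group conservative variation,
member-exclusive substitutions and one insertion, with the unplanted
columns constructed so no spurious exclusive difference can arise (the
target always copies some family member; conservative columns always vary
among the non-target members). The standard bundle mirrors the structure of
a real hypoallergen study — four exclusive substitutions plus one
insertion, five patches of which two are substituted, one
insertion-adjacent and two untouched, and one substitution outside all
patches. All generators are pure functions of (spec, seed).

## Problem sizes and determinism

The test suite and the acceptance script run entirely on synthetic inputs:
6-member, 60-column families; 10–60-residue peptides; single-charge FD-PB
grids of ≤ ~100k nodes. These sizes exercise every code path while keeping
a full run in seconds. Reports are byte-identical across reruns of the same
config and seed; the only randomness anywhere is the seeded generator
input.

## Known limitations

- Heavy-atom SASA and formal charges only; no hydrogens, no pKa shifts,
  no partial-charge force field.
- The Gly-X-Gly reference conformation is this package's own; absolute
  exposure percentages are comparable within the package, approximately
  across packages.
- The FD-PB mode is linear PB only, without focusing or nonlinear terms.
- Comparative model construction, model validation and rendering are out of
  scope: structures come in as PDB files, results leave as tables and
  B-factor-annotated PDBs.
- Patch membership is user input. No de-novo epitope prediction is
  attempted; an example synthetic patch table is generated by
  `make_analysis_bundle`, and real studies supply their own transcription
  of published patch definitions.
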