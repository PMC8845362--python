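# Methods

## Scope and data model

The pipeline analyses *pairs* of crystal structures of one protein. A
structure is a single model of heavy atoms grouped into residues and ligands;
the apo/holo state is derived, never declared: a structure is holo exactly
when it retains at least one ligand after filtering. Hydrogens are dropped
everywhere (they are absent from most crystal structures and would bias RMSDs
and grid occupancy), and alternate locations are collapsed to the
highest-occupancy conformer, ties broken by altloc label order.

### Filters

* **Resolution.** A structure passes when its recorded resolution is
  *strictly* below the cutoff (default 3.0 Å); "better than 3.0 Å" is read
  as lower, the crystallographic convention. Structures without a recorded
  resolution are rejected with a log message rather than an error.
* **Additives.** Waters are always removed. The shipped additive list
  (`data/additives.txt`) holds common PEGs, cryoprotectants, buffer
  components and ions, and is user-replaceable; filtering is idempotent.
  Hetero groups with fewer than four heavy atoms (isolated ions and the
  like) never define the holo state; the threshold is configurable.
* **Oligomer.** Monomers pass; multi-chain structures pass as homo-multimers
  when all chain pairs reach 95% global-alignment sequence identity
  (normalised by the longer chain). Hetero assemblies are excluded so that
  protein–protein contacts do not masquerade as ligand-induced motion. The
  0.95 default tolerates point mutations and ragged termini while rejecting
  genuinely different chains.

### Residue correspondence

Chains are assigned greedily by descending sequence identity; residues are
then matched by author numbering (number + insertion code). When numbering
schemes disagree (fewer than half of the shorter chain matches), the mapping
falls back to a global sequence alignment. Unmatched residues are excluded
from every RMSD. A pair needs at least 30 mapped residues. Positions whose
residue identity differs between the members (mutations) keep their Cα in
the global fit but are excluded from the heavy-atom profile, where the atom
sets are not comparable.

## Superposition and RMSD

The rigid fit minimises the Cα RMSD over mapped residues via the Kabsch
algorithm: SVD of the 3×3 cross-covariance with a determinant correction so
the result is always a proper rotation. Collinear or coincident point sets
(second singular value < 1e-8) raise a degeneracy error rather than
returning an arbitrary rotation. No outlier trimming is applied — the
2.0 Å motionless threshold is defined on the plain least-squares fit.

Per-residue RMSD is computed over the heavy atoms shared by name between the
two copies of a residue, **under the global transform** (no per-residue
refit). This choice makes side-chain rearrangements visible at full
magnitude: a refit would zero out any internal rigid rearrangement. Residues
sharing fewer than two heavy atoms are skipped with a log entry.

The fit uses Cα only (conformation-robust, equal weight per residue); the
profile uses all common heavy atoms (side chains included). Tests cross-check
the SVD route against an independent quaternion closed-form RMSD (largest
eigenvalue of the 4×4 key matrix) to 1e-8 on random point sets.

## Grid pocket model

The ligand site is a sphere around the ligand centroid; its radius is the
ligand's radial extent plus a 6 Å margin (at least 8 Å), so the grid covers
the cavity beyond the ligand's own reach. Within the sphere, a cubic grid
(default spacing 0.8 Å) is built and a cell is *blocked* when its centre
lies within probe + vdW radius of any protein heavy atom (probe 1.4 Å; vdW
by element: C 1.70, N 1.55, O 1.52, S 1.80 Å; unknown elements fall back to
carbon). The bound ligand never occludes its own pocket.

Bulk solvent is removed deterministically: empty cells outside the convex
hull of the site's protein atoms are solvent seeds, and every empty cell in
a 6-connected component containing a seed drains away. What remains is
enclosed cavity; its face-connected components are the sub-pockets, largest
first, with volume = cell count × spacing³. The partition is independent of
cell enumeration order (component labelling is deterministic). Matching two
models cell-by-cell requires an identical grid frame, which the pipeline
guarantees by building both states' models on the frame of the first
structure (the second member's coordinates, and its ligand when the first is
apo, are carried through the pair superposition).

Grid volumes converge with spacing (verified against analytic spherical
cavities: ≈1.5% error at 0.5 Å spacing) but are method-specific; they are
internally consistent, not comparable to volumes from other cavity
detectors.

## Motion classification

* **Overall.** motionless ⇔ Cα RMSD < 2.0 Å. The boundary value 2.0 Å is
  assigned to *motion*: the defining phrases ("smaller than" / "greater
  than") leave exact equality unassigned, and the choice is measure-zero;
  it is documented here and fixed in code.
* **Pocket.** Pocket residues are those with minimum heavy-atom distance to
  the ligand strictly below 5.0 Å (strict inequalities at every distance
  cutoff). A pocket-motion class is assigned only when the *maximum*
  per-residue RMSD over pocket residues exceeds 2.0 Å — "at least one
  moving residue", rather than the mean, which dilutes single-gatekeeper
  motions.
* **Classes.** Priority order PC → PF → PE → PS → OM, topology before
  volume, because creation and fusion usually also change volume and the
  more specific signature should win:
  * PC: apo volume < V_min and holo volume ≥ V_min (V_min = 50 Å³, about
    the smallest cavity that can hold a fragment-sized ligand);
  * PF: the number of sub-pockets at the ligand site (a sub-pocket counts
    when one of its cells comes within 2.0 Å of a ligand atom) drops from
    ≥ 2, and one holo component absorbs ≥ 50% of the cells of at least two
    apo components;
  * PE / PS: relative volume change (V_holo − V_apo)/V_apo beyond ±25%,
    separating class-defining change from breathing noise;
  * OM: a pocket residue moves but volume and topology stay within those
    bounds.
  All thresholds are config-exposed (`PocketMotionParams`); no published
  values exist for them, so they are declared design choices, not recovered
  constants.
* **Direction.** For apo/holo pairs the comparison is oriented apo → holo
  regardless of input order; for same-state pairs the first member plays the
  "before" role and its ligand defines the grid frame. Holo–holo pairs with
  two distinct sites are analysed at the first structure's site; the other
  site can be analysed by swapping the pair.
* **Typical pair.** Among redundant records of one protein and motion type,
  the representative has the largest pocket-residue RMSD (pocket motions) or
  overall RMSD (overall motions); ties break to the lexicographically
  smaller pair id, making the selection order-independent.

## Preference statistics

Frequencies count each (structure, residue) occurrence once — a residue
present in three structures counts three times, matching complex-level
aggregate counting; only the 20 standard amino acids enter the tables.
Overall composition is computed over the same holo corpus as the pocket
tables so numerators and denominators share a universe. The enrichment test
is a two-sided two-proportion z-test with pooled variance and no continuity
correction (equivalent to a 2×2 Pearson chi-square, which the tests use as
an oracle); raw p-values are reported by default with a Bonferroni option,
since the 5%/1% star convention the labels follow is a per-test one.
Pocketphobic = depleted at both 3.0 and 5.0 Å; everything else is
pocketphilic (enrichment at either cutoff indicates short- or long-range
interaction preference). Motion frequency per amino acid is reported in both
normalisations — per pocket occurrence of that amino acid, and as a share of
all moving residues — because either convention is defensible.

## Synthetic generator

The generator produces the study conditions for every stage; its defaults
are fixed once:

* **Helix scaffolds** (default 60–80 residues): ideal α-helix Cα trace
  (2.28 Å radius, 100°/turn, 1.5 Å rise → 3.80 Å Cα–Cα), approximate
  backbone atoms, side chains as idealised extended chains with standard
  atom names. Designed motions are realised exactly: whole-residue
  translations give per-residue RMSD equal to the displacement; side-chain
  displacements are scaled by √(n_heavy/n_side) so the all-atom RMSD equals
  the target while the backbone — and hence the global Cα fit — stays put;
  flips are rigid rotations about the Cα–Cβ axis. Flexible pairs displace
  every residue by a smoothed random field projected free of rigid modes and
  rescaled until the closed-form optimal RMSD hits the target to 1e-9, so
  "designed overall RMSD" is exact, not approximate.
* **Lattice blocks** (3.0 Å cubic lattice of tight 4-atom residues) realise
  the five pocket classes by carving cavities: the carve radius adds the
  occlusion distance, so the realised cavity always *contains* the nominal
  sphere; lattice discreteness only enlarges it. Class geometries are sized
  with wide margins (e.g. expansion designs a ~4.5× volume ratio against the
  1.25× threshold) so discreteness cannot flip a class. Each fixture places
  a rigid 8–9-atom ligand spanning the holo cavity and displaces one "gate"
  residue 3.2–4.8 Å from the ligand, away from the cavity, by > 2 Å.
* **Hollow shells** tile a sphere of radius r + probe + vdW(C) with carbon
  atoms, so the enclosed cavity is the analytic ball of radius r up to
  O(spacing²) boundary error — the oracle for volume accuracy.
* **Binding-site structures** place residues radially at controlled minimum
  distances from a compact ligand (within 0.02 Å), with per-shell
  composition. The default composition corpus enriches Arg/Trp/His in the
  2–3 Å shell against a uniform background, so the MUE profile peaks at
  3.0 Å by construction. Null calibration draws overall and pocket counts
  from the same multinomial law — under exchangeability only residue
  identities matter, so sampling counts is the corpus-level null.

Everything is deterministic given the seed (a single `numpy` Generator per
build step). What the generator does **not** emulate: real packing and
secondary-structure context, correlated backbone/side-chain motion,
crystallographic noise, sequence realism, and physically relaxed geometry
(clash avoidance is approximate). Passing tests therefore demonstrate the
correctness of the measurements and decision rules, not corpus-level
biological conclusions; corpus-scale percentages require real PDB-wide input.

## Problem sizes and numerics

Default test/acceptance sizes: 100 random point sets (n = 4–50) for the
superposition oracle; 100 random rigid transforms for invariance; a 10-pair
pocket suite (two exemplars per class, lattice blocks of ~500–1300
residues); spheres of radius 3–5 Å at 0.5/1.0 Å grids; 6-structure
composition corpora; 2000 replicates for test calibration. These sizes make
each property's verdict unambiguous while keeping a full run to a couple of
minutes on one core. Numerical tolerances: 1e-8 for RMSD oracle agreement
and rigid invariance; 0.01 Å for designed per-residue displacements; 0.05 Å
for designed overall RMSD; 15% for grid volumes at 0.5 Å spacing.

## Known limitations

* Pocket volumes are stand-in grid measurements: deterministic and
  convergent, but not calibrated against any external cavity detector.
* The PE/OM and PS/OM boundaries (±25% relative volume) and V_min = 50 Å³
  are declared conventions; different choices shift borderline classes.
* Only the first ligand of the first structure defines the analysed site;
  multi-site proteins need one pass per site.
* Single-model crystal structures only; NMR ensembles and flexible-fit
  superposition (hinge/domain decomposition) are out of scope.
* UniProt-based pair grouping is not performed; callers group structures by
  identity (sequence identity tooling is provided).
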