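# Methods

This note records the models implemented, the parameter choices that
matter, the numerical decisions, and what the synthetic fixtures do and do
not establish about real structures.

## Constraint network

Structures are read through gemmi (PDB or mmCIF; outputs are always PDB).
Waters and crystallization additives are excluded by default — the analysis
concerns the protein network. Alternate locations default to the
highest-occupancy conformer (ties broken by altloc identifier), giving a
deterministic single-conformer network. Author (PDB) residue numbering is
used everywhere, with inclusive 1-based region selections.

Polar hydrogens are placed internally by ideal geometry: the backbone amide
H in the peptide plane at 1.0 Å from N, anti to the preceding carbonyl;
side-chain hydroxyl, thiol, ammonium, guanidinium, amide, imidazole
N-epsilon and indole hydrogens by standard internal coordinates. Histidine
defaults to the N-epsilon tautomer unless hydrogens are already present.
Placement is idempotent and never moves heavy atoms; a missing anchor atom
skips that hydrogen with a warning.

Covalent bonds come from per-residue templates plus inter-residue peptide
links (C–N ≤ 2.0 Å, otherwise a chain-break warning) and disulfides
(SG–SG < 2.3 Å). Bonds with no free torsion — peptide, carbonyl,
carboxylate, amide, guanidinium and aromatic-ring bonds, and terminal
pendants such as X–H — are *locked*; all other single bonds are
*rotatable*.

Hydrogen bonds pass three geometric gates (donor–acceptor < 3.6 Å,
hydrogen–acceptor < 2.5 Å, D–H···A angle > 110°) and are scored with the
Mayo-form well E = V₀[5(d₀/d)¹² − 6(d₀/d)¹⁰]·cos²θ, V₀ = 8 kcal·mol⁻¹,
d₀ = 2.8 Å, clamped to [−10, 0]. A single cos²(θ_DHA) angular factor is
used for all hybridization cases; the full donor/acceptor case split would
additionally need acceptor-base geometry and changes only the energy
labels, not the detection. Donor–acceptor pairs fewer than four covalent
bonds apart are excluded so that covalently enforced geometry is not
double-counted as a hydrogen bond.

Salt bridges — Asp/Glu carboxylate O against Lys NZ / Arg NE,NH1,NH2 /
His ND1,NE2 within 4.0 Å — are classified before hydrogen bonds, one per
residue pair, and pinned at −10 kcal·mol⁻¹ so they survive every dilution
cut-off; a residue pair classed as a salt bridge is not additionally
counted as a side-chain hydrogen bond. Histidine counts as basic in the
salt-bridge census (the convention of the common web servers) even though
its protonation is pH-dependent.

Hydrophobic tethers join carbon/sulfur atoms of residues more than two
apart in sequence (or on different chains) when their distance is below the
van der Waals sum plus a 0.25 Å slop; only the shortest contact per residue
pair is kept, so one contact patch contributes one tether. The tether
criterion (slop, eligible elements, dedup rule) is the main place where
reasonable implementations differ; the TSV constraint dump exists so any
census can be traced interaction by interaction, and all gates are
parameters of `InteractionParams`.

## Body-bar pebble game

Every atom is a 6-DOF rigid body; constraints contribute bars (locked
covalent 6, rotatable covalent 5, polar 5, tether 2 ambient / 1 cold).
Parallel bars between the same pair sum and cap at six. The (6,6) pebble
game accepts a bar exactly when seven pebbles can be gathered on its
endpoints; by Tay's theorem the accepted count is the generic rank of the
body-bar framework, so the combinatorial game is exact for generic
geometry — no coordinates enter. Acceptance is a matroid rank and therefore
independent of insertion order; the implementation fixes the insertion
order (constraint-list order) and the depth-first search order anyway so
that pebble placements are bit-reproducible.

Floppy modes are reported as total free pebbles minus six: internal degrees
of freedom after removing one set of global rigid-body motions. For a
connected framework this equals 6V − 6 − rank. With this convention the
relative rigid-body motions of disconnected components count as floppy,
which is what the generic-rank identity measures; protein networks analysed
here are connected, where the distinction vanishes.

Rigid clusters are found after the game by pinning six pebbles on a seed
body and testing whether a seventh pebble is reachable from neighbouring
bodies; a failed (read-only) search marks its entire visited region as
rigid with the seed. Mutual rigidity is generically an equivalence, so the
clusters partition the bodies; they are labelled 1..K by size descending,
ties broken by smallest member, for deterministic outputs. Tests verify
the decomposition against an independent null-space oracle (ground one
body's six columns of a random generic bar matrix; a body is rigid with the
ground iff its null-space rows vanish).

Rigidity dilution rebuilds the network at each cut-off of a strictly
decreasing series (default −1, −2, −3, −4 kcal·mol⁻¹) in either regime.
Because each lower cut-off retains a subset of constraints, the largest
cluster size is non-increasing along the series, and the cold regime can
never out-rigidify the ambient one at equal cut-off.

## Elastic network model

One node per residue at the Cα position (polymer residues only; waters and
ligands contribute no nodes), uniform springs of unit strength between all
node pairs strictly closer than 10.0 Å, both chains in one network. Only
mode shapes matter downstream, so the spring constant is arbitrary. The
Hessian is the standard anisotropic form. Six rigid-unit motions
(translations and rotations about the centroid) are constructed
analytically and orthonormalized; collinear node geometry (where only five
independent rigid motions exist) is rejected by `trivial_modes` but handled
internally, so the two-node dumbbell still yields its closed-form
non-trivial eigenvalue 2k.

The lowest non-trivial modes are extracted by shifted block inverse
iteration: repeated solves against H + σI (σ = 10⁻⁶·λ_max, λ_max a
Gershgorin bound), deflation against the rigid-body null space, QR
re-orthonormalization and Rayleigh–Ritz extraction in the iterated
subspace, with four guard vectors beyond the requested count. The block
form was chosen because plain sequential inverse iteration stagnates on the
near-degenerate eigenvalue pairs that symmetric structures (helices,
symmetric dimers) produce; the Hessian is never fully diagonalized.
Convergence requires every requested residual ‖Hv − λv‖ ≤ 10⁻⁹·λ_max.
Degenerate pairs are returned in eigenvalue order with a sign convention
(first non-negligible component positive) for reproducible indexing. Modes
are numbered 07 upward, after the six trivial modes.

## Geometric simulation

The constraint system holds, at their input-structure values: covalent
bond lengths (1–2), angle surrogates (1–3 distances), locked torsions
(1–4 distances across locked bonds); polar and tether contacts may shorten
but not lengthen beyond their input value; all other pairs obey a steric
floor of 0.85 × the van der Waals sum (1–2/1–3/1–4 neighbours and
hydrogen-bond H···acceptor pairs exempt). Floors are additionally capped at
the input-structure separation, so the input itself is always a valid
state and pre-existing close contacts are preserved rather than "repaired".

Each step adds the mode bias — the unit-normalized all-atom vector obtained
by giving every atom its residue's Cα displacement, scaled to 0.1 Å — and
then restores geometry by iterative projection: per constraint, the
correction that satisfies it exactly with both atoms moved equally and
oppositely; corrections are accumulated and applied as per-atom averages
(simultaneous projection), swept until the largest violation falls below an
inner tolerance of 0.03 Å or 200 sweeps elapse. Simultaneous rather than
sequential (Gauss–Seidel) projection was chosen so sweeps are vectorized
and bit-deterministic regardless of constraint order; the acceptance
contract is identical — a step whose residual violation exceeds the 0.1 Å
tolerance halts the run as `geometry_unrestorable`. A single stretched bond
is restored in one sweep with the correction split equally between its two
atoms. Steric pair lists are rebuilt per step from a KD-tree with a motion
margin. Runs are pure functions of their inputs: biasing along a uniform
translation conserves every internal distance to 1e−9 and accumulates
exactly 0.1 Å of coordinate-vector displacement per step.

Frames (including frame 0) are recorded every 50th step by default, giving
at most 11 frames for a 500-step run; the per-frame maximum violation is
logged.

## Structural statistics

RMSD uses Kabsch superposition (proper rotation, via
`scipy.spatial.transform.Rotation.align_vectors`) after pairing atoms by
residue number and atom name. RMSF superposes frames onto the ensemble
mean (mean recomputed once), then takes the per-residue root-mean-square
Cα displacement; the `raw` alignment variant skips superposition, which is
the right comparison for synthetic noise ensembles since superposition
absorbs six degrees of freedom. B-factor profiles report the mean Cα
B-factor over the whole deposited model (all chains) and over a region,
plus their ratio (`normalized_fold`) — the region is a parameter precisely
because which mean to normalize by is a genuine convention choice. SASA is
Shrake–Rupley (via biotite) on heavy atoms with single-element van der
Waals radii, probe 1.4 Å, 960 points per atom; interface area is
(SASA_A + SASA_B − SASA_AB)/2. The composition census prefers SEQRES so
counts do not depend on residues disordered out of the coordinates, and
records which source it used.

## Synthetic fixtures

All algorithmic testing runs on deterministic generated inputs; fixtures
are pure functions of their arguments, and every seed is an explicit
parameter.

* `ideal_helix` — backbone at φ = −57°, ψ = −47° with ideal bond geometry;
  the i→i+4 carbonyl–amide ladder falls inside the hydrogen-bond gates by
  construction (a 20-mer yields 16 backbone hydrogen bonds of −5.2
  kcal·mol⁻¹ each).
* `two_helix_dimer` — two 18-residue helices packed antiparallel at
  10.49 Å axis separation. Interface leucines give seven inter-chain
  tethers, an Asp–Lys pair one inter-chain salt bridge, and interface
  serines hydrogen-bond toward the opposite chain, so the ambient network
  welds the chains into one spanning rigid cluster while the cold network
  does not — a miniature of the dimer-interface behaviour the analysis is
  designed to expose. The side-chain torsions and separation were fixed
  once, by construction against the package's own detectors, and the 0.005
  Å seeded jitter keeps the seed meaningful without crossing any detection
  threshold.
* `random_bodybar` — seeded random multigraphs, the substrate for the
  pebble-game oracle tests.
* `noisy_ensemble` — isotropic Gaussian per-atom displacements for RMSF
  calibration against the closed form σ√(3(n−1)/n).

What the fixtures do not show: ideal geometry has none of the strain,
missing atoms, alternate conformers or heteroatoms of crystal structures
(those paths are exercised separately with hand-written inputs); the
dimer's hydrogen-bond energies are nearly uniform, so its dilution series
is flat between −1 and −4 kcal·mol⁻¹ (the shattering is visible only below
−5 kcal·mol⁻¹), whereas real structures lose constraints throughout the
range; and fixture sizes (≤ 60 residues) probe correctness, not large-N
performance.

## Problem sizes and tolerances

The test suite and the acceptance script use 100 random graphs (≤ 8
bodies, ≤ 40 bars) for the rank oracle, 20 insertion orders per graph for
order-invariance, helices of 20–60 residues for the dense-solver
comparison (agreement to 1e−6 relative), 400–1000 frames for RMSF
calibration (5% band), and full 500-step geometric simulations on the
dimer fixture. Equality of pebble counts with the oracle is exact, not
approximate. SASA uses 960 points per atom, where halving the sampling
changes totals by < 0.5%.

## Known limitations

No aromatic-stacking or cation–π terms, no metal coordination, no explicit
solvent. Hydrogen placement is internal and idealized rather than taken
from a dedicated protonation tool; His protonation is a fixed convention.
The geometric simulation propagates Cα modes to all atoms by per-residue
block replication, the simplest faithful scheme; it cannot break or reform
hydrogen bonds during motion. mmCIF is read but not written. The pebble
game is exact only for *generic* frameworks — pathological exactly-special
geometries (which do not occur with floating-point crystal coordinates)
could in principle differ from the combinatorial answer.
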