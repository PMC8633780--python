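"""Covalent, polar and hydrophobic constraint detection.

Builds the typed, energy-labelled constraint network over atoms that feeds
the body-bar pebble game and the geometric simulation engine:

* covalent bonds from residue templates (+ peptide links and disulfides),
  split into torsionally locked and rotatable bonds;
* hydrogen bonds from donor-hydrogen-acceptor geometry, scored with a
  Mayo-form distance well modulated by the D-H...A angle, clamped to
  [-10, 0] kcal/mol;
* salt bridges (charged donor to charged acceptor within 4 A), pinned to
  -10 kcal/mol so they survive every dilution cut-off;
* hydrophobic tethers between carbon/sulfur atoms of sequence-distant
  residues within van der Waals contact plus a slop allowance.

Bar multiplicities: locked covalent 6, rotatable covalent 5, polar 5,
tether 2 under the ambient regime or 1 under the cold regime (the weakened
hydrophobic effect at low temperature).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
from scipy.spatial import cKDTree

from ._chem import (
    ACIDIC_GROUP_ATOMS,
    BASIC_GROUP_ATOMS,
    SIDECHAIN_ACCEPTORS,
    STANDARD_RESIDUES,
    TETHER_ELEMENTS,
    VDW_RADII,
    residue_bond_template,
)
from .structure_io import RegionSelection, Residue, Structure, donor_hydrogens

Regime = Literal["ambient", "cold"]

KIND_COVALENT_LOCKED = "covalent_locked"
KIND_COVALENT_ROTATABLE = "covalent_rotatable"
KIND_POLAR = "polar"
KIND_TETHER = "tether"

_BARS_FIXED = {
    KIND_COVALENT_LOCKED: 6,
    KIND_COVALENT_ROTATABLE: 5,
    KIND_POLAR: 5,
}


class ChainBreakWarning(UserWarning):
    """Consecutive residues too far apart for a peptide bond."""


@dataclass
class Constraint:
    """One pairwise constraint between two atoms (indices into the atom list).

    ``energy`` is the effective interaction strength in kcal/mol (<= 0,
    polar constraints only; covalent bonds and tethers carry 0).  ``bars``
    is assigned when the network is assembled for a temperature regime.
    """

    kind: str
    atom_i: int
    atom_j: int
    distance: float
    energy: float = 0.0
    bars: int = 0
    is_salt_bridge: bool = False

    def __post_init__(self) -> None:
        if self.atom_i == self.atom_j:
            raise ValueError("constraint endpoints must differ")
        if self.atom_i > self.atom_j:
            self.atom_i, self.atom_j = self.atom_j, self.atom_i

    def pair(self) -> tuple[int, int]:
        return (self.atom_i, self.atom_j)


@dataclass
class InteractionParams:
    """Geometric gates and energy constants for constraint detection.

    The hydrogen-bond well follows the Mayo functional form with well depth
    ``mayo_well_depth`` (kcal/mol) at donor-acceptor equilibrium distance
    ``mayo_equilibrium`` (A).  Salt bridges are assigned
    ``salt_bridge_energy`` outright.
    """

    hb_donor_acceptor_max: float = 3.6
    hb_hydrogen_acceptor_max: float = 2.5
    hb_dha_min_angle: float = 110.0
    mayo_well_depth: float = 8.0
    mayo_equilibrium: float = 2.8
    salt_bridge_energy: float = -10.0
    energy_floor: float = -10.0
    tether_vdw_slop: float = 0.25
    esbri_salt_bridge_cutoff: float = 4.0
    vdw_radii: dict[str, float] = field(default_factory=lambda: dict(VDW_RADII))

    def __post_init__(self) -> None:
        for name in ("hb_donor_acceptor_max", "hb_hydrogen_acceptor_max",
                     "mayo_equilibrium", "esbri_salt_bridge_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mayo_well_depth <= 0:
            raise ValueError("mayo_well_depth must be positive")


@dataclass
class ConstraintNetwork:
    """All constraints retained at one energy cut-off and regime."""

    structure: Structure
    constraints: list[Constraint]
    cutoff: float
    regime: Regime

    def by_kind(self, kind: str) -> list[Constraint]:
        return [c for c in self.constraints if c.kind == kind]


def tether_bars(regime: Regime) -> int:
    if regime == "ambient":
        return 2
    if regime == "cold":
        return 1
    raise ValueError(f"unknown regime {regime!r}")


# --------------------------------------------------------------------------
# covalent bonds
# --------------------------------------------------------------------------

_PEPTIDE_MAX = 2.0
_DISULFIDE_MAX = 2.3
_H_BOND_MAX = 1.6


def detect_covalent(s: Structure) -> list[Constraint]:
    """Covalent bonds: residue templates, peptide links, disulfides, X-H.

    Peptide bonds, double/partial-double bonds (C=O, carboxylate, amide,
    guanidinium, aromatic rings) and terminal pendants (hydrogens, OXT) are
    torsionally locked; all other single bonds are rotatable.  Consecutive
    residues whose C-N distance exceeds 2 A are treated as a chain break.
    """
    out: list[Constraint] = []
    seen: set[tuple[int, int]] = set()

    def add(i: int, j: int, locked: bool) -> None:
        key = (i, j) if i < j else (j, i)
        if key in seen:
            return
        seen.add(key)
        d = float(np.linalg.norm(s.atoms[i].position - s.atoms[j].position))
        kind = KIND_COVALENT_LOCKED if locked else KIND_COVALENT_ROTATABLE
        out.append(Constraint(kind, i, j, d))

    residues = s.residues()
    prev_by_chain: dict[str, Residue] = {}
    sg_atoms: list[int] = []
    for res in residues:
        atoms = {s.atoms[i].name: i for i in res.atom_indices}
        if res.name in STANDARD_RESIDUES:
            for a, b, locked in residue_bond_template(res.name):
                if a in atoms and b in atoms:
                    add(atoms[a], atoms[b], locked)
            if res.name == "CYS" and "SG" in atoms:
                sg_atoms.append(atoms["SG"])
            # hydrogens -> nearest heavy atom, locked pendants
            for i in res.atom_indices:
                if s.atoms[i].element != "H":
                    continue
                best, best_d = None, _H_BOND_MAX
                for j in res.atom_indices:
                    if s.atoms[j].element == "H":
                        continue
                    d = float(np.linalg.norm(
                        s.atoms[j].position - s.atoms[i].position))
                    if d < best_d:
                        best, best_d = j, d
                if best is not None:
                    add(i, best, True)
            # peptide link to the previous residue
            prev = prev_by_chain.get(res.chain_id)
            if prev is not None and "N" in atoms:
                prev_atoms = {s.atoms[i].name: i for i in prev.atom_indices}
                if "C" in prev_atoms:
                    d = float(np.linalg.norm(
                        s.atoms[prev_atoms["C"]].position
                        - s.atoms[atoms["N"]].position))
                    if d <= _PEPTIDE_MAX:
                        add(prev_atoms["C"], atoms["N"], True)
                    else:
                        warnings.warn(
                            f"chain break between {prev.chain_id}{prev.number} "
                            f"and {res.chain_id}{res.number} (C-N {d:.2f} A)",
                            ChainBreakWarning,
                        )
            prev_by_chain[res.chain_id] = res
        else:
            prev_by_chain.pop(res.chain_id, None)

    # disulfides
    for a in range(len(sg_atoms)):
        for b in range(a + 1, len(sg_atoms)):
            i, j = sg_atoms[a], sg_atoms[b]
            d = float(np.linalg.norm(s.atoms[i].position - s.atoms[j].position))
            if d < _DISULFIDE_MAX:
                add(i, j, False)
    return out


def covalent_adjacency(s: Structure,
                       covalent: list[Constraint] | None = None
                       ) -> list[list[int]]:
    if covalent is None:
        covalent = detect_covalent(s)
    adj: list[list[int]] = [[] for _ in s.atoms]
    for c in covalent:
        adj[c.atom_i].append(c.atom_j)
        adj[c.atom_j].append(c.atom_i)
    return adj


def _within_bonds(adj: list[list[int]], i: int, j: int, max_bonds: int) -> bool:
    """True if j is within ``max_bonds`` covalent bonds of i."""
    frontier = {i}
    visited = {i}
    for _ in range(max_bonds):
        nxt = set()
        for w in frontier:
            for x in adj[w]:
                if x not in visited:
                    visited.add(x)
                    nxt.add(x)
        if j in nxt:
            return True
        frontier = nxt
    return False


# --------------------------------------------------------------------------
# hydrophobic tethers
# --------------------------------------------------------------------------

def detect_tethers(s: Structure, params: InteractionParams | None = None
                   ) -> list[Constraint]:
    """Hydrophobic tethers between apolar (C/S) atoms.

    Eligible pairs come from residues more than two apart in sequence (or
    from different chains) with an inter-atom distance below the sum of van
    der Waals radii plus a slop allowance; only the single shortest contact
    per residue pair is kept.
    """
    p = params or InteractionParams()
    idx = [i for i, a in enumerate(s.atoms) if a.element in TETHER_ELEMENTS
           and not a.is_hetero]
    if not idx:
        return []
    coords = np.array([s.atoms[i].position for i in idx])
    radii = np.array([p.vdw_radii[s.atoms[i].element] for i in idx])
    rmax = 2 * radii.max() + p.tether_vdw_slop
    tree = cKDTree(coords)
    best: dict[tuple, tuple[float, int, int]] = {}
    for a, b in sorted(tree.query_pairs(rmax)):
        i, j = idx[a], idx[b]
        ai, aj = s.atoms[i], s.atoms[j]
        if ai.chain_id == aj.chain_id and \
                abs(ai.residue_number - aj.residue_number) <= 2:
            continue
        d = float(np.linalg.norm(ai.position - aj.position))
        if d >= radii[a] + radii[b] + p.tether_vdw_slop:
            continue
        key = (ai.residue_key(), aj.residue_key())
        if key[0] > key[1]:
            key = (key[1], key[0])
        if key not in best or d < best[key][0]:
            best[key] = (d, i, j)
    return [Constraint(KIND_TETHER, i, j, d)
            for d, i, j in sorted(best.values(), key=lambda t: (t[1], t[2]))]


# --------------------------------------------------------------------------
# polar interactions
# --------------------------------------------------------------------------

def mayo_energy(d: float, theta_dha: float, params: InteractionParams) -> float:
    """Mayo-form hydrogen-bond energy (kcal/mol) for donor-acceptor distance
    ``d`` (A) and D-H...A angle ``theta_dha`` (degrees), clamped to
    [energy_floor, 0]."""
    x = params.mayo_equilibrium / d
    radial = params.mayo_well_depth * (5.0 * x**12 - 6.0 * x**10)
    angular = np.cos(np.radians(theta_dha)) ** 2
    return float(np.clip(radial * angular, params.energy_floor, 0.0))


def _charged_atom_map(s: Structure) -> tuple[dict[int, tuple], dict[int, tuple]]:
    """Atom index -> residue key for acidic / basic charged-group atoms."""
    acidic: dict[int, tuple] = {}
    basic: dict[int, tuple] = {}
    for res in s.residues():
        for i in res.atom_indices:
            name = s.atoms[i].name
            if name in ACIDIC_GROUP_ATOMS.get(res.name, ()):
                acidic[i] = res.key()
            if name in BASIC_GROUP_ATOMS.get(res.name, ()):
                basic[i] = res.key()
    return acidic, basic


def _salt_bridge_pairs(s: Structure, cutoff: float):
    """Yield (d, oxygen_index, nitrogen_index, acid_key, base_key) for all
    charged-group atom pairs within ``cutoff``."""
    acidic, basic = _charged_atom_map(s)
    if not acidic or not basic:
        return
    a_idx = sorted(acidic)
    b_idx = sorted(basic)
    a_tree = cKDTree(np.array([s.atoms[i].position for i in a_idx]))
    b_tree = cKDTree(np.array([s.atoms[i].position for i in b_idx]))
    for ai, bs in enumerate(a_tree.query_ball_tree(b_tree, cutoff)):
        i = a_idx[ai]
        for bj in bs:
            j = b_idx[bj]
            d = float(np.linalg.norm(s.atoms[i].position - s.atoms[j].position))
            if d < cutoff:
                yield d, i, j, acidic[i], basic[j]


def detect_polar(s: Structure, params: InteractionParams | None = None
                 ) -> list[Constraint]:
    """Hydrogen bonds and salt bridges with effective energies.

    Salt bridges (charged-group nitrogen vs carboxylate oxygen within the
    ESBRI cut-off) are detected first, one per residue pair, at the pinned
    salt-bridge energy; they do not require hydrogens.  Remaining
    donor-hydrogen-acceptor triples pass three geometric gates (donor-
    acceptor and hydrogen-acceptor distances, D-H...A angle) and are scored
    with the Mayo well.  A residue pair already linked by a salt bridge is
    not double-counted through its charged-group atoms.
    """
    p = params or InteractionParams()
    out: list[Constraint] = []

    # --- salt bridges ---
    best_sb: dict[tuple, tuple[float, int, int]] = {}
    sb_residue_pairs: set[tuple] = set()
    for d, i, j, akey, bkey in _salt_bridge_pairs(s, p.esbri_salt_bridge_cutoff) or []:
        rkey = (akey, bkey) if akey < bkey else (bkey, akey)
        if rkey not in best_sb or d < best_sb[rkey][0]:
            best_sb[rkey] = (d, i, j)
    for rkey, (d, i, j) in sorted(best_sb.items()):
        out.append(Constraint(KIND_POLAR, i, j, d,
                              energy=p.salt_bridge_energy, is_salt_bridge=True))
        sb_residue_pairs.add(rkey)

    # --- hydrogen bonds ---
    adj = covalent_adjacency(s)
    donors = donor_hydrogens(s)
    acidic, basic = _charged_atom_map(s)
    acceptors = []
    for res in s.residues():
        sc = SIDECHAIN_ACCEPTORS.get(res.name, set())
        for i in res.atom_indices:
            name = s.atoms[i].name
            if name in ("O", "OXT") or name in sc:
                acceptors.append(i)
    if acceptors and donors:
        acc_tree = cKDTree(np.array([s.atoms[i].position for i in acceptors]))
        best_hb: dict[tuple[int, int], Constraint] = {}
        for d_idx, hs in sorted(donors.items()):
            d_atom = s.atoms[d_idx]
            for h_idx in hs:
                h_atom = s.atoms[h_idx]
                for ak in acc_tree.query_ball_point(
                        h_atom.position, p.hb_hydrogen_acceptor_max):
                    a_idx2 = acceptors[ak]
                    a_atom = s.atoms[a_idx2]
                    if a_idx2 == d_idx:
                        continue
                    if a_atom.residue_key() == d_atom.residue_key():
                        continue
                    if _within_bonds(adj, d_idx, a_idx2, 3):
                        continue
                    daa = float(np.linalg.norm(
                        a_atom.position - d_atom.position))
                    if daa >= p.hb_donor_acceptor_max:
                        continue
                    dha = _angle(d_atom.position, h_atom.position,
                                 a_atom.position)
                    if dha <= p.hb_dha_min_angle:
                        continue
                    # salt-bridge classification wins over the H-bond route
                    if d_idx in basic and a_idx2 in acidic:
                        rkey = tuple(sorted((basic[d_idx], acidic[a_idx2])))
                        if rkey in sb_residue_pairs:
                            continue
                    energy = mayo_energy(daa, dha, p)
                    key = (min(d_idx, a_idx2), max(d_idx, a_idx2))
                    c = Constraint(KIND_POLAR, d_idx, a_idx2, daa, energy=energy)
                    if key not in best_hb or energy < best_hb[key].energy:
                        best_hb[key] = c
        out.extend(best_hb[k] for k in sorted(best_hb))
    return out


def _angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    u = a - b
    v = c - b
    cosv = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosv, -1.0, 1.0))))


def count_salt_bridges(s: Structure,
                       selection: RegionSelection | str | None = None,
                       cutoff: float = 4.0) -> int:
    """Count unique oppositely charged residue pairs (Asp/Glu carboxylate O
    vs Lys/Arg/His side-chain N) with any inter-atom distance below
    ``cutoff`` (A).  ``selection`` restricts both residues to a chain id or
    region; hydrogens are not required."""
    def in_sel(key: tuple) -> bool:
        if selection is None:
            return True
        if isinstance(selection, str):
            return key[0] == selection
        return selection.contains(key[0], key[1])

    pairs = set()
    for d, i, j, akey, bkey in _salt_bridge_pairs(s, cutoff) or []:
        if in_sel(akey) and in_sel(bkey):
            pairs.add((akey, bkey))
    return len(pairs)


# --------------------------------------------------------------------------
# network assembly
# --------------------------------------------------------------------------

def build_network(s: Structure, cutoff: float = -1.0,
                  regime: Regime = "ambient",
                  params: InteractionParams | None = None,
                  covalent: list[Constraint] | None = None,
                  tethers: list[Constraint] | None = None,
                  polar: list[Constraint] | None = None) -> ConstraintNetwork:
    """Assemble the constraint network at one energy cut-off and regime.

    Retains all covalent bonds and tethers plus polar constraints with
    energy <= ``cutoff``; assigns bar multiplicities (locked 6, rotatable 5,
    polar 5, tether 2 ambient / 1 cold).  Pre-detected constraint lists may
    be passed to avoid re-detection across a dilution series.
    """
    if cutoff > 0:
        raise ValueError("cutoff must be <= 0 kcal/mol")
    p = params or InteractionParams()
    covalent = detect_covalent(s) if covalent is None else covalent
    tethers = detect_tethers(s, p) if tethers is None else tethers
    polar = detect_polar(s, p) if polar is None else polar

    tb = tether_bars(regime)
    constraints: list[Constraint] = []
    for c in covalent:
        constraints.append(Constraint(c.kind, c.atom_i, c.atom_j, c.distance,
                                      bars=_BARS_FIXED[c.kind]))
    for c in tethers:
        constraints.append(Constraint(c.kind, c.atom_i, c.atom_j, c.distance,
                                      bars=tb))
    for c in polar:
        if c.energy <= cutoff:
            constraints.append(Constraint(c.kind, c.atom_i, c.atom_j,
                                          c.distance, energy=c.energy,
                                          bars=_BARS_FIXED[KIND_POLAR],
                                          is_salt_bridge=c.is_salt_bridge))
    return ConstraintNetwork(structure=s, constraints=constraints,
                             cutoff=cutoff, regime=regime)


# --------------------------------------------------------------------------
# tabular dump
# --------------------------------------------------------------------------

def write_constraints_tsv(s: Structure, constraints: list[Constraint],
                          path: str | Path) -> None:
    """Dump constraints as TSV for inspection and reproducibility."""
    with open(path, "w") as fh:
        fh.write("kind\tchain_i\tres_i\tatom_i\tchain_j\tres_j\tatom_j\t"
                 "distance\tenergy\tbars\tsalt_bridge\n")
        for c in constraints:
            ai, aj = s.atoms[c.atom_i], s.atoms[c.atom_j]
            fh.write(f"{c.kind}\t{ai.chain_id}\t{ai.residue_number}\t{ai.name}\t"
                     f"{aj.chain_id}\t{aj.residue_number}\t{aj.name}\t"
                     f"{c.distance:.3f}\t{c.energy:.3f}\t{c.bars}\t"
                     f"{int(c.is_salt_bridge)}\n")


def read_constraints_tsv(s: Structure, path: str | Path) -> list[Constraint]:
    """Read back a constraint dump written by :func:`write_constraints_tsv`."""
    index = s.atom_index()
    out: list[Constraint] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            rec = dict(zip(header, line.rstrip("\n").split("\t")))
            i = index[(rec["chain_i"], int(rec["res_i"]), "", rec["atom_i"])]
            j = index[(rec["chain_j"], int(rec["res_j"]), "", rec["atom_j"])]
            out.append(Constraint(rec["kind"], i, j, float(rec["distance"]),
                                  energy=float(rec["energy"]),
                                  bars=int(rec["bars"]),
                                  is_salt_bridge=bool(int(rec["salt_bridge"]))))
    return out
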