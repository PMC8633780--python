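"""Reading, filtering and writing macromolecular structures.

The in-memory model is deliberately small: a :class:`Structure` is an ordered
list of :class:`AtomRecord` plus per-chain SEQRES sequences.  PDB and mmCIF
parsing/writing is delegated to gemmi; everything downstream (constraint
detection, rigidity, simulation) operates on these containers.

Residue numbering follows the author (PDB) numbering throughout, and region
selections are inclusive 1-based ranges in that numbering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal

import gemmi
import numpy as np

from ._chem import (
    SIDECHAIN_DONOR_H,
    STANDARD_RESIDUES,
    WATER_NAMES,
    element_of,
)
from ._geometry import place_atom, unit

AltlocPolicy = Literal["highest_occupancy", "first_listed", "keep_all"]


class StructureError(Exception):
    """Base error for structure handling."""


class ParseError(StructureError):
    """Unreadable or malformed coordinate file."""


class EmptyStructureError(StructureError):
    """File parsed but contains no atoms."""


class HydrogenPlacementWarning(UserWarning):
    """A polar hydrogen could not be placed (missing heavy-atom anchor)."""


@dataclass
class AtomRecord:
    """One atom of a structure (PDB semantics, author numbering)."""

    serial: int
    name: str
    element: str
    alt_loc: str
    residue_name: str
    chain_id: str
    residue_number: int
    insertion_code: str
    position: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0
    is_hetero: bool = False

    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.insertion_code)


@dataclass
class Residue:
    """View over the atoms of one residue (in file order)."""

    chain_id: str
    number: int
    insertion_code: str
    name: str
    atom_indices: list[int]

    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.number, self.insertion_code)


@dataclass
class RegionSelection:
    """Inclusive residue range on one chain, author numbering."""

    chain_id: str
    first_residue: int
    last_residue: int

    def __post_init__(self) -> None:
        if self.first_residue > self.last_residue:
            raise ValueError("first_residue must be <= last_residue")

    def contains(self, chain_id: str, residue_number: int) -> bool:
        return (
            chain_id == self.chain_id
            and self.first_residue <= residue_number <= self.last_residue
        )


@dataclass
class Structure:
    """Ordered atom list with residue/chain indexing and SEQRES sequences."""

    title: str = ""
    atoms: list[AtomRecord] = field(default_factory=list)
    seqres: dict[str, list[str]] = field(default_factory=dict)

    # -- indexing -------------------------------------------------------------
    def residues(self) -> list[Residue]:
        out: list[Residue] = []
        current: Residue | None = None
        for i, a in enumerate(self.atoms):
            key = a.residue_key()
            if current is None or current.key() != key or current.name != a.residue_name:
                current = Residue(a.chain_id, a.residue_number, a.insertion_code,
                                  a.residue_name, [])
                out.append(current)
            current.atom_indices.append(i)
        return out

    def chain_ids(self) -> list[str]:
        seen: list[str] = []
        for a in self.atoms:
            if a.chain_id not in seen:
                seen.append(a.chain_id)
        return seen

    def chains(self) -> dict[str, list[Residue]]:
        index: dict[str, list[Residue]] = {}
        for res in self.residues():
            index.setdefault(res.chain_id, []).append(res)
        return index

    def sequence(self, chain_id: str, source: str = "auto") -> list[str]:
        """Chain sequence as 3-letter codes; SEQRES when available."""
        if source in ("auto", "seqres") and chain_id in self.seqres:
            return list(self.seqres[chain_id])
        if source == "seqres":
            raise KeyError(f"no SEQRES for chain {chain_id!r}")
        return [r.name for r in self.chains().get(chain_id, [])
                if r.name in STANDARD_RESIDUES]

    # -- coordinates ----------------------------------------------------------
    def coord_array(self) -> np.ndarray:
        return np.array([a.position for a in self.atoms], dtype=float)

    def set_coords(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        for a, xyz in zip(self.atoms, coords):
            a.position = xyz.copy()

    def copy(self) -> "Structure":
        return Structure(
            title=self.title,
            atoms=[replace(a, position=a.position.copy()) for a in self.atoms],
            seqres={k: list(v) for k, v in self.seqres.items()},
        )

    # -- selections -----------------------------------------------------------
    def select(self, region: RegionSelection, atom_names: Iterable[str] | None = None
               ) -> list[int]:
        names = set(atom_names) if atom_names is not None else None
        return [
            i for i, a in enumerate(self.atoms)
            if region.contains(a.chain_id, a.residue_number)
            and (names is None or a.name in names)
        ]

    def atom_index(self) -> dict[tuple[str, int, str, str], int]:
        """(chain, resnum, icode, atom name) -> atom position in the list."""
        return {
            (a.chain_id, a.residue_number, a.insertion_code, a.name): i
            for i, a in enumerate(self.atoms)
        }


# --------------------------------------------------------------------------
# reading
# --------------------------------------------------------------------------

def _atom_from_gemmi(serial: int, chain: str, res: gemmi.Residue, atom: gemmi.Atom,
                     hetero: bool) -> AtomRecord:
    el = atom.element.name if atom.element and atom.element.name != "X" else \
        element_of(atom.name)
    return AtomRecord(
        serial=serial,
        name=atom.name,
        element=el,
        alt_loc=atom.altloc if atom.altloc else "",
        residue_name=res.name,
        chain_id=chain,
        residue_number=res.seqid.num,
        insertion_code=res.seqid.icode.strip(),
        position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
        occupancy=float(atom.occ),
        b_factor=float(atom.b_iso),
        is_hetero=hetero,
    )


def _apply_altloc(group: list[AtomRecord], policy: AltlocPolicy) -> list[AtomRecord]:
    if len(group) == 1 or policy == "keep_all":
        return group
    if policy == "first_listed":
        return [group[0]]
    if policy == "highest_occupancy":
        best = max(group, key=lambda a: (a.occupancy, -ord(a.alt_loc or "~")))
        return [best]
    raise ValueError(f"unknown altloc policy {policy!r}")


def read_structure(path: str | Path, keep_waters: bool = False,
                   altloc_policy: AltlocPolicy = "highest_occupancy") -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure` (first model).

    Waters are dropped unless ``keep_waters``; alternate locations are
    resolved per atom group according to ``altloc_policy``.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    st.setup_entities()

    if len(st) == 0 or sum(res.__len__() for ch in st[0] for res in ch) == 0:
        raise EmptyStructureError(f"{path} contains no atoms")

    out = Structure(title=st.name or path.stem)
    model = st[0]
    serial = 0
    for chain in model:
        for res in chain:
            if res.name in WATER_NAMES and not keep_waters:
                continue
            hetero = res.het_flag == "H"
            # group atoms by name to apply the altloc policy
            groups: dict[str, list[AtomRecord]] = {}
            order: list[str] = []
            for atom in res:
                serial += 1
                rec = _atom_from_gemmi(serial, chain.name, res, atom, hetero)
                if rec.name not in groups:
                    groups[rec.name] = []
                    order.append(rec.name)
                groups[rec.name].append(rec)
            for name in order:
                out.atoms.extend(_apply_altloc(groups[name], altloc_policy))

    # renumber serials after filtering
    for i, a in enumerate(out.atoms, start=1):
        a.serial = i

    # SEQRES / entity sequences
    for chain in model:
        polymer = chain.get_polymer()
        ent = st.get_entity_of(polymer)
        if ent is not None and ent.full_sequence:
            out.seqres[chain.name] = [
                gemmi.Entity.first_mon(m) for m in ent.full_sequence
            ]
    if not out.atoms:
        raise EmptyStructureError(f"{path} contains no atoms after filtering")
    return out


def read_ensemble(path: str | Path) -> list[Structure]:
    """Read every MODEL of a multi-model PDB as a separate Structure."""
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    frames: list[Structure] = []
    for model in st:
        frame = Structure(title=st.name or path.stem)
        serial = 0
        for chain in model:
            for res in chain:
                hetero = res.het_flag == "H"
                for atom in res:
                    serial += 1
                    frame.atoms.append(
                        _atom_from_gemmi(serial, chain.name, res, atom, hetero))
        frames.append(frame)
    if not frames:
        raise EmptyStructureError(f"{path} contains no models")
    return frames


# --------------------------------------------------------------------------
# writing
# --------------------------------------------------------------------------

def _to_gemmi(s: Structure) -> gemmi.Model:
    model = gemmi.Model(1)
    for a in s.atoms:
        if len(model) == 0 or model[-1].name != a.chain_id:
            model.add_chain(gemmi.Chain(a.chain_id))
        chain = model[-1]
        need_new = (
            len(chain) == 0
            or chain[-1].seqid.num != a.residue_number
            or chain[-1].seqid.icode.strip() != a.insertion_code
            or chain[-1].name != a.residue_name
        )
        if need_new:
            res = gemmi.Residue()
            res.name = a.residue_name
            res.seqid = gemmi.SeqId(a.residue_number, a.insertion_code or " ")
            res.het_flag = "H" if a.is_hetero else "A"
            chain.add_residue(res)
        res = chain[-1]
        atom = gemmi.Atom()
        atom.name = a.name
        atom.element = gemmi.Element(a.element)
        atom.altloc = a.alt_loc or "\x00"
        atom.pos = gemmi.Position(*a.position)
        atom.occ = a.occupancy
        atom.b_iso = a.b_factor
        res.add_atom(atom)
    return model


def write_structure(s: Structure, path: str | Path) -> None:
    """Write a Structure as a PDB file."""
    st = gemmi.Structure()
    st.name = s.title
    st.add_model(_to_gemmi(s))
    st.setup_entities()
    _apply_seqres(st, s)
    try:
        st.write_pdb(str(path))
    except (RuntimeError, OSError) as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc


def _apply_seqres(st: gemmi.Structure, s: Structure) -> None:
    if not s.seqres:
        return
    for chain in st[0]:
        if chain.name not in s.seqres:
            continue
        ent = st.get_entity_of(chain.get_polymer())
        if ent is not None:
            ent.full_sequence = list(s.seqres[chain.name])


def write_ensemble(frames: list[Structure], path: str | Path) -> None:
    """Write coordinate frames as a multi-model (MODEL/ENDMDL) PDB file."""
    if not frames:
        raise ValueError("empty frame list")
    st = gemmi.Structure()
    st.name = frames[0].title
    for i, frame in enumerate(frames, start=1):
        model = _to_gemmi(frame)
        model.num = i
        st.add_model(model)
    st.setup_entities()
    try:
        st.write_pdb(str(path))
    except (RuntimeError, OSError) as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc


# --------------------------------------------------------------------------
# polar hydrogens
# --------------------------------------------------------------------------

_H_BOND_LENGTH = {"N": 1.01, "O": 0.96, "S": 1.34}

# side-chain H recipes: heavy -> list of (h_name, kind, anchors...)
# kind "bisector": H opposite the bisector of two heavy neighbours (planar N-H)
# kind "torsion":  NeRF placement (a, b, parent, angle, torsion)


def _sidechain_h_recipes(resname: str) -> list[tuple]:
    r = resname
    recipes: list[tuple] = []
    if r == "SER":
        recipes.append(("HG", "torsion", "CA", "CB", "OG", 109.5, 180.0))
    elif r == "THR":
        recipes.append(("HG1", "torsion", "CA", "CB", "OG1", 109.5, 180.0))
    elif r == "TYR":
        recipes.append(("HH", "torsion", "CE1", "CZ", "OH", 109.5, 180.0))
    elif r == "CYS":
        recipes.append(("HG", "torsion", "CA", "CB", "SG", 96.0, 180.0))
    elif r == "LYS":
        recipes.extend([
            ("HZ1", "torsion", "CD", "CE", "NZ", 109.5, 180.0),
            ("HZ2", "torsion", "CD", "CE", "NZ", 109.5, 60.0),
            ("HZ3", "torsion", "CD", "CE", "NZ", 109.5, -60.0),
        ])
    elif r == "ARG":
        recipes.extend([
            ("HE", "bisector", "CD", "CZ", "NE"),
            ("HH11", "torsion", "NE", "CZ", "NH1", 120.0, 0.0),
            ("HH12", "torsion", "NE", "CZ", "NH1", 120.0, 180.0),
            ("HH21", "torsion", "NE", "CZ", "NH2", 120.0, 0.0),
            ("HH22", "torsion", "NE", "CZ", "NH2", 120.0, 180.0),
        ])
    elif r == "ASN":
        recipes.extend([
            ("HD21", "torsion", "CB", "CG", "ND2", 120.0, 0.0),
            ("HD22", "torsion", "CB", "CG", "ND2", 120.0, 180.0),
        ])
    elif r == "GLN":
        recipes.extend([
            ("HE21", "torsion", "CG", "CD", "NE2", 120.0, 0.0),
            ("HE22", "torsion", "CG", "CD", "NE2", 120.0, 180.0),
        ])
    elif r == "HIS":
        recipes.append(("HE2", "bisector", "CE1", "CD2", "NE2"))
    elif r == "TRP":
        recipes.append(("HE1", "bisector", "CD1", "CE2", "NE1"))
    return recipes


def add_polar_hydrogens(s: Structure) -> Structure:
    """Return a copy of ``s`` with polar hydrogens placed by ideal geometry.

    Backbone amide H sits in the peptide plane, 1.0 A from N, anti to the
    preceding carbonyl O.  Side-chain polar hydrogens (hydroxyl, thiol,
    ammonium, guanidinium, amide, imidazole N-epsilon, indole) follow ideal
    internal geometry.  Existing hydrogens are preserved; heavy atoms are
    never moved.  The operation is idempotent.
    """
    out = s.copy()
    residues = out.residues()
    new_atoms: list[AtomRecord] = []

    def res_atom(res: Residue, name: str) -> AtomRecord | None:
        for i in res.atom_indices:
            if out.atoms[i].name == name:
                return out.atoms[i]
        return None

    def has_h(res: Residue, name: str, placed: list[AtomRecord]) -> bool:
        return res_atom(res, name) is not None or any(a.name == name for a in placed)

    prev_by_chain: dict[str, Residue | None] = {}
    for res in residues:
        placed: list[AtomRecord] = []
        if res.name not in STANDARD_RESIDUES:
            prev_by_chain[res.chain_id] = None
            new_atoms.extend(out.atoms[i] for i in res.atom_indices)
            continue
        prev = prev_by_chain.get(res.chain_id)
        # backbone amide H (not for proline, not at the N-terminus)
        if res.name != "PRO" and not has_h(res, "H", placed):
            n = res_atom(res, "N")
            ca = res_atom(res, "CA")
            prev_c = res_atom(prev, "C") if prev is not None else None
            prev_ok = (
                prev is not None and prev_c is not None and n is not None
                and prev.chain_id == res.chain_id
                and float(np.linalg.norm(prev_c.position - n.position)) < 2.0
            )
            if prev_ok and ca is not None:
                direction = -(
                    unit(prev_c.position - n.position)
                    + unit(ca.position - n.position)
                )
                h_pos = n.position + 1.0 * unit(direction)
                placed.append(_make_h(n, "H", h_pos))
            elif prev is not None and not prev_ok and n is not None:
                warnings.warn(
                    f"cannot place amide H on {res.chain_id}{res.number}: "
                    "no preceding carbonyl within bonding distance",
                    HydrogenPlacementWarning,
                )
        # side-chain polar hydrogens
        for recipe in _sidechain_h_recipes(res.name):
            h_name, kind = recipe[0], recipe[1]
            if has_h(res, h_name, placed):
                continue
            anchors = [res_atom(res, name) for name in recipe[2:5]]
            if any(a is None for a in anchors):
                warnings.warn(
                    f"cannot place {h_name} on {res.name} {res.chain_id}"
                    f"{res.number}: missing heavy-atom anchor",
                    HydrogenPlacementWarning,
                )
                continue
            a, b, parent = anchors
            blen = _H_BOND_LENGTH[parent.element]
            if kind == "bisector":
                direction = -(
                    unit(a.position - parent.position)
                    + unit(b.position - parent.position)
                )
                pos = parent.position + blen * unit(direction)
            else:
                ang, tor = recipe[5], recipe[6]
                pos = place_atom(a.position, b.position, parent.position,
                                 blen, ang, tor)
            placed.append(_make_h(parent, h_name, pos))
        new_atoms.extend(out.atoms[i] for i in res.atom_indices)
        new_atoms.extend(placed)
        prev_by_chain[res.chain_id] = res

    out.atoms = new_atoms
    for i, a in enumerate(out.atoms, start=1):
        a.serial = i
    return out


def _make_h(parent: AtomRecord, name: str, pos: np.ndarray) -> AtomRecord:
    return AtomRecord(
        serial=0,
        name=name,
        element="H",
        alt_loc="",
        residue_name=parent.residue_name,
        chain_id=parent.chain_id,
        residue_number=parent.residue_number,
        insertion_code=parent.insertion_code,
        position=np.asarray(pos, dtype=float),
        occupancy=parent.occupancy,
        b_factor=parent.b_factor,
        is_hetero=parent.is_hetero,
    )


def donor_hydrogens(s: Structure) -> dict[int, list[int]]:
    """Map donor heavy-atom index -> indices of its attached hydrogens.

    Hydrogens are associated by residue membership and naming convention
    (backbone H to N; side-chain H per the donor tables), falling back to
    the nearest heavy atom for non-standard names.
    """
    mapping: dict[int, list[int]] = {}
    for res in s.residues():
        atoms = {s.atoms[i].name: i for i in res.atom_indices}
        name_map: dict[str, str] = {}
        if "N" in atoms:
            name_map["H"] = "N"
        for heavy, hs in SIDECHAIN_DONOR_H.get(res.name, {}).items():
            for h in hs:
                name_map[h] = heavy
        for i in res.atom_indices:
            a = s.atoms[i]
            if a.element != "H":
                continue
            heavy_name = name_map.get(a.name)
            if heavy_name is not None and heavy_name in atoms:
                mapping.setdefault(atoms[heavy_name], []).append(i)
            else:
                # nearest heavy atom in the residue
                best, best_d = None, 1.6
                for j in res.atom_indices:
                    other = s.atoms[j]
                    if other.element == "H":
                        continue
                    d = float(np.linalg.norm(other.position - a.position))
                    if d < best_d:
                        best, best_d = j, d
                if best is not None:
                    mapping.setdefault(best, []).append(i)
    return mapping
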