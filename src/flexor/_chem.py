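"""Chemical reference data for standard amino-acid residues.

Covalent bond templates (with locked / rotatable classification), van der
Waals radii, hydrogen-bond donor / acceptor tables, charged-group membership
and ideal side-chain internal coordinates used by the fixture builders.

"Locked" bonds are those with no free torsion: double / partially double
bonds (peptide C-N, carbonyl, carboxylate, amide, guanidinium) and aromatic
ring bonds.  Everything else is a rotatable single bond.  Terminal pendant
bonds (X-H, C-OXT) are locked to their parent.
"""

from __future__ import annotations

# --- van der Waals radii (A), element keyed ---------------------------------
VDW_RADII = {
    "H": 1.00,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
}

TETHER_ELEMENTS = frozenset({"C", "S"})

WATER_NAMES = frozenset({"HOH", "WAT", "DOD", "H2O"})

STANDARD_RESIDUES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

# --- covalent bond templates -------------------------------------------------
# (atom_i, atom_j, locked)
_BACKBONE = [("N", "CA", False), ("CA", "C", False), ("C", "O", True)]

_SIDE_CHAIN_BONDS = {
    "ALA": [("CA", "CB", False)],
    "ARG": [("CA", "CB", False), ("CB", "CG", False), ("CG", "CD", False),
            ("CD", "NE", False), ("NE", "CZ", True), ("CZ", "NH1", True),
            ("CZ", "NH2", True)],
    "ASN": [("CA", "CB", False), ("CB", "CG", False), ("CG", "OD1", True),
            ("CG", "ND2", True)],
    "ASP": [("CA", "CB", False), ("CB", "CG", False), ("CG", "OD1", True),
            ("CG", "OD2", True)],
    "CYS": [("CA", "CB", False), ("CB", "SG", False)],
    "GLN": [("CA", "CB", False), ("CB", "CG", False), ("CG", "CD", False),
            ("CD", "OE1", True), ("CD", "NE2", True)],
    "GLU": [("CA", "CB", False), ("CB", "CG", False), ("CG", "CD", False),
            ("CD", "OE1", True), ("CD", "OE2", True)],
    "GLY": [],
    "HIS": [("CA", "CB", False), ("CB", "CG", False), ("CG", "ND1", True),
            ("ND1", "CE1", True), ("CE1", "NE2", True), ("NE2", "CD2", True),
            ("CD2", "CG", True)],
    "ILE": [("CA", "CB", False), ("CB", "CG1", False), ("CB", "CG2", False),
            ("CG1", "CD1", False)],
    "LEU": [("CA", "CB", False), ("CB", "CG", False), ("CG", "CD1", False),
            ("CG", "CD2", False)],
    "LYS": [("CA", "CB", False), ("CB", "CG", False), ("CG", "CD", False),
            ("CD", "CE", False), ("CE", "NZ", False)],
    "MET": [("CA", "CB", False), ("CB", "CG", False), ("CG", "SD", False),
            ("SD", "CE", False)],
    "PHE": [("CA", "CB", False), ("CB", "CG", False), ("CG", "CD1", True),
            ("CD1", "CE1", True), ("CE1", "CZ", True), ("CZ", "CE2", True),
            ("CE2", "CD2", True), ("CD2", "CG", True)],
    "PRO": [("CA", "CB", False), ("CB", "CG", False), ("CG", "CD", False),
            ("CD", "N", False)],
    "SER": [("CA", "CB", False), ("CB", "OG", False)],
    "THR": [("CA", "CB", False), ("CB", "OG1", False), ("CB", "CG2", False)],
    "TRP": [("CA", "CB", False), ("CB", "CG", False), ("CG", "CD1", True),
            ("CD1", "NE1", True), ("NE1", "CE2", True), ("CE2", "CD2", True),
            ("CD2", "CG", True), ("CD2", "CE3", True), ("CE3", "CZ3", True),
            ("CZ3", "CH2", True), ("CH2", "CZ2", True), ("CZ2", "CE2", True)],
    "TYR": [("CA", "CB", False), ("CB", "CG", False), ("CG", "CD1", True),
            ("CD1", "CE1", True), ("CE1", "CZ", True), ("CZ", "CE2", True),
            ("CE2", "CD2", True), ("CD2", "CG", True), ("CZ", "OH", False)],
    "VAL": [("CA", "CB", False), ("CB", "CG1", False), ("CB", "CG2", False)],
}


def residue_bond_template(resname: str) -> list[tuple[str, str, bool]]:
    """Heavy-atom bonds for a standard residue (backbone + side chain + OXT)."""
    bonds = list(_BACKBONE) + _SIDE_CHAIN_BONDS.get(resname, [])
    bonds.append(("C", "OXT", True))  # only applied when OXT present
    return bonds


# --- hydrogen-bond chemistry -------------------------------------------------
# Side-chain donor heavy atoms -> names of their hydrogens.
SIDECHAIN_DONOR_H = {
    "SER": {"OG": ["HG"]},
    "THR": {"OG1": ["HG1"]},
    "TYR": {"OH": ["HH"]},
    "CYS": {"SG": ["HG"]},
    "LYS": {"NZ": ["HZ1", "HZ2", "HZ3"]},
    "ARG": {"NE": ["HE"], "NH1": ["HH11", "HH12"], "NH2": ["HH21", "HH22"]},
    "ASN": {"ND2": ["HD21", "HD22"]},
    "GLN": {"NE2": ["HE21", "HE22"]},
    "HIS": {"NE2": ["HE2"]},  # default N-epsilon tautomer
    "TRP": {"NE1": ["HE1"]},
}

# Side-chain acceptor heavy atoms per residue.
SIDECHAIN_ACCEPTORS = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
    "ASN": {"OD1"},
    "GLN": {"OE1"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "HIS": {"ND1"},  # lone pair on the unprotonated ring nitrogen
    "MET": {"SD"},
    "CYS": {"SG"},
}

# Charged side-chain groups for salt-bridge detection (ESBRI convention:
# His counts as basic).
ACIDIC_GROUP_ATOMS = {
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
}
BASIC_GROUP_ATOMS = {
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
    "HIS": ("ND1", "NE2"),
}

ACIDIC_RESIDUES = frozenset(ACIDIC_GROUP_ATOMS)
BASIC_RESIDUES = frozenset(BASIC_GROUP_ATOMS)


# --- ideal side-chain internal coordinates -----------------------------------
# atom: (ref_a, ref_b, ref_c, bond, angle, torsion-spec)
# torsion-spec is either a float (degrees) or ("chiN", offset).
SIDE_CHAIN_ICS = {
    "ALA": [],
    "SER": [("OG", "N", "CA", "CB", 1.417, 110.8, ("chi1", 0.0))],
    "CYS": [("SG", "N", "CA", "CB", 1.808, 113.8, ("chi1", 0.0))],
    "THR": [("OG1", "N", "CA", "CB", 1.433, 109.6, ("chi1", 0.0)),
            ("CG2", "N", "CA", "CB", 1.521, 110.5, ("chi1", -120.0))],
    "VAL": [("CG1", "N", "CA", "CB", 1.521, 110.5, ("chi1", 0.0)),
            ("CG2", "N", "CA", "CB", 1.521, 110.5, ("chi1", 122.0))],
    "LEU": [("CG", "N", "CA", "CB", 1.530, 116.3, ("chi1", 0.0)),
            ("CD1", "CA", "CB", "CG", 1.521, 110.7, ("chi2", 0.0)),
            ("CD2", "CA", "CB", "CG", 1.521, 110.7, ("chi2", 122.0))],
    "ILE": [("CG1", "N", "CA", "CB", 1.530, 110.4, ("chi1", 0.0)),
            ("CG2", "N", "CA", "CB", 1.521, 110.5, ("chi1", -122.0)),
            ("CD1", "CA", "CB", "CG1", 1.513, 113.8, ("chi2", 0.0))],
    "ASP": [("CG", "N", "CA", "CB", 1.516, 112.6, ("chi1", 0.0)),
            ("OD1", "CA", "CB", "CG", 1.249, 118.4, ("chi2", 0.0)),
            ("OD2", "CA", "CB", "CG", 1.249, 118.4, ("chi2", 180.0))],
    "ASN": [("CG", "N", "CA", "CB", 1.516, 112.6, ("chi1", 0.0)),
            ("OD1", "CA", "CB", "CG", 1.231, 120.8, ("chi2", 0.0)),
            ("ND2", "CA", "CB", "CG", 1.328, 116.4, ("chi2", 180.0))],
    "GLU": [("CG", "N", "CA", "CB", 1.520, 114.1, ("chi1", 0.0)),
            ("CD", "CA", "CB", "CG", 1.516, 112.6, ("chi2", 0.0)),
            ("OE1", "CB", "CG", "CD", 1.249, 118.4, ("chi3", 0.0)),
            ("OE2", "CB", "CG", "CD", 1.249, 118.4, ("chi3", 180.0))],
    "GLN": [("CG", "N", "CA", "CB", 1.520, 114.1, ("chi1", 0.0)),
            ("CD", "CA", "CB", "CG", 1.516, 112.6, ("chi2", 0.0)),
            ("OE1", "CB", "CG", "CD", 1.231, 120.8, ("chi3", 0.0)),
            ("NE2", "CB", "CG", "CD", 1.328, 116.4, ("chi3", 180.0))],
    "LYS": [("CG", "N", "CA", "CB", 1.520, 114.1, ("chi1", 0.0)),
            ("CD", "CA", "CB", "CG", 1.520, 111.3, ("chi2", 0.0)),
            ("CE", "CB", "CG", "CD", 1.520, 111.3, ("chi3", 0.0)),
            ("NZ", "CG", "CD", "CE", 1.489, 111.9, ("chi4", 0.0))],
    "ARG": [("CG", "N", "CA", "CB", 1.520, 114.1, ("chi1", 0.0)),
            ("CD", "CA", "CB", "CG", 1.520, 111.3, ("chi2", 0.0)),
            ("NE", "CB", "CG", "CD", 1.461, 112.0, ("chi3", 0.0)),
            ("CZ", "CG", "CD", "NE", 1.330, 124.6, ("chi4", 0.0)),
            ("NH1", "CD", "NE", "CZ", 1.326, 120.0, 0.0),
            ("NH2", "CD", "NE", "CZ", 1.326, 120.0, 180.0)],
    "MET": [("CG", "N", "CA", "CB", 1.520, 114.1, ("chi1", 0.0)),
            ("SD", "CA", "CB", "CG", 1.803, 112.7, ("chi2", 0.0)),
            ("CE", "CB", "CG", "SD", 1.791, 100.9, ("chi3", 0.0))],
    "PHE": [("CG", "N", "CA", "CB", 1.502, 113.8, ("chi1", 0.0)),
            ("CD1", "CA", "CB", "CG", 1.391, 120.8, ("chi2", 0.0)),
            ("CD2", "CA", "CB", "CG", 1.391, 120.8, ("chi2", 180.0)),
            ("CE1", "CB", "CG", "CD1", 1.391, 120.8, 180.0),
            ("CE2", "CB", "CG", "CD2", 1.391, 120.8, 180.0),
            ("CZ", "CG", "CD1", "CE1", 1.391, 120.0, 0.0)],
    "TYR": [("CG", "N", "CA", "CB", 1.502, 113.8, ("chi1", 0.0)),
            ("CD1", "CA", "CB", "CG", 1.391, 120.8, ("chi2", 0.0)),
            ("CD2", "CA", "CB", "CG", 1.391, 120.8, ("chi2", 180.0)),
            ("CE1", "CB", "CG", "CD1", 1.391, 120.8, 180.0),
            ("CE2", "CB", "CG", "CD2", 1.391, 120.8, 180.0),
            ("CZ", "CG", "CD1", "CE1", 1.391, 120.0, 0.0),
            ("OH", "CD1", "CE1", "CZ", 1.377, 119.9, 180.0)],
    "HIS": [("CG", "N", "CA", "CB", 1.502, 113.8, ("chi1", 0.0)),
            ("ND1", "CA", "CB", "CG", 1.380, 122.7, ("chi2", 0.0)),
            ("CD2", "CA", "CB", "CG", 1.360, 131.2, ("chi2", 180.0)),
            ("CE1", "CB", "CG", "ND1", 1.324, 109.2, 180.0),
            ("NE2", "CG", "ND1", "CE1", 1.321, 108.2, 0.0)],
    "TRP": [("CG", "N", "CA", "CB", 1.499, 113.6, ("chi1", 0.0)),
            ("CD1", "CA", "CB", "CG", 1.365, 126.9, ("chi2", 0.0)),
            ("CD2", "CA", "CB", "CG", 1.433, 126.7, ("chi2", 180.0)),
            ("NE1", "CB", "CG", "CD1", 1.374, 110.2, 180.0),
            ("CE2", "CB", "CG", "CD2", 1.409, 107.2, 180.0),
            ("CE3", "CG", "CD2", "CE2", 1.398, 133.9, 180.0),
            ("CZ2", "CG", "CD2", "CE2", 1.394, 122.4, 0.0),
            ("CZ3", "CD2", "CE2", "CZ2", 1.368, 117.5, 180.0),
            ("CH2", "CE2", "CZ2", "CZ3", 1.400, 117.5, 0.0)],
    "GLY": [],
    "PRO": [("CG", "N", "CA", "CB", 1.492, 104.5, ("chi1", 30.0)),
            ("CD", "CA", "CB", "CG", 1.503, 106.1, ("chi2", -35.0))],
}


def element_of(atom_name: str) -> str:
    """Best-effort element from a PDB atom name (protein atoms)."""
    name = atom_name.strip()
    if not name:
        raise ValueError("empty atom name")
    if name[0].isdigit():
        name = name.lstrip("0123456789")
    if name[0] == "H" or (len(name) > 1 and name[0].isdigit()):
        return "H"
    return name[0]
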