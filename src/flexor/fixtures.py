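"""Deterministic synthetic inputs: ideal peptides, a toy two-helix dimer,
random body-bar multigraphs and noisy coordinate ensembles.

Every generator is a pure function of its arguments (seeds are explicit),
so regenerating a fixture always yields bit-identical output.  Structures
are ordinary :class:`~flexor.structure_io.Structure` objects and can be
written to PDB so tests exercise the real I/O path.
"""

from __future__ import annotations

import numpy as np

from ._chem import ONE_TO_THREE, SIDE_CHAIN_ICS
from ._geometry import place_atom, rotation_about_axis, unit
from .pebble import BodyBarGraph
from .structure_io import AtomRecord, Structure

# ideal backbone geometry (Engh-Huber-like values)
_B_N_CA = 1.458
_B_CA_C = 1.525
_B_C_N = 1.329
_B_C_O = 1.231
_A_N_CA_C = 111.2
_A_CA_C_N = 116.2
_A_C_N_CA = 121.7
_A_CA_C_O = 120.5
_HELIX_PHI = -57.0
_HELIX_PSI = -47.0

_DEFAULT_B = 20.0


def _norm_sequence(n_residues: int, sequence) -> list[str]:
    if sequence is None:
        return ["ALA"] * n_residues
    if isinstance(sequence, str):
        seq = [ONE_TO_THREE[c] for c in sequence]
    else:
        seq = list(sequence)
    if len(seq) != n_residues:
        raise ValueError("sequence length does not match n_residues")
    return seq


def _build_peptide(sequence: list[str], phi: float, psi: float,
                   chain_id: str, chi: dict | None,
                   b_factors=None) -> Structure:
    """Backbone + side chains at fixed (phi, psi), ideal internal geometry."""
    n = len(sequence)
    N = [None] * n
    CA = [None] * n
    C = [None] * n
    N[0] = np.zeros(3)
    CA[0] = np.array([_B_N_CA, 0.0, 0.0])
    t = np.radians(180.0 - _A_N_CA_C)
    C[0] = CA[0] + _B_CA_C * np.array([np.cos(t), np.sin(t), 0.0])
    for i in range(n - 1):
        N[i + 1] = place_atom(N[i], CA[i], C[i], _B_C_N, _A_CA_C_N, psi)
        CA[i + 1] = place_atom(CA[i], C[i], N[i + 1], _B_N_CA, _A_C_N_CA, 180.0)
        C[i + 1] = place_atom(C[i], N[i + 1], CA[i + 1], _B_CA_C, _A_N_CA_C, phi)

    s = Structure(title=f"ideal peptide {chain_id}")
    serial = 0
    for i, resname in enumerate(sequence):
        pos: dict[str, np.ndarray] = {"N": N[i], "CA": CA[i], "C": C[i]}
        pos["O"] = place_atom(N[i], CA[i], C[i], _B_C_O, _A_CA_C_O, psi + 180.0)
        if resname != "GLY":
            pos["CB"] = place_atom(N[i], C[i], CA[i], 1.530, 110.5, 122.5)
        res_chi = dict(chi.get(i + 1, {})) if chi else {}
        for entry in SIDE_CHAIN_ICS.get(resname, []):
            name, ra, rb, rc, bond, ang, tor = entry
            if isinstance(tor, tuple):
                chi_name, offset = tor
                tor_val = res_chi.get(chi_name, 180.0) + offset
            else:
                tor_val = tor
            pos[name] = place_atom(pos[ra], pos[rb], pos[rc], bond, ang, tor_val)
        b = _DEFAULT_B if b_factors is None else float(b_factors[i])
        for name, xyz in pos.items():
            serial += 1
            s.atoms.append(AtomRecord(
                serial=serial, name=name, element=name[0],
                alt_loc="", residue_name=resname, chain_id=chain_id,
                residue_number=i + 1, insertion_code="",
                position=np.asarray(xyz, dtype=float),
                occupancy=1.0, b_factor=b, is_hetero=False))
    s.seqres[chain_id] = list(sequence)
    return s


def ideal_peptide(sequence, phi: float = _HELIX_PHI, psi: float = _HELIX_PSI,
                  chain_id: str = "A", chi: dict | None = None,
                  b_factors=None) -> Structure:
    """Peptide of any length at fixed backbone torsions, ideal geometry.

    ``sequence`` is a 1-letter string or list of 3-letter codes."""
    if isinstance(sequence, str):
        seq = [ONE_TO_THREE[c] for c in sequence]
    else:
        seq = list(sequence)
    if not seq:
        raise ValueError("empty sequence")
    return _build_peptide(seq, phi, psi, chain_id, chi, b_factors)


def ideal_helix(n_residues: int, sequence=None, chain_id: str = "A",
                chi: dict | None = None, b_factors=None) -> Structure:
    """Ideal alpha-helix (phi = -57, psi = -47) with standard bond geometry.

    ``sequence`` may be a 1-letter string or list of 3-letter codes
    (default poly-Ala); ``chi`` maps residue number -> {chi name: degrees}
    for side-chain torsions (default 180).  The i -> i+4 backbone
    carbonyl / amide pairs fall inside the polar-detection gates once polar
    hydrogens are added.
    """
    if n_residues < 4:
        raise ValueError("an ideal helix needs at least 4 residues")
    seq = _norm_sequence(n_residues, sequence)
    return _build_peptide(seq, _HELIX_PHI, _HELIX_PSI, chain_id, chi, b_factors)


def single_residue() -> Structure:
    """One alanine residue (5 heavy atoms), for identity-case tests."""
    s = _build_peptide(["ALA"], _HELIX_PHI, _HELIX_PSI, "A", None)
    s.title = "single alanine"
    return s


def _ca_coords(s: Structure) -> np.ndarray:
    return np.array([a.position for a in s.atoms if a.name == "CA"])


def _orient_helix(s: Structure, face_residue: int) -> Structure:
    """Rotate/translate so the helix axis is +z (N->C), centroid at origin,
    and the CB of ``face_residue`` points toward +x."""
    ca = _ca_coords(s)
    centroid = ca.mean(axis=0)
    # axis via principal component of CA coordinates, oriented N->C
    u, sv, vt = np.linalg.svd(ca - centroid)
    axis = vt[0]
    if np.dot(axis, ca[-1] - ca[0]) < 0:
        axis = -axis
    # rotation taking axis -> z
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(axis, z)
    if np.linalg.norm(v) < 1e-12:
        R1 = np.eye(3)
    else:
        ang = np.degrees(np.arccos(np.clip(np.dot(axis, z), -1, 1)))
        R1 = rotation_about_axis(v, ang)
    coords = (s.coord_array() - centroid) @ R1.T
    out = s.copy()
    out.set_coords(coords)
    # phase: CB of the face residue -> +x
    cb = next(a.position for a in out.atoms
              if a.residue_number == face_residue and a.name == "CB")
    ca_face = next(a.position for a in out.atoms
                   if a.residue_number == face_residue and a.name == "CA")
    radial = cb - ca_face
    phase = np.degrees(np.arctan2(radial[1], radial[0]))
    R2 = rotation_about_axis(z, -phase)
    out.set_coords(out.coord_array() @ R2.T)
    return out


def two_helix_dimer(seed: int = 0) -> Structure:
    """Antiparallel two-helix dimer: a miniature analogue of a dimeric
    protein interface for end-to-end tests.

    Chain A carries interface leucines and an aspartate, chain B interface
    leucines and a lysine; the helices are packed so that several
    inter-chain C...C contacts satisfy the hydrophobic-tether criterion and
    the Asp/Lys pair forms an inter-chain salt bridge.  A tiny seeded
    coordinate jitter (0.005 A) makes the seed meaningful without
    perturbing any detection criterion.
    """
    n = 18
    seq_a = ["ALA"] * n
    seq_b = ["ALA"] * n
    for i in (4, 11, 15):
        seq_a[i - 1] = "LEU"
    seq_a[8 - 1] = "ASP"
    for i in (5, 12):
        seq_a[i - 1] = "SER"
    for i in (4, 8, 15):
        seq_b[i - 1] = "LEU"
    seq_b[11 - 1] = "LYS"
    for i in (7, 14):
        seq_b[i - 1] = "SER"

    # side-chain torsions chosen so interface side chains interdigitate
    # without steric overlap: several C...C pairs inside the tether window,
    # the Asp carboxylate / Lys ammonium pair inside the salt-bridge
    # cut-off, and serine hydroxyls reaching the opposite chain so the
    # ambient network welds the two helices into one rigid cluster
    chi_a = {4: {"chi1": 80.0, "chi2": -80.0},
             5: {"chi1": 60.0},
             8: {"chi1": 160.0, "chi2": -110.0},
             11: {"chi1": -100.0, "chi2": 160.0},
             12: {"chi1": 60.0},
             15: {"chi1": 105.0, "chi2": -130.0}}
    chi_b = {4: {"chi1": 140.0, "chi2": -150.0},
             7: {"chi1": 60.0},
             8: {"chi1": -20.0, "chi2": 160.0},
             11: {"chi1": 55.0, "chi2": -90.0, "chi3": -20.0, "chi4": -80.0},
             14: {"chi1": 60.0},
             15: {"chi1": -40.0, "chi2": 140.0}}

    helix_a = _orient_helix(ideal_helix(n, seq_a, "A", chi_a), face_residue=8)
    helix_b = _orient_helix(ideal_helix(n, seq_b, "B", chi_b), face_residue=11)

    sep = 10.487  # helix-axis separation (A)
    coords_a = helix_a.coord_array() + np.array([-sep / 2, 0.0, 0.0])
    flip = rotation_about_axis(np.array([0.0, 1.0, 0.0]), 180.0)
    coords_b = helix_b.coord_array() @ flip.T + np.array([sep / 2, 0.0, 0.0])

    helix_a.set_coords(coords_a)
    helix_b.set_coords(coords_b)

    dimer = Structure(title="two-helix dimer")
    dimer.atoms = helix_a.atoms + helix_b.atoms
    for i, a in enumerate(dimer.atoms, start=1):
        a.serial = i
    dimer.seqres = {"A": seq_a, "B": seq_b}

    rng = np.random.default_rng(seed)
    jitter = rng.normal(0.0, 0.005, size=(len(dimer.atoms), 3))
    dimer.set_coords(dimer.coord_array() + jitter)
    return dimer


def random_bodybar(n_bodies: int, n_bars: int,
                   multiplicities=(1, 2, 5, 6), seed: int = 0) -> BodyBarGraph:
    """Random body-bar multigraph: uniform endpoints, multiplicities drawn
    uniformly from ``multiplicities``.  Seeded and deterministic."""
    if n_bodies < 1:
        raise ValueError("need at least one body")
    rng = np.random.default_rng(seed)
    g = BodyBarGraph(n_bodies)
    mult = list(multiplicities)
    for _ in range(n_bars):
        if n_bodies < 2:
            break
        u = int(rng.integers(n_bodies))
        v = int(rng.integers(n_bodies - 1))
        if v >= u:
            v += 1
        g.add_bars(u, v, int(mult[rng.integers(len(mult))]))
    return g


def noisy_ensemble(s: Structure, sigma: float, n_frames: int, seed: int = 0):
    """Ensemble of ``n_frames`` copies of ``s`` with independent isotropic
    Gaussian displacement (standard deviation ``sigma`` per coordinate)."""
    from .geosim import Ensemble

    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    base = s.coord_array()
    frames = [base + rng.normal(0.0, sigma, size=base.shape)
              for _ in range(n_frames)]
    return Ensemble(structure=s, frames=frames,
                    steps_completed=0, halt_reason="max_steps")
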