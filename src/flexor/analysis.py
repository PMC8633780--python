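"""Structural statistics: superposition RMSD, ensemble RMSF, B-factor
profiling with region normalization, solvent-accessible surface area and
buried interface area, and residue-composition censuses.

These are the conventional descriptive measures that accompany a rigidity /
flexibility study: RMSD via Kabsch superposition, per-residue C-alpha RMSF
about the ensemble mean, the ratio of a region's mean C-alpha B-factor to
the whole-structure mean (how mobile a lid or cap is relative to its
protein), Shrake-Rupley SASA and the half buried-surface interface area,
and simple sequence composition counts (acidic : basic ratios, prolines,
fraction charged).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

import biotite.structure as bst

from ._chem import ACIDIC_RESIDUES, STANDARD_RESIDUES, VDW_RADII
from .structure_io import RegionSelection, Structure

_BASIC_KR = frozenset({"LYS", "ARG"})
_CHARGED = frozenset({"ASP", "GLU", "LYS", "ARG"})


# --------------------------------------------------------------------------
# superposition RMSD
# --------------------------------------------------------------------------

def _as_coords(x, atom_names=("CA",), chain_id=None) -> np.ndarray:
    if isinstance(x, Structure):
        sel = [a for a in x.atoms
               if a.name in atom_names
               and (chain_id is None or a.chain_id == chain_id)]
        return np.array([a.position for a in sel])
    return np.asarray(x, dtype=float)


def paired_ca_coords(s: Structure, chain_a: str, chain_b: str
                     ) -> tuple[np.ndarray, np.ndarray]:
    """C-alpha coordinate pairs matched by residue number across two chains."""
    def ca_map(chain):
        return {a.residue_number: a.position for a in s.atoms
                if a.chain_id == chain and a.name == "CA"
                and a.residue_name in STANDARD_RESIDUES}
    ma, mb = ca_map(chain_a), ca_map(chain_b)
    common = sorted(set(ma) & set(mb))
    if not common:
        raise ValueError(f"no paired C-alpha atoms between chains "
                         f"{chain_a!r} and {chain_b!r}")
    return (np.array([ma[i] for i in common]),
            np.array([mb[i] for i in common]))


def kabsch_rmsd(a, b, atom_names=("CA",)) -> float:
    """RMSD (A) after least-squares optimal (proper-rotation) superposition.

    ``a`` and ``b`` may be coordinate arrays or Structures (in which case
    their ``atom_names`` atoms are paired in order).  Symmetric in its
    arguments and invariant to rigid transforms of either."""
    ca = _as_coords(a, atom_names)
    cb = _as_coords(b, atom_names)
    if ca.shape != cb.shape:
        raise ValueError(
            f"cannot pair coordinates: {ca.shape[0]} vs {cb.shape[0]} atoms")
    ca = ca - ca.mean(axis=0)
    cb = cb - cb.mean(axis=0)
    _, rssd = Rotation.align_vectors(ca, cb)
    return float(rssd / np.sqrt(len(ca)))


def _superpose_onto(coords: np.ndarray, ref: np.ndarray) -> np.ndarray:
    c = coords - coords.mean(axis=0)
    r = ref - ref.mean(axis=0)
    rot, _ = Rotation.align_vectors(r, c)
    return rot.apply(c) + ref.mean(axis=0)


# --------------------------------------------------------------------------
# ensemble RMSF
# --------------------------------------------------------------------------

@dataclass
class EnsembleStats:
    """Per-residue C-alpha RMSF about the ensemble mean."""

    residues: list[tuple[str, int]]   # (chain, resnum)
    rmsf: np.ndarray                  # per residue, in `unit`
    unit: str = "A"
    reference: str = "mean structure"
    alignment: str = "superposed"


def rmsf(ensemble, atom_names=("CA",), superpose: bool = True) -> EnsembleStats:
    """Residue-by-residue RMSF of C-alpha positions across an ensemble.

    Frames are superposed onto the ensemble mean (one re-iteration, the
    mean recomputed once after the first superposition), then RMSF per
    residue is the root-mean-square displacement of its C-alpha from the
    mean position.  ``ensemble`` is a geosim Ensemble or a list of
    same-topology Structures."""
    if hasattr(ensemble, "frames"):
        s = ensemble.structure
        coord_frames = [np.asarray(f) for f in ensemble.frames]
    else:
        structures = list(ensemble)
        s = structures[0]
        coord_frames = [st.coord_array() for st in structures]
    if len(coord_frames) < 2:
        raise ValueError("RMSF needs at least two frames")

    idx = [i for i, a in enumerate(s.atoms) if a.name in atom_names]
    if not idx:
        raise ValueError("no atoms selected for RMSF")
    sel = np.array([f[idx] for f in coord_frames])
    if superpose:
        mean = sel.mean(axis=0)
        for _ in range(2):  # superpose, recompute mean, superpose once more
            sel = np.array([_superpose_onto(f, mean) for f in sel])
            mean = sel.mean(axis=0)
    else:
        mean = sel.mean(axis=0)
    sq = ((sel - mean) ** 2).sum(axis=2).mean(axis=0)
    residues = [(s.atoms[i].chain_id, s.atoms[i].residue_number) for i in idx]
    return EnsembleStats(residues=residues, rmsf=np.sqrt(sq),
                         alignment="superposed" if superpose else "raw")


# --------------------------------------------------------------------------
# B-factor profiling
# --------------------------------------------------------------------------

@dataclass
class BFactorProfile:
    """C-alpha B-factor profile with a region fold-change.

    ``normalized_fold`` is the region mean divided by the whole-structure
    mean -- the conventional way to compare lid/cap mobility between
    structures with different overall B-factor scales."""

    residues: list[tuple[str, int]]
    bfactors: np.ndarray
    overall_mean: float
    region_mean: float
    normalized_fold: float


def bfactor_profile(s: Structure, region: RegionSelection) -> BFactorProfile:
    """Mean C-alpha B-factor overall and over ``region``, plus their ratio.

    The overall mean runs over every C-alpha of the whole deposited model
    (all chains); the region mean over the region's chain and residue range.
    """
    cas = [a for a in s.atoms if a.name == "CA"
           and a.residue_name in STANDARD_RESIDUES]
    if not cas:
        raise ValueError("structure has no C-alpha atoms")
    b = np.array([a.b_factor for a in cas])
    in_region = np.array([region.contains(a.chain_id, a.residue_number)
                          for a in cas])
    if not in_region.any():
        raise ValueError(f"region {region} contains no C-alpha atoms")
    overall = float(b.mean())
    region_mean = float(b[in_region].mean())
    return BFactorProfile(
        residues=[(a.chain_id, a.residue_number) for a in cas],
        bfactors=b,
        overall_mean=overall,
        region_mean=region_mean,
        normalized_fold=region_mean / overall if overall > 0 else 0.0,
    )


# --------------------------------------------------------------------------
# SASA and interface area
# --------------------------------------------------------------------------

def _to_biotite(s: Structure, indices: Sequence[int]) -> bst.AtomArray:
    arr = bst.AtomArray(len(indices))
    arr.coord = np.array([s.atoms[i].position for i in indices], dtype=np.float32)
    arr.chain_id = np.array([s.atoms[i].chain_id for i in indices], dtype="U4")
    arr.res_id = np.array([s.atoms[i].residue_number for i in indices])
    arr.res_name = np.array([s.atoms[i].residue_name for i in indices], dtype="U5")
    arr.atom_name = np.array([s.atoms[i].name for i in indices], dtype="U6")
    arr.element = np.array([s.atoms[i].element for i in indices], dtype="U2")
    arr.hetero = np.array([s.atoms[i].is_hetero for i in indices])
    return arr


def sasa(s: Structure, probe: float = 1.4, samples_per_atom: int = 960,
         subset: Sequence[int] | None = None) -> np.ndarray:
    """Per-atom Shrake-Rupley solvent-accessible surface area (A^2).

    Heavy atoms only (hydrogens are ignored and report 0); single-element
    van der Waals radii.  ``subset`` restricts the computation to those
    atom indices (the rest of the structure is removed, not just masked)."""
    indices = list(subset) if subset is not None else list(range(len(s.atoms)))
    heavy = [i for i in indices if s.atoms[i].element != "H"]
    unknown = [s.atoms[i].name for i in heavy
               if s.atoms[i].element not in VDW_RADII]
    if unknown:
        raise ValueError(f"unknown element for atoms: {', '.join(unknown)}")
    arr = _to_biotite(s, heavy)
    areas = bst.sasa(arr, probe_radius=probe, point_number=samples_per_atom,
                     vdw_radii="Single", ignore_ions=False)
    out = np.zeros(len(s.atoms))
    for i, a in zip(heavy, areas):
        out[i] = 0.0 if np.isnan(a) else float(a)
    return out[indices] if subset is not None else out


def total_sasa(s: Structure, probe: float = 1.4,
               samples_per_atom: int = 960,
               chain_id: str | None = None) -> float:
    """Total SASA (A^2) of the structure or of one chain in isolation."""
    if chain_id is None:
        return float(sasa(s, probe, samples_per_atom).sum())
    subset = [i for i, a in enumerate(s.atoms) if a.chain_id == chain_id]
    if not subset:
        raise ValueError(f"no atoms in chain {chain_id!r}")
    return float(sasa(s, probe, samples_per_atom, subset=subset).sum())


def interface_area(s: Structure, chain_a: str, chain_b: str,
                   probe: float = 1.4, samples_per_atom: int = 960) -> float:
    """Buried interface area between two chains (A^2):
    (SASA(A alone) + SASA(B alone) - SASA(AB)) / 2.  Symmetric in its
    arguments."""
    ids = {a.chain_id for a in s.atoms}
    for c in (chain_a, chain_b):
        if c not in ids:
            raise ValueError(f"chain {c!r} not present")
    both = [i for i, a in enumerate(s.atoms) if a.chain_id in (chain_a, chain_b)]
    sasa_ab = float(sasa(s, probe, samples_per_atom, subset=both).sum())
    sasa_a = total_sasa(s, probe, samples_per_atom, chain_id=chain_a)
    sasa_b = total_sasa(s, probe, samples_per_atom, chain_id=chain_b)
    return (sasa_a + sasa_b - sasa_ab) / 2.0


# --------------------------------------------------------------------------
# composition census
# --------------------------------------------------------------------------

def composition_census(source, chain_id: str | None = None,
                       sequence_source: str = "auto") -> dict:
    """Residue-type counts plus derived charge classes.

    ``source`` is a Structure (SEQRES preferred, observed residues as
    fallback; the provenance is recorded in the result) or a plain sequence
    of 3-letter codes.  Derived entries: acidic (D+E), basic_kr (K+R),
    charged (D/E/K/R), fraction_charged, and the acidic:basic ratio."""
    if isinstance(source, Structure):
        chains = [chain_id] if chain_id else source.chain_ids()
        seq: list[str] = []
        used = "seqres"
        for c in chains:
            part = source.sequence(c, source=sequence_source)
            if not source.seqres.get(c):
                used = "observed"
            seq.extend(part)
    else:
        seq = [r.upper() for r in source]
        used = "sequence"
    counts: dict[str, int] = {}
    for r in seq:
        counts[r] = counts.get(r, 0) + 1
    acidic = sum(counts.get(r, 0) for r in ACIDIC_RESIDUES)
    basic = sum(counts.get(r, 0) for r in _BASIC_KR)
    charged = sum(counts.get(r, 0) for r in _CHARGED)
    total = len(seq)
    return {
        "counts": counts,
        "n_residues": total,
        "acidic": acidic,
        "basic_kr": basic,
        "charged": charged,
        "fraction_charged": charged / total if total else 0.0,
        "acidic_to_basic": (acidic, basic),
        "source": used,
    }
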