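"""Geometric simulation of flexible motion.

The all-atom structure is biased along a (C-alpha) normal-mode direction in
small steps; after each step the bonding and steric geometry of the input
structure is restored by iterative constraint projection.  No force field
and no randomness are involved: the ensemble explores how far the structure
can travel along an "easy" direction while keeping every covalent length,
angle (as a 1-3 distance), locked torsion (as a 1-4 distance), retained
non-covalent contact, and steric floor within a tolerance.

A run halts after ``max_steps`` or at the first step whose geometry cannot
be restored to within tolerance; every ``frame_interval``-th step (plus the
input frame 0) is recorded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import json
import numpy as np
from scipy.spatial import cKDTree

from .enm import ElasticNetwork, NormalMode
from .interactions import (
    KIND_COVALENT_LOCKED,
    ConstraintNetwork,
    InteractionParams,
    build_network,
)
from .structure_io import Structure

Direction = Literal["parallel", "antiparallel"]


@dataclass
class GeoSimConfig:
    """Step, tolerance and constraint parameters for a geometric simulation.

    ``step_scale`` is the bias amplitude per step in A (applied to the unit
    mode vector), ``tolerance`` the restoration criterion on constraint and
    steric deviations, ``network_cutoff`` the energy cut-off of the retained
    non-covalent network, and ``steric_factor`` the fraction of the van der
    Waals radius sum used as the steric floor for non-bonded pairs.
    """

    step_scale: float = 0.1
    tolerance: float = 0.1
    max_steps: int = 500
    frame_interval: int = 50
    network_cutoff: float = -4.0
    direction: Direction = "parallel"
    max_relax_sweeps: int = 200
    steric_factor: float = 0.85

    def __post_init__(self) -> None:
        if self.step_scale <= 0 or self.tolerance <= 0:
            raise ValueError("step_scale and tolerance must be positive")
        if self.frame_interval > self.max_steps:
            raise ValueError("frame_interval must be <= max_steps")


@dataclass
class ConstraintTargets:
    """Distance-constraint system extracted from a structure + network.

    Equality constraints hold covalent 1-2 lengths, 1-3 angle surrogates and
    1-4 distances across locked bonds at their input-structure values.
    Upper bounds keep polar / tether contacts from lengthening beyond their
    input value; steric floors keep non-bonded pairs above a fraction of the
    van der Waals sum (never demanding more separation than the input
    structure itself had)."""

    eq_pairs: np.ndarray          # (m, 2) int
    eq_targets: np.ndarray        # (m,)
    ub_pairs: np.ndarray          # (m2, 2) int
    ub_targets: np.ndarray        # (m2,)
    excluded: set[tuple[int, int]]  # pairs exempt from the steric floor
    radii: np.ndarray             # per-atom vdW radius
    steric_factor: float
    initial_floor_cap: dict[tuple[int, int], float] = field(default_factory=dict)

    def steric_floor(self, i: int, j: int) -> float:
        floor = self.steric_factor * (self.radii[i] + self.radii[j])
        key = (i, j) if i < j else (j, i)
        cap = self.initial_floor_cap.get(key)
        return min(floor, cap) if cap is not None else floor


def constraint_targets(s: Structure, net: ConstraintNetwork,
                       params: InteractionParams | None = None,
                       steric_factor: float = 0.85) -> ConstraintTargets:
    """Build the distance-constraint system for geometric simulation."""
    p = params or InteractionParams()
    coords = s.coord_array()
    n = len(s.atoms)

    adj: list[list[int]] = [[] for _ in range(n)]
    locked: list[tuple[int, int]] = []
    eq: dict[tuple[int, int], float] = {}
    ub: dict[tuple[int, int], float] = {}

    def key(i: int, j: int) -> tuple[int, int]:
        return (i, j) if i < j else (j, i)

    def dist(i: int, j: int) -> float:
        return float(np.linalg.norm(coords[i] - coords[j]))

    for c in net.constraints:
        if c.kind.startswith("covalent"):
            adj[c.atom_i].append(c.atom_j)
            adj[c.atom_j].append(c.atom_i)
            eq[key(c.atom_i, c.atom_j)] = dist(c.atom_i, c.atom_j)
            if c.kind == KIND_COVALENT_LOCKED:
                locked.append((c.atom_i, c.atom_j))
        else:  # polar or tether: keep the contact, allow shortening
            ub.setdefault(key(c.atom_i, c.atom_j), dist(c.atom_i, c.atom_j))

    # 1-3 angle surrogates
    for b in range(n):
        nbrs = sorted(set(adj[b]))
        for x in range(len(nbrs)):
            for y in range(x + 1, len(nbrs)):
                i, j = nbrs[x], nbrs[y]
                eq.setdefault(key(i, j), dist(i, j))
    # 1-4 distances across torsionally locked bonds
    for (b, c) in locked:
        for a in set(adj[b]) - {c}:
            for d in set(adj[c]) - {b}:
                if a != d:
                    eq.setdefault(key(a, d), dist(a, d))

    # pairs exempt from the steric floor: 1-2, 1-3, 1-4 and constrained pairs
    excluded: set[tuple[int, int]] = set(eq) | set(ub)
    for b in range(n):
        for c in set(adj[b]):
            for a in set(adj[b]) - {c}:
                for d in set(adj[c]) - {b}:
                    if a != d:
                        excluded.add(key(a, d))
    # hydrogen-bond hydrogens sit closer to the acceptor than the floor
    for c in net.constraints:
        if c.kind == "polar":
            for end in (c.atom_i, c.atom_j):
                other = c.atom_j if end == c.atom_i else c.atom_i
                for h in adj[end]:
                    if s.atoms[h].element == "H":
                        excluded.add(key(h, other))

    radii = np.array([p.vdw_radii.get(a.element, 1.7) for a in s.atoms])

    eq_pairs = np.array(sorted(eq), dtype=int).reshape(-1, 2)
    ub_pairs = np.array(sorted(ub), dtype=int).reshape(-1, 2)
    targets = ConstraintTargets(
        eq_pairs=eq_pairs,
        eq_targets=np.array([eq[tuple(p_)] for p_ in eq_pairs]),
        ub_pairs=ub_pairs,
        ub_targets=np.array([ub[tuple(p_)] for p_ in ub_pairs]),
        excluded=excluded,
        radii=radii,
        steric_factor=steric_factor,
    )
    # cap floors at input-structure separations so the input itself is valid
    tree = cKDTree(coords)
    rmax = steric_factor * 2 * radii.max()
    for a, b in tree.query_pairs(rmax):
        i, j = (a, b) if a < b else (b, a)
        if (i, j) in excluded:
            continue
        d = dist(i, j)
        if d < targets.steric_floor(i, j):
            targets.initial_floor_cap[(i, j)] = d
    return targets


def _steric_pairs(coords: np.ndarray, targets: ConstraintTargets,
                  margin: float = 0.6):
    """Non-excluded pairs near the steric floor (with a motion margin)."""
    rmax = targets.steric_factor * 2 * targets.radii.max() + margin
    tree = cKDTree(coords)
    pairs, floors = [], []
    for a, b in sorted(tree.query_pairs(rmax)):
        i, j = (a, b) if a < b else (b, a)
        if (i, j) in targets.excluded:
            continue
        pairs.append((i, j))
        floors.append(targets.steric_floor(i, j))
    if not pairs:
        return np.empty((0, 2), dtype=int), np.empty(0)
    return np.array(pairs, dtype=int), np.array(floors)


def _violations(coords, targets, st_pairs, st_floors):
    """(eq deltas, ub deltas, steric deltas); deltas signed d - target."""
    def deltas(pairs, ref):
        if len(pairs) == 0:
            return np.empty(0)
        d = np.linalg.norm(coords[pairs[:, 1]] - coords[pairs[:, 0]], axis=1)
        return d - ref

    eq_d = deltas(targets.eq_pairs, targets.eq_targets)
    ub_d = np.maximum(deltas(targets.ub_pairs, targets.ub_targets), 0.0)
    st_d = np.minimum(deltas(st_pairs, st_floors), 0.0)
    return eq_d, ub_d, st_d


def max_violation(coords: np.ndarray, targets: ConstraintTargets) -> float:
    """Largest constraint deviation (A) of a coordinate set."""
    st_pairs, st_floors = _steric_pairs(coords, targets, margin=0.0)
    eq_d, ub_d, st_d = _violations(coords, targets, st_pairs, st_floors)
    worst = 0.0
    for arr in (np.abs(eq_d), ub_d, -st_d):
        if arr.size:
            worst = max(worst, float(arr.max()))
    return worst


def relax_geometry(coords: np.ndarray, targets: ConstraintTargets,
                   cfg: GeoSimConfig | None = None,
                   ) -> tuple[np.ndarray, int, float]:
    """Restore constraint geometry by iterative projection.

    Sweeps over all constraints, computing for each pair the displacement
    that satisfies it exactly (both atoms moved equally and oppositely) and
    applying the per-atom average of all pairwise corrections, until the
    largest violation is far inside tolerance or the sweep budget is
    exhausted.  Returns (new coords, sweeps used, final max violation).
    A coordinate set already satisfying every constraint is returned
    unchanged with 0 sweeps.
    """
    cfg = cfg or GeoSimConfig()
    coords = np.asarray(coords, dtype=float).copy()
    inner_tol = min(cfg.tolerance * 0.3, 0.03)

    st_pairs, st_floors = _steric_pairs(coords, targets)
    all_pairs = np.vstack([targets.eq_pairs, targets.ub_pairs, st_pairs])

    counts = np.zeros(len(coords))
    if len(all_pairs):
        np.add.at(counts, all_pairs[:, 0], 1.0)
        np.add.at(counts, all_pairs[:, 1], 1.0)
    counts = np.maximum(counts, 1.0)

    sweeps = 0
    worst = _worst(coords, targets, st_pairs, st_floors)
    while worst > inner_tol and sweeps < cfg.max_relax_sweeps:
        eq_d, ub_d, st_d = _violations(coords, targets, st_pairs, st_floors)
        disp = np.zeros_like(coords)
        for pairs, deltas in ((targets.eq_pairs, eq_d),
                              (targets.ub_pairs, ub_d),
                              (st_pairs, st_d)):
            if len(pairs) == 0:
                continue
            active = np.abs(deltas) > 1e-12
            if not np.any(active):
                continue
            pi = pairs[active]
            dd = deltas[active]
            vec = coords[pi[:, 1]] - coords[pi[:, 0]]
            dist = np.linalg.norm(vec, axis=1)
            u = vec / dist[:, None]
            corr = 0.5 * dd[:, None] * u
            np.add.at(disp, pi[:, 0], corr)
            np.add.at(disp, pi[:, 1], -corr)
        coords = coords + disp / counts[:, None]
        sweeps += 1
        worst = _worst(coords, targets, st_pairs, st_floors)
    return coords, sweeps, worst


def _worst(coords, targets, st_pairs, st_floors) -> float:
    eq_d, ub_d, st_d = _violations(coords, targets, st_pairs, st_floors)
    worst = 0.0
    for arr in (np.abs(eq_d), ub_d, -st_d):
        if arr.size:
            worst = max(worst, float(arr.max()))
    return worst


@dataclass
class Ensemble:
    """Ordered all-atom coordinate frames from a geometric simulation."""

    structure: Structure
    frames: list[np.ndarray]
    steps_completed: int
    halt_reason: Literal["max_steps", "geometry_unrestorable"]
    frame_violations: list[float] = field(default_factory=list)
    mode_index: int | None = None
    direction: Direction | None = None

    def __len__(self) -> int:
        return len(self.frames)

    def to_structures(self) -> list[Structure]:
        out = []
        for f in self.frames:
            frame = self.structure.copy()
            frame.set_coords(f)
            out.append(frame)
        return out

    def write(self, path: str | Path) -> None:
        from .structure_io import write_ensemble
        write_ensemble(self.to_structures(), path)

    def run_log(self) -> dict:
        return {
            "mode_index": self.mode_index,
            "direction": self.direction,
            "steps_completed": self.steps_completed,
            "halt_reason": self.halt_reason,
            "n_frames": len(self.frames),
            "frame_max_violation": self.frame_violations,
        }


def project_mode(mode: NormalMode, s: Structure, net: ElasticNetwork,
                 step_scale: float = 0.1,
                 direction: Direction = "parallel") -> np.ndarray:
    """All-atom bias vector from a C-alpha mode: each atom inherits its
    residue's node displacement; the full vector is normalized to unit norm
    and scaled by ``step_scale`` (negated for antiparallel)."""
    node_of = {key: i for i, key in enumerate(net.node_residues)}
    disp = mode.node_displacements()
    bias = np.zeros((len(s.atoms), 3))
    for res in s.residues():
        if res.name not in node_of and res.key() not in node_of:
            pass
        idx = node_of.get(res.key())
        if idx is None:
            if any(not s.atoms[i].is_hetero for i in res.atom_indices):
                raise ValueError(
                    f"residue {res.chain_id}{res.number} has no network node")
            continue
        for i in res.atom_indices:
            bias[i] = disp[idx]
    norm = np.linalg.norm(bias)
    if norm == 0.0:
        raise ValueError("mode projects to a zero bias vector")
    bias = bias / norm * step_scale
    if direction == "antiparallel":
        bias = -bias
    return bias


def run_geosim(s: Structure, mode: NormalMode, cfg: GeoSimConfig | None = None,
               enm_net: ElasticNetwork | None = None,
               net: ConstraintNetwork | None = None,
               params: InteractionParams | None = None) -> Ensemble:
    """Bias the structure along a mode, restoring geometry each step.

    Deterministic given its inputs.  Frames (including frame 0) are saved
    every ``cfg.frame_interval`` steps; the run halts after ``max_steps`` or
    at the first step whose geometry cannot be restored to within
    ``cfg.tolerance``, whichever comes first.
    """
    from .enm import build_enm

    cfg = cfg or GeoSimConfig()
    if enm_net is None:
        enm_net = build_enm(s)
    if net is None:
        net = build_network(s, cutoff=cfg.network_cutoff, params=params)
    targets = constraint_targets(s, net, params=params,
                                 steric_factor=cfg.steric_factor)
    bias = project_mode(mode, s, enm_net, cfg.step_scale, cfg.direction)

    coords = s.coord_array()
    frames = [coords.copy()]
    violations = [max_violation(coords, targets)]
    steps_completed = 0
    halt = "max_steps"
    for step in range(1, cfg.max_steps + 1):
        trial = coords + bias
        relaxed, _sweeps, worst = relax_geometry(trial, targets, cfg)
        if worst > cfg.tolerance:
            halt = "geometry_unrestorable"
            break
        coords = relaxed
        steps_completed = step
        if step % cfg.frame_interval == 0:
            frames.append(coords.copy())
            violations.append(worst)
    return Ensemble(structure=s, frames=frames,
                    steps_completed=steps_completed, halt_reason=halt,
                    frame_violations=violations,
                    mode_index=mode.index, direction=cfg.direction)


def write_run_log(ensemble: Ensemble, path: str | Path) -> None:
    Path(path).write_text(json.dumps(ensemble.run_log(), indent=2) + "\n")
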