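"""One-node-per-residue anisotropic elastic network model.

Nodes sit at the C-alpha positions; uniform springs join every node pair
closer than a distance cut-off (default 10 A, strict inequality).  The
Hessian is the standard anisotropic network form: per spring a 3x3 block
-k * (r_hat r_hat^T) off-diagonal, accumulated on-diagonal.  Six trivial
rigid-body modes (three translations, three rotations about the centroid)
are constructed analytically; the lowest non-trivial modes are extracted by
shifted inverse iteration with deflation rather than a full
eigendecomposition, and are indexed 07 upward following the convention that
modes 01-06 are the trivial ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.spatial import cKDTree

from ._chem import STANDARD_RESIDUES
from .structure_io import RegionSelection, Structure


class ENMError(Exception):
    pass


class MissingCalphaError(ENMError):
    """A polymer residue has no C-alpha atom."""


class CollinearGeometryError(ENMError):
    """Node geometry is degenerate (collinear), rotations are not all
    independent."""


class ConvergenceError(ENMError):
    """Inverse iteration failed to reach the residual tolerance."""


@dataclass
class ElasticNetwork:
    """C-alpha node network with uniform springs inside a distance cut-off."""

    nodes: np.ndarray                      # (N, 3) positions, A
    node_residues: list[tuple[str, int, str]]  # (chain, resnum, icode)
    spring_pairs: np.ndarray               # (M, 2) int
    spring_constant: float = 1.0
    distance_cutoff: float = 10.0

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def hessian(self) -> sp.csr_matrix:
        """3N x 3N anisotropic-network Hessian."""
        n = self.n_nodes
        k = self.spring_constant
        rows, cols, vals = [], [], []
        for i, j in self.spring_pairs:
            rij = self.nodes[j] - self.nodes[i]
            d = np.linalg.norm(rij)
            u = rij / d
            block = k * np.outer(u, u)
            for a in range(3):
                for b in range(3):
                    v = block[a, b]
                    rows += [3 * i + a, 3 * j + a, 3 * i + a, 3 * j + a]
                    cols += [3 * j + b, 3 * i + b, 3 * i + b, 3 * j + b]
                    vals += [-v, -v, v, v]
        h = sp.coo_matrix((vals, (rows, cols)), shape=(3 * n, 3 * n))
        return h.tocsr()


@dataclass
class NormalMode:
    """One eigenpair of the network Hessian.

    Indices 1-6 are the trivial rigid-body motions (eigenvalue 0); the
    lowest non-trivial modes are numbered from 7.  Eigenvectors are unit
    3N-vectors."""

    index: int
    eigenvalue: float
    eigenvector: np.ndarray

    def node_displacements(self) -> np.ndarray:
        return self.eigenvector.reshape(-1, 3)


def build_enm(s: Structure, cutoff: float = 10.0,
              spring_constant: float = 1.0) -> ElasticNetwork:
    """Elastic network over the C-alpha atoms of all polymer residues.

    Springs join node pairs strictly closer than ``cutoff`` (A).  Raises
    :class:`MissingCalphaError` listing any standard residue without a CA.
    """
    nodes, keys, missing = [], [], []
    for res in s.residues():
        if res.name not in STANDARD_RESIDUES:
            continue
        ca = next((s.atoms[i] for i in res.atom_indices
                   if s.atoms[i].name == "CA"), None)
        if ca is None:
            missing.append(f"{res.chain_id}{res.number}")
        else:
            nodes.append(ca.position)
            keys.append(res.key())
    if missing:
        raise MissingCalphaError(
            "residues lacking a C-alpha: " + ", ".join(missing))
    if not nodes:
        raise ENMError("no C-alpha nodes found")
    coords = np.array(nodes)
    tree = cKDTree(coords)
    pairs = np.array(sorted(tree.query_pairs(cutoff)), dtype=int)
    # query_pairs uses <= r; enforce the strict inequality
    if len(pairs):
        d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
        pairs = pairs[d < cutoff]
    else:
        pairs = np.empty((0, 2), dtype=int)
    return ElasticNetwork(nodes=coords, node_residues=keys,
                          spring_pairs=pairs,
                          spring_constant=spring_constant,
                          distance_cutoff=cutoff)


def _rigid_basis(net: ElasticNetwork, min_rank: int | None = None) -> np.ndarray:
    """Orthonormal basis of rigid-body motions (columns).  Rank 6 for
    generic geometry, 5 for collinear nodes."""
    n = net.n_nodes
    centroid = net.nodes.mean(axis=0)
    rel = net.nodes - centroid
    raw = np.zeros((3 * n, 6))
    for a in range(3):
        raw[a::3, a] = 1.0
    axes = np.eye(3)
    for a in range(3):
        rot = np.cross(np.broadcast_to(axes[a], rel.shape), rel)
        raw[:, 3 + a] = rot.reshape(-1)
    q, r = np.linalg.qr(raw)
    diag = np.abs(np.diag(r))
    keep = diag > 1e-10 * max(diag.max(), 1.0)
    basis = q[:, keep]
    if min_rank is not None and basis.shape[1] < min_rank:
        raise CollinearGeometryError(
            "node geometry is degenerate (collinear); only "
            f"{basis.shape[1]} independent rigid-body motions")
    return basis


def trivial_modes(net: ElasticNetwork) -> list[NormalMode]:
    """The six zero-frequency rigid-body modes, orthonormalized.

    Requires at least three non-collinear nodes; each returned vector lies
    in the Hessian null space by construction."""
    if net.n_nodes < 3:
        raise CollinearGeometryError("need at least 3 nodes for 6 rigid modes")
    basis = _rigid_basis(net, min_rank=6)
    return [NormalMode(index=i + 1, eigenvalue=0.0,
                       eigenvector=_sign_fix(basis[:, i]))
            for i in range(6)]


def _sign_fix(v: np.ndarray) -> np.ndarray:
    nz = np.nonzero(np.abs(v) > 1e-8)[0]
    if len(nz) and v[nz[0]] < 0:
        return -v
    return v


def lowest_modes(net: ElasticNetwork, n: int = 10,
                 tol: float = 1e-9, max_iter: int = 2000
                 ) -> list[NormalMode]:
    """The ``n`` lowest-frequency non-trivial modes by shifted block inverse
    iteration (subspace iteration with Rayleigh-Ritz extraction), deflated
    against the rigid-body null space.  Only repeated shifted solves are
    used -- the Hessian is never fully diagonalized.  Returned modes are
    indexed 07 .. 06+n with non-decreasing eigenvalues; each satisfies
    ||Hv - lambda v|| <= tol * lambda_max."""
    h = net.hessian()
    dim = h.shape[0]
    rigid = _rigid_basis(net)
    n_rigid = rigid.shape[1]
    if n > dim - n_rigid:
        raise ENMError(f"requested {n} non-trivial modes; only "
                       f"{dim - n_rigid} exist")
    lam_max = float(np.abs(h).sum(axis=1).max())  # Gershgorin bound
    if lam_max == 0.0:
        raise ENMError("network has no springs; all modes are trivial")
    sigma = 1e-6 * lam_max
    lu = spla.splu((h + sigma * sp.identity(dim)).tocsc())

    # guard vectors accelerate convergence of the wanted block
    block = min(n + 4, dim - n_rigid)
    rng = np.random.default_rng(20211201)

    def deflate(v: np.ndarray) -> np.ndarray:
        return v - rigid @ (rigid.T @ v)

    v = deflate(rng.standard_normal((dim, block)))
    v, _ = np.linalg.qr(v)
    resid = np.inf
    for _ in range(max_iter):
        w = deflate(lu.solve(v))
        w, _ = np.linalg.qr(w)
        # Rayleigh-Ritz in the current subspace
        hw = h @ w
        small = w.T @ hw
        small = 0.5 * (small + small.T)
        evals, rot = np.linalg.eigh(small)
        v = w @ rot
        hv = hw @ rot
        resid = max(
            float(np.linalg.norm(hv[:, k] - evals[k] * v[:, k]))
            for k in range(n)
        )
        if resid <= tol * lam_max:
            break
    else:
        raise ConvergenceError(
            f"residual {resid:.2e} after {max_iter} block iterations "
            f"(tolerance {tol * lam_max:.2e})")

    modes = [
        NormalMode(index=7 + k, eigenvalue=float(evals[k]),
                   eigenvector=_sign_fix(v[:, k] / np.linalg.norm(v[:, k])))
        for k in range(n)
    ]
    return modes


def mode_participation(mode: NormalMode, region: RegionSelection,
                       net: ElasticNetwork) -> float:
    """Fraction of the mode's squared amplitude carried by a residue region
    (1.0 for the whole structure)."""
    idx = [i for i, (chain, num, _ic) in enumerate(net.node_residues)
           if region.contains(chain, num)]
    if not idx:
        raise ValueError(f"region {region} maps onto no network nodes")
    disp = mode.node_displacements()
    total = float(np.sum(disp ** 2))
    return float(np.sum(disp[idx] ** 2) / total)


# --------------------------------------------------------------------------
# output writers
# --------------------------------------------------------------------------

def write_mode_table(modes: list[NormalMode], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("mode\teigenvalue\n")
        for m in modes:
            fh.write(f"{m.index:02d}\t{m.eigenvalue:.8g}\n")


def write_mode_vectors(modes: list[NormalMode], net: ElasticNetwork,
                       path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("mode\tchain\tresnum\tdx\tdy\tdz\n")
        for m in modes:
            for (chain, num, _ic), d in zip(net.node_residues,
                                            m.node_displacements()):
                fh.write(f"{m.index:02d}\t{chain}\t{num}\t"
                         f"{d[0]:.6f}\t{d[1]:.6f}\t{d[2]:.6f}\n")


def write_mode_animation(s: Structure, net: ElasticNetwork, mode: NormalMode,
                         path: str | Path, amplitude: float = 3.0,
                         n_frames: int = 7) -> None:
    """Multi-model PDB sweeping the structure so its most-displaced atom
    moves +/- ``amplitude`` A along a mode (per-residue rigid displacement
    of each residue with its CA node)."""
    from .geosim import project_mode
    from .structure_io import write_ensemble

    bias = project_mode(mode, s, net, step_scale=1.0)
    bias = bias / np.linalg.norm(bias, axis=1).max()
    base = s.coord_array()
    frames = []
    for t in np.linspace(-amplitude, amplitude, n_frames):
        frame = s.copy()
        frame.set_coords(base + t * bias)
        frames.append(frame)
    write_ensemble(frames, path)
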