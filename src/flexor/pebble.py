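"""Body-bar pebble-game rigidity analysis.

Every atom (or abstract vertex) is a rigid body with six degrees of freedom;
each constraint contributes one to six "bars", each bar generically removing
one relative degree of freedom.  The (6,6) pebble game plays out Tay's
theorem combinatorially: a multigraph is the bar multiset of a generically
isostatic body-bar framework exactly when it is (6,6)-tight, so counting
accepted (independent) bars yields the generic rank of the framework and
hence the number of internal "floppy" modes, with no numerics.

The game: every body starts with six pebbles.  A bar between u and v is
accepted iff seven pebbles can be gathered onto {u, v} by reversing
previously accepted bars; accepting consumes one pebble.  The accepted-bar
count is a matroid rank, hence independent of insertion order.

Rigid clusters are maximal body sets with zero pairwise relative degrees of
freedom, identified after the game by pinning six pebbles on a seed body and
testing whether a seventh pebble is reachable from candidate bodies; a
failed search marks its whole visited region as rigid with the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

DOF_PER_BODY = 6


@dataclass
class BodyBarGraph:
    """Multigraph of rigid bodies joined by bars.

    ``edges`` maps an unordered body pair to its bar multiplicity; parallel
    constraint bars between the same pair sum and are capped at six (more
    than six bars between two six-DOF bodies is always redundant).
    """

    n_bodies: int
    edges: dict[tuple[int, int], int] = field(default_factory=dict)
    provenance: dict[tuple[int, int], list] = field(default_factory=dict)

    @classmethod
    def from_bars(cls, n_bodies: int,
                  bars: Iterable[tuple[int, int, int]]) -> "BodyBarGraph":
        """Build from (u, v, multiplicity) triples, aggregating and capping."""
        g = cls(n_bodies)
        for u, v, m in bars:
            g.add_bars(u, v, m)
        return g

    def add_bars(self, u: int, v: int, multiplicity: int, tag=None) -> None:
        if u == v:
            raise ValueError("self-bars are not allowed")
        if not (0 <= u < self.n_bodies and 0 <= v < self.n_bodies):
            raise ValueError("body index out of range")
        if multiplicity < 1:
            raise ValueError("bar multiplicity must be >= 1")
        key = (u, v) if u < v else (v, u)
        self.edges[key] = min(DOF_PER_BODY, self.edges.get(key, 0) + multiplicity)
        if tag is not None:
            self.provenance.setdefault(key, []).append(tag)

    def bar_list(self) -> list[tuple[int, int]]:
        """Individual bars, one entry per unit bar, in insertion order."""
        out = []
        for (u, v), m in self.edges.items():
            out.extend([(u, v)] * m)
        return out

    def total_bars(self) -> int:
        return sum(self.edges.values())

    def neighbors(self) -> list[list[int]]:
        adj: list[list[int]] = [[] for _ in range(self.n_bodies)]
        for (u, v) in self.edges:
            adj[u].append(v)
            adj[v].append(u)
        return adj


@dataclass
class RigidClusterDecomposition:
    """Partition of bodies into rigid clusters.

    Clusters are sorted by size descending, ties broken by smallest member,
    and labelled 1..K in that order.  ``floppy_modes`` counts internal
    degrees of freedom with the six global rigid-body motions removed.
    """

    clusters: list[list[int]]
    floppy_modes: int
    independent_bars: int = 0
    redundant_bars: int = 0

    def __post_init__(self) -> None:
        self.clusters = sorted(
            (sorted(c) for c in self.clusters),
            key=lambda c: (-len(c), c[0]),
        )

    @property
    def cluster_of(self) -> dict[int, int]:
        return {b: k for k, cluster in enumerate(self.clusters, start=1)
                for b in cluster}

    def largest_size(self) -> int:
        return len(self.clusters[0]) if self.clusters else 0

    def summary(self) -> dict:
        return {
            "n_clusters": len(self.clusters),
            "largest_size": self.largest_size(),
            "floppy_modes": self.floppy_modes,
            "independent_bars": self.independent_bars,
            "redundant_bars": self.redundant_bars,
        }


class _PebbleGame:
    """Mutable (6,6) pebble-game state with directed accepted bars."""

    def __init__(self, n: int):
        self.n = n
        self.pebbles = [DOF_PER_BODY] * n
        self.out: list[list[int]] = [[] for _ in range(n)]

    # -- pebble search --------------------------------------------------------
    def _gather_one(self, start: int, forbidden: frozenset[int]) -> bool:
        """Move one free pebble to ``start`` by path reversal; False if none
        reachable.  Pebbles sitting on ``forbidden`` bodies are not taken."""
        parent: dict[int, int] = {start: -1}
        stack = [start]
        found = -1
        while stack:
            w = stack.pop()
            if w != start and w not in forbidden and self.pebbles[w] > 0:
                found = w
                break
            for x in self.out[w]:
                if x not in parent:
                    parent[x] = w
                    stack.append(x)
        if found < 0:
            return False
        # reverse the path start -> ... -> found
        node = found
        while parent[node] != -1:
            prev = parent[node]
            self.out[prev].remove(node)
            self.out[node].append(prev)
            node = prev
        self.pebbles[found] -= 1
        self.pebbles[start] += 1
        return True

    def _reachable_free(self, start: int, forbidden: frozenset[int]
                        ) -> tuple[bool, set[int]]:
        """Read-only: is a free pebble (outside ``forbidden``) reachable from
        ``start``?  Returns (found, visited bodies)."""
        visited = {start}
        stack = [start]
        while stack:
            w = stack.pop()
            if w not in forbidden and self.pebbles[w] > 0:
                return True, visited
            for x in self.out[w]:
                if x not in visited:
                    visited.add(x)
                    stack.append(x)
        return False, visited

    # -- bar insertion --------------------------------------------------------
    def insert_bar(self, u: int, v: int) -> bool:
        """Try to accept one bar between u and v; True if independent."""
        pair = frozenset((u, v))
        while self.pebbles[u] + self.pebbles[v] < DOF_PER_BODY + 1:
            moved = False
            if self.pebbles[u] < DOF_PER_BODY:
                moved = self._gather_one(u, pair)
            if not moved and self.pebbles[v] < DOF_PER_BODY:
                moved = self._gather_one(v, pair)
            if not moved:
                return False
        tail, head = (u, v) if self.pebbles[u] > 0 else (v, u)
        self.pebbles[tail] -= 1
        self.out[tail].append(head)
        return True

    def free_pebbles(self) -> int:
        return sum(self.pebbles)


def _play(g: BodyBarGraph, order: Sequence[tuple[int, int]] | None = None
          ) -> tuple[_PebbleGame, int]:
    game = _PebbleGame(g.n_bodies)
    bars = list(order) if order is not None else g.bar_list()
    accepted = 0
    for (u, v) in bars:
        if game.insert_bar(u, v):
            accepted += 1
    return game, accepted


def pebble_game(g: BodyBarGraph,
                order: Sequence[tuple[int, int]] | None = None
                ) -> tuple[int, int]:
    """Run the (6,6) pebble game; return (independent bars, floppy modes).

    Floppy modes are total free pebbles minus six, i.e. internal degrees of
    freedom after removing one set of global rigid-body motions; for a
    connected framework this equals 6V - 6 - rank.  The result is
    order-independent (matroid rank); ``order`` only fixes the insertion
    sequence for reproducibility experiments.
    """
    game, accepted = _play(g, order)
    floppy = game.free_pebbles() - DOF_PER_BODY
    return accepted, max(floppy, 0)


def rigid_clusters(g: BodyBarGraph) -> RigidClusterDecomposition:
    """Decompose bodies into maximal mutually rigid clusters."""
    game, accepted = _play(g)
    floppy = max(game.free_pebbles() - DOF_PER_BODY, 0)
    adj = g.neighbors()

    label = [-1] * g.n_bodies
    clusters: list[list[int]] = []
    for seed in range(g.n_bodies):
        if label[seed] >= 0:
            continue
        # pin six pebbles on the seed
        while game.pebbles[seed] < DOF_PER_BODY:
            ok = game._gather_one(seed, frozenset((seed,)))
            if not ok:  # impossible in a valid game state
                raise RuntimeError("pebble gathering failed")
        cluster = {seed}
        not_rigid: set[int] = set()
        frontier = [v for v in sorted(set(adj[seed])) if label[v] < 0]
        while frontier:
            v = frontier.pop()
            if v in cluster or v in not_rigid or label[v] >= 0:
                continue
            found, visited = game._reachable_free(v, frozenset((seed,)))
            if found:
                not_rigid.add(v)
            else:
                for w in visited:
                    if w not in cluster and label[w] < 0:
                        cluster.add(w)
                        frontier.extend(x for x in sorted(set(adj[w]))
                                        if label[x] < 0 and x not in cluster)
        cid = len(clusters)
        for w in cluster:
            label[w] = cid
        clusters.append(sorted(cluster))

    return RigidClusterDecomposition(
        clusters=clusters,
        floppy_modes=floppy,
        independent_bars=accepted,
        redundant_bars=g.total_bars() - accepted,
    )


# --------------------------------------------------------------------------
# molecular wrappers
# --------------------------------------------------------------------------

@dataclass
class DilutionSeries:
    """Rigid-cluster decompositions over a descending series of energy
    cut-offs, in one temperature regime."""

    regime: str
    entries: list[tuple[float, RigidClusterDecomposition]]

    def largest_sizes(self) -> list[int]:
        return [dec.largest_size() for _, dec in self.entries]

    def summary(self) -> list[dict]:
        return [
            {"cutoff": cutoff, "regime": self.regime, **dec.summary()}
            for cutoff, dec in self.entries
        ]


def graph_from_network(net) -> BodyBarGraph:
    """Body-bar multigraph of a :class:`~flexor.interactions.ConstraintNetwork`:
    one body per atom, bar multiplicities from the constraint kinds."""
    n = len(net.structure.atoms)
    g = BodyBarGraph(n)
    for c in net.constraints:
        g.add_bars(c.atom_i, c.atom_j, c.bars, tag=c.kind)
    return g


def rigidity_dilution(s, cutoffs: Sequence[float], regime: str = "ambient",
                      params=None) -> DilutionSeries:
    """Rigid-cluster decomposition at each cut-off of a dilution series.

    ``cutoffs`` must be sorted descending (toward more negative values); the
    constraint network is rebuilt at each cut-off with regime-appropriate
    tether bars.
    """
    from .interactions import build_network

    cutoffs = list(cutoffs)
    if any(b >= a for a, b in zip(cutoffs, cutoffs[1:])):
        raise ValueError("cutoffs must be strictly decreasing")
    entries = []
    for cutoff in cutoffs:
        net = build_network(s, cutoff=cutoff, regime=regime, params=params)
        entries.append((cutoff, rigid_clusters(graph_from_network(net))))
    return DilutionSeries(regime=regime, entries=entries)


# --------------------------------------------------------------------------
# output writers
# --------------------------------------------------------------------------

def write_cluster_tsv(s, dec: RigidClusterDecomposition, path: str | Path) -> None:
    """Atom -> cluster-label table (TSV)."""
    cluster_of = dec.cluster_of
    with open(path, "w") as fh:
        fh.write("serial\tchain\tresnum\tresname\tatom\tcluster\n")
        for i, a in enumerate(s.atoms):
            fh.write(f"{a.serial}\t{a.chain_id}\t{a.residue_number}\t"
                     f"{a.residue_name}\t{a.name}\t{cluster_of.get(i, 0)}\n")


def write_cluster_pymol(s, dec: RigidClusterDecomposition, path: str | Path,
                        n_colored: int = 20) -> None:
    """PyMOL command script colouring the largest clusters red -> blue."""
    import colorsys

    lines = ["color grey80, all"]
    shown = [c for c in dec.clusters if len(c) > 1][:n_colored]
    for k, cluster in enumerate(shown):
        frac = k / max(len(shown) - 1, 1)
        r, g, b = colorsys.hsv_to_rgb(frac * (240.0 / 360.0), 1.0, 1.0)
        lines.append(f"set_color cluster{k + 1}, [{r:.3f}, {g:.3f}, {b:.3f}]")
        serials = "+".join(str(s.atoms[i].serial) for i in cluster)
        lines.append(f"color cluster{k + 1}, id {serials}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_dilution_json(series: DilutionSeries, path: str | Path) -> None:
    Path(path).write_text(json.dumps(series.summary(), indent=2) + "\n")


def write_graph_tsv(g: BodyBarGraph, path: str | Path) -> None:
    """Edge list (body_i, body_j, bars) of a body-bar graph."""
    with open(path, "w") as fh:
        fh.write(f"# bodies\t{g.n_bodies}\n")
        fh.write("body_i\tbody_j\tbars\n")
        for (u, v), m in sorted(g.edges.items()):
            fh.write(f"{u}\t{v}\t{m}\n")


def read_graph_tsv(path: str | Path) -> BodyBarGraph:
    lines = Path(path).read_text().strip().splitlines()
    n_bodies = int(lines[0].split("\t")[1])
    g = BodyBarGraph(n_bodies)
    for line in lines[2:]:
        u, v, m = (int(x) for x in line.split("\t"))
        g.add_bars(u, v, m)
    return g
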