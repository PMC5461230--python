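"""Ring perception: ring-bond marking, SSSR, and bounded all-rings search.

``mark_rings`` flags every bond that lies on some cycle (linear time via a
bridge-finding DFS).  ``sssr`` returns a smallest set of smallest rings —
a minimum cycle basis — using Horton-style candidate generation with a
greedy GF(2) independence test; because the SSSR is not unique, ties are
broken deterministically by lexicographic atom order.  ``all_rings``
enumerates every simple cycle up to a size bound with a machine-
independent escape counter instead of a timeout.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .model import Molecule

__all__ = ["Ring", "RingSearchResult", "mark_rings", "circuit_rank", "sssr", "all_rings"]

DEFAULT_MAX_RING_SIZE = 12
DEFAULT_ESCAPE_THRESHOLD = 1_000_000


@dataclass(frozen=True)
class Ring:
    """A simple cycle as a cyclic ordered atom sequence, canonicalized so
    the smallest atom index comes first and its smaller neighbour second."""

    atoms: tuple[int, ...]

    @property
    def size(self) -> int:
        return len(self.atoms)

    @staticmethod
    def from_cycle(cycle: list[int]) -> "Ring":
        if len(set(cycle)) != len(cycle):
            raise ValueError("ring contains a repeated atom")
        k = cycle.index(min(cycle))
        rot = cycle[k:] + cycle[:k]
        if rot[-1] < rot[1]:
            rot = [rot[0]] + rot[:0:-1]
        return Ring(tuple(rot))

    def edges(self) -> set[frozenset[int]]:
        n = len(self.atoms)
        return {frozenset((self.atoms[i], self.atoms[(i + 1) % n])) for i in range(n)}


@dataclass(frozen=True)
class RingSearchResult:
    rings: tuple[Ring, ...]
    truncated: bool


def _graph(mol: Molecule) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(len(mol)))
    g.add_edges_from((b.begin, b.end) for b in mol.bonds)
    return g


def mark_rings(mol: Molecule) -> int:
    """Flag ring bonds in place and return the ring-bond count.

    A bond lies on a ring iff it is not a bridge of the graph.
    """
    g = _graph(mol)
    bridges = {frozenset(e) for e in nx.bridges(g)}
    count = 0
    for bond in mol.bonds:
        bond.in_ring = frozenset((bond.begin, bond.end)) not in bridges
        count += bond.in_ring
    return count


def circuit_rank(mol: Molecule) -> int:
    """|E| - |V| + number of connected components."""
    g = _graph(mol)
    return g.number_of_edges() - g.number_of_nodes() + nx.number_connected_components(g)


def _shortest_path_cycles(g: nx.Graph) -> list[Ring]:
    """Horton candidate rings: for each vertex v and edge (x, y), the cycle
    formed by shortest paths v..x, v..y plus the edge, when node-disjoint."""
    candidates: dict[tuple[int, ...], Ring] = {}
    for v in g.nodes:
        # BFS shortest-path tree with deterministic (sorted) neighbor order.
        parent: dict[int, int | None] = {v: None}
        order = [v]
        for u in order:
            for w in sorted(g.neighbors(u)):
                if w not in parent:
                    parent[w] = u
                    order.append(w)

        def path(u: int) -> list[int]:
            out = [u]
            while parent[out[-1]] is not None:
                out.append(parent[out[-1]])  # type: ignore[arg-type]
            return out[::-1]  # v .. u

        for x, y in g.edges:
            if x not in parent or y not in parent:
                continue
            px, py = path(x), path(y)
            if set(px) & set(py) != {v}:
                continue
            cycle = px + py[::-1][:-1]
            if len(cycle) < 3:
                continue  # BFS path ran through the edge itself
            ring = Ring.from_cycle(cycle)
            candidates.setdefault(ring.atoms, ring)
    return sorted(candidates.values(), key=lambda r: (r.size, r.atoms))


def _edge_vector(ring: Ring, edge_index: dict[frozenset[int], int]) -> int:
    vec = 0
    for e in ring.edges():
        vec |= 1 << edge_index[e]
    return vec


def sssr(mol: Molecule) -> list[Ring]:
    """A smallest set of smallest rings (minimum cycle basis).

    Exactly ``circuit_rank`` rings, chosen greedily from size-sorted
    candidates under GF(2) linear independence; output sorted by size then
    lexicographic atom order.
    """
    g = _graph(mol)
    rank = circuit_rank(mol)
    if rank == 0:
        return []
    edge_index = {frozenset(e): i for i, e in enumerate(g.edges)}
    basis: list[int] = []  # row-reduced GF(2) vectors
    chosen: list[Ring] = []
    for ring in _shortest_path_cycles(g):
        vec = _edge_vector(ring, edge_index)
        for row in basis:
            vec = min(vec, vec ^ row)
        if vec:
            basis.append(vec)
            basis.sort(reverse=True)
            chosen.append(ring)
            if len(chosen) == rank:
                break
    if len(chosen) != rank:  # pragma: no cover - Horton set always spans
        raise RuntimeError("candidate rings do not span the cycle space")
    return sorted(chosen, key=lambda r: (r.size, r.atoms))


def all_rings(
    mol: Molecule,
    max_size: int = DEFAULT_MAX_RING_SIZE,
    escape_threshold: int = DEFAULT_ESCAPE_THRESHOLD,
) -> RingSearchResult:
    """All simple cycles of size <= ``max_size``, each reported once.

    The search is a DFS rooted at the smallest vertex of each cycle; the
    work counter counts edges explored, and the search stops (reporting
    ``truncated=True``) once it exceeds ``escape_threshold``.
    """
    if max_size < 3:
        raise ValueError("max_size must be >= 3")
    g = _graph(mol)
    # Restrict to ring bonds: bridges can never participate in a cycle.
    bridges = {frozenset(e) for e in nx.bridges(g)}
    h = nx.Graph()
    h.add_edges_from(e for e in g.edges if frozenset(e) not in bridges)

    rings: list[Ring] = []
    work = 0
    truncated = False

    adj = {v: sorted(h.neighbors(v)) for v in h.nodes}
    for s in sorted(adj):
        if truncated:
            break
        # Cycles whose smallest vertex is s; path vertices all > s except s.
        stack: list[tuple[list[int], set[int]]] = [([s], {s})]
        while stack:
            if work > escape_threshold:
                truncated = True
                break
            path, onpath = stack.pop()
            v = path[-1]
            for w in adj[v]:
                work += 1
                if w == s and len(path) >= 3:
                    # Count each cycle once: fix the orientation.
                    if path[1] < path[-1]:
                        rings.append(Ring.from_cycle(path))
                elif w > s and w not in onpath and len(path) < max_size:
                    stack.append((path + [w], onpath | {w}))

    rings.sort(key=lambda r: (r.size, r.atoms))
    return RingSearchResult(tuple(rings), truncated)
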