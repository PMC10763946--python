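"""Communication-graph generation: ring lattice -> small world -> random.

Agents communicate over an undirected Watts-Strogatz graph.  The lattice
parameter ``k`` counts neighbours *per side* of the ring, so the regular
lattice has degree ``2k`` (degree 4 at the default ``k = 2``) — a degree-2
ring has zero clustering and could not support the clustering-based
structure effects the model is used to study.  Rewiring each clockwise
lattice edge with probability ``p_rewire`` moves the topology continuously
from the regular lattice (``p_rewire = 0``) through small-world graphs to a
random graph (``p_rewire = 1``), conserving the edge count throughout.

Disconnected graphs produced by rewiring are kept as-is; the engine records
a connectivity flag per run instead of repairing them.

For ``n <= 2k`` the ring cannot supply 2k distinct neighbours and the
generator saturates to the complete graph (e.g. n = 4, k = 2 gives K4), so
the smallest populations used in the size sweeps remain well defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple

import networkx as nx
import numpy as np

__all__ = [
    "NetworkTopology",
    "ring_lattice",
    "small_world",
    "clustering_coefficient",
    "export_edges",
    "read_edges",
]

Edge = Tuple[int, int]


@dataclass(frozen=True)
class NetworkTopology:
    """Undirected agent graph plus the generator parameters that made it."""

    n: int
    k: int
    p_rewire: float
    edges: frozenset

    def __post_init__(self) -> None:
        for u, v in self.edges:
            if u == v:
                raise ValueError(f"self-loop at node {u}")
            if not (0 <= u < self.n and 0 <= v < self.n):
                raise ValueError(f"edge ({u}, {v}) outside node range [0, {self.n})")

    @staticmethod
    def from_graph(graph: nx.Graph, k: int, p_rewire: float) -> "NetworkTopology":
        edges = frozenset(tuple(sorted(e)) for e in graph.edges())
        return NetworkTopology(n=graph.number_of_nodes(), k=k, p_rewire=p_rewire, edges=edges)

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(self.edges)
        return g

    def neighbors(self) -> list:
        """Adjacency as a list of sorted integer arrays, indexed by node."""
        adj: list = [[] for _ in range(self.n)]
        for u, v in self.edges:
            adj[u].append(v)
            adj[v].append(u)
        return [np.array(sorted(a), dtype=np.int64) for a in adj]

    def is_connected(self) -> bool:
        return nx.is_connected(self.to_graph()) if self.n > 0 else False

    def sorted_edges(self) -> list:
        return sorted(self.edges)


def _validate_nk(n: int, k: int) -> None:
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if n < 2:
        raise ValueError(f"need at least 2 nodes, got {n}")


def ring_lattice(n: int, k: int) -> NetworkTopology:
    """Regular ring lattice: each node adjacent to its k nearest neighbours
    on each side (degree 2k, edge count n*k).

    Saturates to the complete graph when n <= 2k + 1 (for n = 2k + 1 the
    lattice *is* complete; for smaller n no 2k-regular ring exists).
    """
    _validate_nk(n, k)
    if n <= 2 * k + 1:
        g = nx.complete_graph(n)
    else:
        g = nx.watts_strogatz_graph(n, 2 * k, 0.0)
    return NetworkTopology.from_graph(g, k=k, p_rewire=0.0)


def small_world(
    n: int, k: int, p_rewire: float, rng: np.random.Generator
) -> NetworkTopology:
    """Watts-Strogatz small-world graph.

    Starting from :func:`ring_lattice`, each clockwise lattice edge of each
    node is rewired, with probability ``p_rewire``, to a uniformly chosen
    target that is neither the node itself nor an existing neighbour.  Edge
    count is conserved for every ``p_rewire``.  Deterministic given the
    generator state.
    """
    _validate_nk(n, k)
    if not 0.0 <= p_rewire <= 1.0:
        raise ValueError(f"p_rewire must lie in [0, 1], got {p_rewire}")
    if n <= 2 * k + 1:
        # complete graph: every rewiring target is already a neighbour
        g = nx.complete_graph(n)
    else:
        seed = int(rng.integers(0, 2**32))
        g = nx.watts_strogatz_graph(n, 2 * k, p_rewire, seed=seed)
    return NetworkTopology.from_graph(g, k=k, p_rewire=p_rewire)


def clustering_coefficient(net: NetworkTopology) -> float:
    """Mean local clustering coefficient (nodes of degree < 2 contribute 0).

    For the k-per-side ring lattice this equals 3(k-1) / (2(2k-1)), i.e.
    0.5 at k = 2.
    """
    return float(nx.average_clustering(net.to_graph(), count_zeros=True))


def export_edges(net: NetworkTopology, destination) -> None:
    """Write a sorted, zero-based, whitespace-delimited edge list.

    One undirected edge per line, smaller index first.  Round-trips
    losslessly with :func:`read_edges`.  An edgeless graph produces an empty
    file with a warning.
    """
    edges = net.sorted_edges()
    if not edges:
        warnings.warn("exporting a graph with no edges", stacklevel=2)
    text = "".join(f"{u} {v}\n" for u, v in edges)
    if hasattr(destination, "write"):
        destination.write(text)
    else:
        with open(destination, "w", encoding="utf-8") as fh:
            fh.write(text)


def read_edges(source) -> list:
    """Read an edge list written by :func:`export_edges`.

    Returns the sorted list of (u, v) pairs with u < v.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source, "r", encoding="utf-8") as fh:
            text = fh.read()
    edges = []
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        u, v = (int(x) for x in line.split())
        edges.append((min(u, v), max(u, v)))
    return sorted(edges)
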