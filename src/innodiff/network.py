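"""Observation network: the social structure agents watch.

Group structure is a Barabási–Albert (BA) scale-free graph: starting from a
star on ``l + 1`` nodes, each new node attaches ``l`` edges to distinct
existing nodes with probability proportional to current degree.  The star
seed is a fixed convention that makes the edge count deterministic:
``l * (n - l)`` edges for ``n`` nodes.

Edges are undirected; agent i observes the adoption state of its adjacency
set B_i.  The quantity driving the dynamics is the neighborhood adoption
fraction q_i = (adopting neighbors) / |B_i|.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import scipy.sparse as sp

__all__ = [
    "ObservationNetwork",
    "generate_ba",
    "adoption_fraction",
    "read_edgelist",
    "write_edgelist",
]


@dataclass
class ObservationNetwork:
    """Undirected simple graph over agents 0 .. n-1.

    ``l`` records the attachment parameter for BA-generated networks and is
    None for imported graphs.
    """

    graph: nx.Graph
    l: int | None = None

    def __post_init__(self) -> None:
        n = self.graph.number_of_nodes()
        if set(self.graph.nodes) != set(range(n)):
            raise ValueError("node ids must be the contiguous integers 0 .. n-1")
        if any(self.graph.has_edge(i, i) for i in self.graph.nodes):
            raise ValueError("self-loops are not allowed")

    @property
    def n(self) -> int:
        return self.graph.number_of_nodes()

    def neighbor_sets(self) -> list[set[int]]:
        """B_i for every agent i."""
        return [set(self.graph.adj[i]) for i in range(self.n)]

    def adjacency(self) -> tuple[sp.csr_array, np.ndarray]:
        """CSR adjacency matrix and degree vector, node order 0 .. n-1."""
        a = nx.to_scipy_sparse_array(
            self.graph, nodelist=range(self.n), dtype=float, format="csr"
        )
        return a, np.asarray(a.sum(axis=1)).ravel()


def generate_ba(n: int, l: int, rng: np.random.Generator) -> ObservationNetwork:
    """Grow a BA preferential-attachment graph with star seed on l + 1 nodes.

    Parameters
    ----------
    n : int
        Number of nodes; must exceed ``l``.
    l : int
        Edges attached per new node (so the mean degree is about ``2 l``).
    rng : numpy.random.Generator
        Seeded source of randomness; identical (n, l, rng state) reproduces
        the graph bit for bit.
    """
    if l < 1:
        raise ValueError(f"attachment parameter l must be >= 1, got {l!r}")
    if n <= l:
        raise ValueError(f"node count n must exceed l, got n={n!r}, l={l!r}")
    graph = nx.barabasi_albert_graph(n, l, seed=rng, initial_graph=nx.star_graph(l))
    return ObservationNetwork(graph=graph, l=l)


def adoption_fraction(net: ObservationNetwork, states, i: int) -> float:
    """Fraction q_i of i's neighbors currently adopting, in [0, 1].

    Returns 0 for an isolated node (its neighborhood offers no evidence, so
    it adopts only if its cognition level is exactly 1).
    """
    if i not in net.graph:
        raise KeyError(f"unknown node id {i!r}")
    w = np.asarray(getattr(states, "w", states))
    neighbors = list(net.graph.adj[i])
    if not neighbors:
        return 0.0
    return float(sum(int(w[j]) for j in neighbors) / len(neighbors))


def write_edgelist(net: ObservationNetwork, path: str | Path) -> None:
    """Write whitespace-separated 0-based integer pairs, one edge per line."""
    with open(path, "w") as fh:
        for u, v in sorted(net.graph.edges()):
            fh.write(f"{u} {v}\n")


def read_edgelist(path: str | Path) -> ObservationNetwork:
    """Read an edge list written by :func:`write_edgelist`.

    Node ids must be 0-based contiguous integers; isolated nodes cannot be
    expressed in this format.
    """
    graph = nx.read_edgelist(path, nodetype=int)
    return ObservationNetwork(graph=nx.Graph(graph))
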