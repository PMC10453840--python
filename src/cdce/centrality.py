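"""Clique-sum edge weights, link strength, and node centralities.

The chain of quantities, all local:

* ``omega(u, v)`` — the sum of the sizes of the maximal cliques containing
  both endpoints of edge (u, v).  An edge inside one triangle gets 3; an
  edge shared by two triangles gets 6; a bridge in no counted clique
  gets 0.
* link strength ``W(u, v) = 1 + omega(u, v)`` on every edge — a local
  similarity index, never below 1 so that any edge still beats a
  non-edge.
* density-based entropy centrality ``CE(v)``: Shannon entropy of the
  normalised link strengths from v to its neighbours.  High when v sits
  at the centre of a dense subgraph with many comparably strong ties;
  0 for leaves and isolated nodes.
* clique centrality ``CC(v)``: the plain sum of v's incident link
  strengths (a weighted degree).
* degree centrality ``deg(v) / (n - 1)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from cdce.cliques import DEFAULT_MIN_SIZE, Clique, enumerate_maximal_cliques
from cdce.graph_io import node_index

DEFAULT_LOG_BASE = 10.0

EdgeKey = tuple[int, int]


def _key(i: int, j: int) -> EdgeKey:
    return (i, j) if i < j else (j, i)


@dataclass
class LinkStrengthMap:
    """Symmetric per-edge weights: clique-sum ``omega`` and link strength
    ``W = 1 + omega``, keyed by ordered index pairs (i < j)."""

    nodes: list[Hashable]
    omega: dict[EdgeKey, int] = field(default_factory=dict)
    strength: dict[EdgeKey, float] = field(default_factory=dict)

    def w(self, i: int, j: int) -> float:
        """Link strength between node indices *i* and *j* (0 if non-edge)."""
        return self.strength.get(_key(i, j), 0.0)

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {
                "u": self.nodes[i],
                "v": self.nodes[j],
                "omega": self.omega.get((i, j), 0),
                "strength": w,
            }
            for (i, j), w in sorted(self.strength.items())
        ]
        return pd.DataFrame(rows, columns=["u", "v", "omega", "strength"])


@dataclass
class CentralityScores:
    """Per-node centrality values, index-aligned with ``nodes``."""

    nodes: list[Hashable]
    ce: np.ndarray
    cc: np.ndarray
    degree: np.ndarray

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node": self.nodes,
                "degree_centrality": self.degree,
                "clique_centrality": self.cc,
                "entropy_centrality": self.ce,
            }
        )

    def by_node(self, kind: str = "ce") -> dict[Hashable, float]:
        values = getattr(self, kind)
        return {node: float(values[i]) for i, node in enumerate(self.nodes)}


def clique_edge_weights(
    graph: nx.Graph, cliques: Sequence[Clique]
) -> dict[EdgeKey, int]:
    """Accumulate omega: for each edge, the sum of sizes of the counted
    maximal cliques containing both endpoints.

    Raises ``ValueError`` if a clique references a node index outside the
    graph (enumeration/graph mismatch).
    """
    n = graph.number_of_nodes()
    omega: dict[EdgeKey, int] = {}
    for clique in cliques:
        size = len(clique)
        for a, i in enumerate(clique):
            if not 0 <= i < n:
                raise ValueError(f"clique {clique} references node index {i} "
                                 f"outside a {n}-node graph")
            for j in clique[a + 1:]:
                key = _key(i, j)
                omega[key] = omega.get(key, 0) + size
    return omega


def link_strength(
    graph: nx.Graph, omega: Mapping[EdgeKey, int]
) -> LinkStrengthMap:
    """Attach ``W = 1 + omega`` to every edge of *graph*.

    Edges in no counted clique get strength exactly 1, still above the
    0 of a non-edge.
    """
    index = node_index(graph)
    strengths: dict[EdgeKey, float] = {}
    for u, v in graph.edges():
        key = _key(index[u], index[v])
        strengths[key] = 1.0 + omega.get(key, 0)
    return LinkStrengthMap(
        nodes=list(graph.nodes()), omega=dict(omega), strength=strengths
    )


def entropy_centrality(
    graph: nx.Graph,
    strengths: LinkStrengthMap,
    log_base: float = DEFAULT_LOG_BASE,
) -> np.ndarray:
    """Density-based entropy centrality per node (index order).

    For node v with neighbours v_1..v_d, the incident strengths are
    normalised to a distribution p_i = W(v, v_i) / sum_j W(v, v_j) and
    CE(v) = -sum_i p_i log_b p_i.  CE is 0 for degree <= 1 and bounded
    above by log_b(deg v), attained when all incident strengths are
    equal.
    """
    if log_base <= 1:
        raise ValueError(f"log_base must exceed 1, got {log_base}")
    index = node_index(graph)
    ce = np.zeros(graph.number_of_nodes())
    log_b = math.log(log_base)
    for v in graph.nodes():
        i = index[v]
        ws = [strengths.w(i, index[u]) for u in graph.neighbors(v)]
        if len(ws) <= 1:
            continue
        total = math.fsum(ws)
        ce[i] = -math.fsum(
            (w / total) * (math.log(w / total) / log_b) for w in ws
        )
    return ce


def clique_centrality(graph: nx.Graph, strengths: LinkStrengthMap) -> np.ndarray:
    """Sum of incident link strengths per node (index order)."""
    index = node_index(graph)
    cc = np.zeros(graph.number_of_nodes())
    for v in graph.nodes():
        i = index[v]
        cc[i] = math.fsum(strengths.w(i, index[u]) for u in graph.neighbors(v))
    return cc


def degree_centrality(graph: nx.Graph) -> np.ndarray:
    """deg(v) / (n - 1) per node (index order); needs n >= 2."""
    n = graph.number_of_nodes()
    if n < 2:
        raise ValueError(f"degree centrality needs >= 2 nodes, got {n}")
    return np.array([d for _, d in graph.degree()], dtype=float) / (n - 1)


def compute_centralities(
    graph: nx.Graph,
    min_size: int = DEFAULT_MIN_SIZE,
    log_base: float = DEFAULT_LOG_BASE,
) -> tuple[LinkStrengthMap, CentralityScores]:
    """Run the full chain cliques -> omega -> W -> (CE, CC, degree)."""
    cliques = enumerate_maximal_cliques(graph, min_size=min_size)
    omega = clique_edge_weights(graph, cliques)
    strengths = link_strength(graph, omega)
    n = graph.number_of_nodes()
    scores = CentralityScores(
        nodes=list(graph.nodes()),
        ce=entropy_centrality(graph, strengths, log_base=log_base),
        cc=clique_centrality(graph, strengths),
        degree=(
            degree_centrality(graph) if n >= 2 else np.zeros(n)
        ),
    )
    return strengths, scores
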