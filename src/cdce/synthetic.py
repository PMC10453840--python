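"""Synthetic graphs with planted community structure.

Two generator families cover the regimes the detector is meant for:

* planted-partition graphs — equal-sized communities, dense inside
  (``p_in``), sparse between (``p_out``); the stochastic test bed for
  recovery experiments;
* rings of cliques — perfectly clean communities joined by single
  bridge edges; the deterministic sanity case where the correct answer
  is unambiguous.

Both are bit-reproducible from an integer seed (NumPy ``default_rng``).
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import networkx as nx
import numpy as np

from cdce.graph_io import Partition

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PlantedPartitionSpec:
    """Parameters of a planted-partition (equal-block SBM) graph."""

    n_communities: int = 8
    community_size: int = 16
    p_in: float = 0.3
    p_out: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_communities < 2:
            raise ValueError("need at least 2 communities")
        if self.community_size < 3:
            raise ValueError("communities need at least 3 nodes")
        if not (0 <= self.p_out <= self.p_in <= 1):
            raise ValueError("require 0 <= p_out <= p_in <= 1")

    @property
    def n_nodes(self) -> int:
        return self.n_communities * self.community_size


def generate_planted_partition(
    spec: PlantedPartitionSpec,
) -> tuple[nx.Graph, Partition]:
    """Sample a planted-partition graph and its ground-truth labels.

    Each intra-community pair is an edge with probability ``p_in``,
    each inter-community pair with ``p_out``.  Nodes left isolated by
    the sampling are re-wired to one random same-community neighbour so
    every planted community stays connected to itself.
    """
    n = spec.n_nodes
    labels = np.repeat(np.arange(spec.n_communities), spec.community_size)
    expected_degree = (
        spec.p_in * (spec.community_size - 1)
        + spec.p_out * (n - spec.community_size)
    )
    if expected_degree < 1:
        logger.warning(
            "expected degree %.2f < 1; graph will be mostly isolated nodes",
            expected_degree,
        )
    rng = np.random.default_rng(spec.seed)
    graph = nx.empty_graph(n)
    iu, ju = np.triu_indices(n, k=1)
    same = labels[iu] == labels[ju]
    probs = np.where(same, spec.p_in, spec.p_out)
    mask = rng.random(len(iu)) < probs
    graph.add_edges_from(zip(iu[mask].tolist(), ju[mask].tolist()))
    for v in range(n):
        if graph.degree(v) == 0:
            mates = [u for u in range(n) if labels[u] == labels[v] and u != v]
            graph.add_edge(v, int(rng.choice(mates)))
    truth = Partition({v: int(labels[v]) for v in range(n)})
    return graph, truth


def generate_ring_of_cliques(
    n_cliques: int, clique_size: int
) -> tuple[nx.Graph, Partition]:
    """A ring of ``n_cliques`` complete graphs of ``clique_size`` nodes.

    Clique i's node 0 is joined to clique (i+1 mod n)'s node 1, so each
    bridge edge lies in no triangle and the planted communities are
    exactly the cliques.
    """
    if n_cliques < 3:
        raise ValueError("need at least 3 cliques to form a ring")
    if clique_size < 3:
        raise ValueError("cliques need at least 3 nodes")
    graph = nx.Graph()
    assignment = {}
    for c in range(n_cliques):
        base = c * clique_size
        members = range(base, base + clique_size)
        graph.add_edges_from(
            (u, v) for u in members for v in members if u < v
        )
        for v in members:
            assignment[v] = c
    for c in range(n_cliques):
        u = c * clique_size  # node 0 of clique c
        v = ((c + 1) % n_cliques) * clique_size + 1  # node 1 of next clique
        graph.add_edge(u, v)
    return graph, Partition(assignment)
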