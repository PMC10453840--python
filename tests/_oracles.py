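"""Independent brute-force oracles used to validate the implementation.

Everything here is written from definitions, deliberately ignoring the
code paths under test: cliques by exhaustive subset enumeration,
modularity by the double loop over node pairs, NMI from the confusion
matrix, entropy centrality from an explicit weight matrix.
"""

from __future__ import annotations

import itertools
import math

import networkx as nx
import numpy as np


def brute_force_maximal_cliques(graph: nx.Graph) -> set[frozenset]:
    """All maximal cliques by testing every vertex subset (n <= ~14)."""
    nodes = list(graph.nodes())
    n = len(nodes)
    adj = {v: set(graph.neighbors(v)) for v in nodes}

    def is_clique(subset):
        return all(v in adj[u] for u, v in itertools.combinations(subset, 2))

    cliques = []
    for r in range(1, n + 1):
        for subset in itertools.combinations(nodes, r):
            if is_clique(subset):
                cliques.append(set(subset))
    maximal = [
        c for c in cliques
        if not any(c < other for other in cliques)
    ]
    return {frozenset(c) for c in maximal}


def brute_force_omega(graph: nx.Graph, min_size: int) -> dict[frozenset, int]:
    """Per-edge clique-size sums from the exhaustive clique set."""
    cliques = [
        c for c in brute_force_maximal_cliques(graph) if len(c) >= min_size
    ]
    omega: dict[frozenset, int] = {}
    for u, v in graph.edges():
        omega[frozenset((u, v))] = sum(
            len(c) for c in cliques if u in c and v in c
        )
    return omega


def strength_matrix(graph: nx.Graph, min_size: int) -> np.ndarray:
    """Dense link-strength matrix W = (1 + omega) * A from the
    exhaustive clique oracle."""
    nodes = list(graph.nodes())
    idx = {v: i for i, v in enumerate(nodes)}
    omega = brute_force_omega(graph, min_size)
    W = np.zeros((len(nodes), len(nodes)))
    for u, v in graph.edges():
        w = 1 + omega[frozenset((u, v))]
        W[idx[u], idx[v]] = W[idx[v], idx[u]] = w
    return W


def entropy_from_matrix(W: np.ndarray, log_base: float) -> np.ndarray:
    """Row-wise entropy of the normalised positive entries of W."""
    out = np.zeros(W.shape[0])
    for i, row in enumerate(W):
        ws = row[row > 0]
        if len(ws) <= 1:
            continue
        p = ws / ws.sum()
        out[i] = -(p * np.log(p) / math.log(log_base)).sum()
    return out


def modularity_double_loop(graph: nx.Graph, assignment: dict) -> float:
    """Q = (1/2m) sum_ij [A_ij - k_i k_j / 2m] delta(c_i, c_j)."""
    nodes = list(graph.nodes())
    m = graph.number_of_edges()
    deg = dict(graph.degree())
    q = 0.0
    for u in nodes:
        for v in nodes:
            if assignment[u] != assignment[v]:
                continue
            a = 1.0 if graph.has_edge(u, v) else 0.0
            q += a - deg[u] * deg[v] / (2 * m)
    return q / (2 * m)


def nmi_direct(labels_a: list[int], labels_b: list[int]) -> float:
    """2 I(A;B) / (H(A) + H(B)) summed straight from confusion counts."""
    n = len(labels_a)
    from collections import Counter

    ca, cb = Counter(labels_a), Counter(labels_b)
    joint = Counter(zip(labels_a, labels_b))
    h_a = -sum(c / n * math.log(c / n) for c in ca.values())
    h_b = -sum(c / n * math.log(c / n) for c in cb.values())
    mi = 0.0
    for (a, b), c in joint.items():
        mi += c / n * math.log(n * c / (ca[a] * cb[b]))
    if h_a + h_b == 0:
        return 1.0
    return 2 * mi / (h_a + h_b)


def f1_best_match(detected: list[set], truth: list[set]) -> float:
    """Symmetric best-match F1 via explicit loops over community pairs."""

    def directional(from_comms, to_comms):
        total = 0.0
        for c in from_comms:
            best = 0.0
            for t in to_comms:
                inter = len(c & t)
                if inter:
                    p, r = inter / len(c), inter / len(t)
                    best = max(best, 2 * p * r / (p + r))
            total += best
        return total / len(from_comms)

    return (directional(detected, truth) + directional(truth, detected)) / 2


def random_graph(rng: np.random.Generator, n: int, p: float) -> nx.Graph:
    """Seeded Erdős–Rényi graph with integer nodes 0..n-1."""
    graph = nx.empty_graph(n)
    for u, v in itertools.combinations(range(n), 2):
        if rng.random() < p:
            graph.add_edge(u, v)
    return graph
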