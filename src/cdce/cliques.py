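"""Maximal clique enumeration.

Enumeration itself is delegated to networkx's pivoting Bron-Kerbosch
implementation; this module adds the canonical ordering and the minimum
clique-size filter the rest of the pipeline relies on.

The ``min_size`` knob decides whether maximal 2-cliques — edges that are
not contained in any triangle — count as cliques when edge weights are
accumulated.  With ``min_size=3`` (the package default) such bridge edges
carry no clique weight and keep link strength 1, which is what gives
entropy centrality its contrast between dense cores and sparse
peripheries.
"""

from __future__ import annotations

from typing import Hashable, Sequence

import networkx as nx

from cdce.graph_io import node_index

Clique = tuple[int, ...]

DEFAULT_MIN_SIZE = 3


def enumerate_maximal_cliques(
    graph: nx.Graph, min_size: int = DEFAULT_MIN_SIZE
) -> list[Clique]:
    """Return all maximal cliques of *graph* with at least *min_size* nodes.

    Cliques are returned as tuples of 0-based node indices (positions in
    ``graph.nodes()`` order), each sorted internally, with the list itself
    sorted lexicographically — a canonical form independent of traversal
    order.

    Parameters
    ----------
    graph:
        Simple undirected graph.
    min_size:
        Smallest clique size to keep; 2 keeps every maximal clique
        (every edge is then covered), 3 discards maximal edges.
    """
    if min_size < 1:
        raise ValueError(f"min_size must be >= 1, got {min_size}")
    index = node_index(graph)
    cliques = [
        tuple(sorted(index[v] for v in clique))
        for clique in nx.find_cliques(graph)
        if len(clique) >= min_size
    ]
    cliques.sort()
    return cliques


def clique_members(
    graph: nx.Graph, cliques: Sequence[Clique]
) -> list[tuple[Hashable, ...]]:
    """Translate index-form cliques back to node labels."""
    nodes = list(graph.nodes())
    return [tuple(nodes[i] for i in clique) for clique in cliques]
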