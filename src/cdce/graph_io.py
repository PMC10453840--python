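"""Graph and partition I/O.

Graphs are held as :class:`networkx.Graph` objects with node labels kept
exactly as read (strings for file input, ints for generators).  Readers
normalise to a simple undirected graph: self-loops are dropped and
duplicate / reciprocal edges collapsed, each with a logged warning, since
every downstream quantity (maximal cliques, link strength, entropy
centrality) is defined on simple graphs only.

Node order is significant: the position of a node in ``G.nodes()``
(insertion order) is its index, used for all deterministic tie-breaking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Iterable, Mapping

import networkx as nx

logger = logging.getLogger(__name__)

Node = Hashable


class ParseError(ValueError):
    """Raised for malformed edge-list or partition files."""


@dataclass
class Partition:
    """A disjoint, total assignment of nodes to integer community ids.

    Parameters
    ----------
    assignment:
        Mapping node -> community id.  Every node of the graph under
        study must appear exactly once.
    """

    assignment: dict[Node, int] = field(default_factory=dict)

    @property
    def communities(self) -> dict[int, set[Node]]:
        """Inverse view: community id -> set of member nodes."""
        out: dict[int, set[Node]] = {}
        for node, cid in self.assignment.items():
            out.setdefault(cid, set()).add(node)
        return out

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values()))

    def __len__(self) -> int:
        return len(self.assignment)

    def __getitem__(self, node: Node) -> int:
        return self.assignment[node]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Partition):
            return NotImplemented
        return self.assignment == other.assignment

    def relabel(self) -> "Partition":
        """Return an equivalent partition with community ids renumbered
        0..k-1 in order of first appearance (canonical form)."""
        mapping: dict[int, int] = {}
        out = {}
        for node, cid in self.assignment.items():
            out[node] = mapping.setdefault(cid, len(mapping))
        return Partition(out)

    def validate(self, graph: nx.Graph) -> None:
        """Check totality against *graph*; raise ``ValueError`` if a graph
        node is missing or a foreign node is present."""
        nodes = set(graph.nodes())
        assigned = set(self.assignment)
        if nodes - assigned:
            raise ValueError(
                f"partition is missing {len(nodes - assigned)} graph node(s), "
                f"e.g. {sorted(map(str, nodes - assigned))[:3]}"
            )
        if assigned - nodes:
            raise ValueError(
                f"partition contains {len(assigned - nodes)} node(s) absent "
                f"from the graph"
            )

    @classmethod
    def from_communities(cls, communities: Iterable[Iterable[Node]]) -> "Partition":
        assignment: dict[Node, int] = {}
        for cid, members in enumerate(communities):
            for node in members:
                if node in assignment:
                    raise ValueError(f"node {node!r} appears in two communities")
                assignment[node] = cid
        return cls(assignment)


def _normalise(graph: nx.Graph, source: str) -> nx.Graph:
    """Drop self-loops (logged); collapsing of duplicate edges is implied
    by nx.Graph set semantics."""
    loops = list(nx.selfloop_edges(graph))
    if loops:
        logger.warning("%s: dropping %d self-loop(s)", source, len(loops))
        graph.remove_edges_from(loops)
    return graph


def read_edgelist(
    path: str | Path,
    comment_prefix: str = "#",
    delimiter: str | None = None,
) -> nx.Graph:
    """Read a whitespace- or *delimiter*-separated edge list.

    Each non-comment line names one edge's two endpoints; extra tokens
    (e.g. weights) are ignored with a warning.  Self-loops are dropped and
    duplicate edges collapsed.  Node labels are preserved as strings.
    """
    path = Path(path)
    graph = nx.Graph()
    extra_tokens = 0
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(comment_prefix):
                continue
            tokens = line.split(delimiter)
            if len(tokens) < 2:
                raise ParseError(
                    f"{path}:{lineno}: expected at least 2 tokens, got {len(tokens)}"
                )
            if len(tokens) > 2:
                extra_tokens += 1
            u, v = tokens[0], tokens[1]
            graph.add_edge(u, v)
    if extra_tokens:
        logger.warning(
            "%s: ignored extra tokens on %d line(s)", path, extra_tokens
        )
    return _normalise(graph, str(path))


def read_gml(path: str | Path) -> nx.Graph:
    """Read a GML file, applying the same normalisation as
    :func:`read_edgelist`.  Directed GML edges are symmetrised with a
    warning."""
    path = Path(path)
    try:
        graph = nx.read_gml(path, label="label")
    except Exception as exc:  # nx raises NetworkXError / ParseError subtypes
        raise ParseError(f"{path}: malformed GML ({exc})") from exc
    if graph.is_directed():
        logger.warning("%s: directed GML symmetrised to undirected", path)
        graph = graph.to_undirected()
    if graph.is_multigraph():
        logger.warning("%s: parallel GML edges collapsed", path)
        graph = nx.Graph(graph)
    return _normalise(graph, str(path))


def write_edgelist(graph: nx.Graph, path: str | Path) -> None:
    """Write one ``u<TAB>v`` line per edge, in graph edge order."""
    path = Path(path)
    with path.open("w") as fh:
        for u, v in graph.edges():
            fh.write(f"{u}\t{v}\n")


def write_partition(partition: Partition | Mapping[Node, int], path: str | Path) -> None:
    """Write a two-column TSV ``node<TAB>community_id`` in input order."""
    assignment = (
        partition.assignment if isinstance(partition, Partition) else partition
    )
    path = Path(path)
    with path.open("w") as fh:
        for node, cid in assignment.items():
            fh.write(f"{node}\t{cid}\n")
    if not assignment:
        logger.warning("%s: wrote empty partition", path)


def read_partition(path: str | Path) -> Partition:
    """Read the TSV written by :func:`write_partition` (round-trip)."""
    path = Path(path)
    assignment: dict[Node, int] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split("\t")
            if len(tokens) != 2:
                raise ParseError(
                    f"{path}:{lineno}: expected 'node<TAB>community', got {raw!r}"
                )
            assignment[tokens[0]] = int(tokens[1])
    return Partition(assignment)


def node_index(graph: nx.Graph) -> dict[Node, int]:
    """Dense 0-based index of each node in insertion order.

    This ordering underpins every deterministic tie-break in the
    pipeline, so it must be identical across runs on the same input.
    """
    return {node: i for i, node in enumerate(graph.nodes())}
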