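"""Benchmark graph access.

The Zachary karate club graph ships with networkx and is exposed here
with the conventional 1-based member labels.  The other published
benchmarks (dolphins, polbooks, football, jazz, polblogs) are not
redistributed; :func:`load_external` reads them from a local directory
of downloaded GML / edge-list files.
"""

from __future__ import annotations

from pathlib import Path

import networkx as nx

from cdce import graph_io

#: expected (nodes, edges) of the published benchmark graphs
BENCHMARK_SIZES = {
    "karate": (34, 78),
    "dolphins": (62, 159),
    "polbooks": (105, 441),
    "football": (115, 613),
    "jazz": (198, 2742),
    "polblogs": (1490, 19062),
}


def karate_club() -> nx.Graph:
    """Zachary's karate club (34 members, 78 ties), nodes labeled 1-34."""
    return nx.relabel_nodes(nx.karate_club_graph(), lambda v: v + 1)


def load_external(name: str, data_dir: str | Path = "data/external") -> nx.Graph:
    """Load a downloaded benchmark graph from *data_dir*.

    Looks for ``<name>.gml``, ``<name>.edgelist`` or ``<name>.net`` and
    raises ``FileNotFoundError`` with a hint when absent.
    """
    data_dir = Path(data_dir)
    for suffix, reader in ((".gml", graph_io.read_gml),
                           (".edgelist", graph_io.read_edgelist),
                           (".txt", graph_io.read_edgelist)):
        path = data_dir / f"{name}{suffix}"
        if path.exists():
            return reader(path)
    raise FileNotFoundError(
        f"benchmark '{name}' not found under {data_dir}/ — download the "
        f"published GML/edge-list file and place it there"
    )
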