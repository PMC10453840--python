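"""The CDCE community-detection pipeline.

Three stages, all deterministic:

1. **Seed detection** — nodes whose entropy centrality dominates their
   neighbourhood are seeds.  A node that is locally dominated still
   qualifies if it is the strict strongest link of the dominating
   neighbour.
2. **Core formation** — each seed pulls in its strongest-linked
   neighbour and every neighbour whose link strength exceeds a fraction
   (default 0.9) of that maximum.  Core labels are frozen.
3. **Label propagation** — unlabeled nodes, visited in decreasing
   centrality order, adopt the community with the largest summed link
   strength among their labeled neighbours; after everything is
   labeled, stabilisation sweeps run until no non-core label changes.

All tie-breaks (processing order, strongest link, label adoption) fall
back to the smallest node index / community id, so repeated runs on the
same input give identical partitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Hashable, Literal

import networkx as nx
import numpy as np

from cdce.centrality import (
    DEFAULT_LOG_BASE,
    CentralityScores,
    LinkStrengthMap,
    compute_centralities,
)
from cdce.cliques import DEFAULT_MIN_SIZE
from cdce.graph_io import Partition, node_index

logger = logging.getLogger(__name__)

UNASSIGNED = -1

DEFAULT_CORE_THRESHOLD = 0.9
DEFAULT_MAX_ITER = 100

SeedCentrality = Literal["entropy", "clique", "degree"]


@dataclass
class CommunityAssignment:
    """Working state of the pipeline: per-index community id (or
    ``UNASSIGNED``), plus seed and core flags."""

    nodes: list[Hashable]
    comm_no: np.ndarray  # int, UNASSIGNED where unlabeled
    is_seed: np.ndarray  # bool
    is_core: np.ndarray  # bool

    @classmethod
    def empty(cls, graph: nx.Graph) -> "CommunityAssignment":
        n = graph.number_of_nodes()
        return cls(
            nodes=list(graph.nodes()),
            comm_no=np.full(n, UNASSIGNED, dtype=int),
            is_seed=np.zeros(n, dtype=bool),
            is_core=np.zeros(n, dtype=bool),
        )

    @property
    def n_seeds(self) -> int:
        return int(self.is_seed.sum())

    @property
    def n_cores(self) -> int:
        return int(self.is_core.sum())

    def to_partition(self) -> Partition:
        if (self.comm_no == UNASSIGNED).any():
            raise ValueError("assignment is not total; run propagation first")
        return Partition(
            {node: int(self.comm_no[i]) for i, node in enumerate(self.nodes)}
        ).relabel()


def _adjacency(graph: nx.Graph) -> list[list[int]]:
    index = node_index(graph)
    adj: list[list[int]] = [[] for _ in range(graph.number_of_nodes())]
    for v in graph.nodes():
        adj[index[v]] = sorted(index[u] for u in graph.neighbors(v))
    return adj


def _processing_order(values: np.ndarray) -> list[int]:
    """Decreasing value, ties by ascending index."""
    return sorted(range(len(values)), key=lambda i: (-values[i], i))


def detect_seeds_and_cores(
    graph: nx.Graph,
    scores: np.ndarray,
    strengths: LinkStrengthMap,
    core_threshold: float = DEFAULT_CORE_THRESHOLD,
    seeds_only: bool = False,
) -> CommunityAssignment:
    """Seed and core detection.

    Nodes are processed in decreasing *scores* order (ties: ascending
    index).  Node v qualifies as a seed iff every neighbour v_i either
    has no higher score, or v is v_i's strict strongest link.  A
    qualifying v founds (or joins, see below) a community: its
    strongest-linked neighbour maxSim is absorbed if still unlabeled,
    otherwise v adopts maxSim's community; finally every neighbour
    within ``core_threshold`` of the maximal incident strength is
    absorbed as core.  With ``seeds_only`` the absorption steps are
    skipped and each seed keeps a singleton community.
    """
    if not 0 < core_threshold <= 1:
        raise ValueError(f"core_threshold must lie in (0, 1], got {core_threshold}")
    n = graph.number_of_nodes()
    if len(scores) != n:
        raise ValueError("scores length does not match graph size")
    assignment = CommunityAssignment.empty(graph)
    adj = _adjacency(graph)
    if graph.number_of_edges() == 0:
        logger.warning("graph has no edges; every node is its own seed")
    comm, seed, core = assignment.comm_no, assignment.is_seed, assignment.is_core

    # top-two incident strengths per node, for the strict-strongest-link test
    top2 = []
    for i in range(n):
        ws = sorted((strengths.w(i, j) for j in adj[i]), reverse=True)
        top2.append((ws[0] if ws else 0.0, ws[1] if len(ws) > 1 else -np.inf))

    def is_strict_strongest_link(vi: int, v: int) -> bool:
        w = strengths.w(vi, v)
        t1, t2 = top2[vi]
        return w == t1 and t1 > t2

    for v in _processing_order(scores):
        qualifies = all(
            scores[v] >= scores[vi] or is_strict_strongest_link(vi, v)
            for vi in adj[v]
        )
        if not qualifies:
            continue
        seed[v] = True
        core[v] = True
        comm[v] = v
        if not adj[v]:
            continue
        # strongest-linked neighbour; ties broken by ascending index
        max_sim = max(adj[v], key=lambda u: (strengths.w(v, u), -u))
        max_link_strength = strengths.w(v, max_sim)
        if comm[max_sim] == UNASSIGNED:
            if not seeds_only:
                core[max_sim] = True
                comm[max_sim] = comm[v]
        else:
            # adjacent seeds merge through their strongest link even in
            # the seeds-only ablation; only neighbour absorption is the
            # core-detection step being ablated
            comm[v] = comm[max_sim]
        if seeds_only:
            continue
        for vi in adj[v]:
            if strengths.w(v, vi) > core_threshold * max_link_strength:
                core[vi] = True
                comm[vi] = comm[v]
    return assignment


def propagate_labels(
    graph: nx.Graph,
    assignment: CommunityAssignment,
    strengths: LinkStrengthMap,
    scores: np.ndarray,
    max_iter: int = DEFAULT_MAX_ITER,
) -> Partition:
    """Strength-weighted label propagation from the detected cores.

    Unlabeled nodes are swept in decreasing *scores* order; each adopts
    the community maximising the sum of link strengths to its labeled
    neighbours (ties: smallest community id).  Sweeps repeat until total;
    stabilisation sweeps over non-core nodes then run until a fixed
    point or *max_iter*.  Core labels are never overwritten.  Components
    containing no core get their lowest-index node promoted to a
    singleton seed first.
    """
    if max_iter < 1:
        raise ValueError(f"max_iter must be >= 1, got {max_iter}")
    n = graph.number_of_nodes()
    adj = _adjacency(graph)
    comm = assignment.comm_no
    core = assignment.is_core
    index = node_index(graph)

    for component in nx.connected_components(graph):
        idxs = [index[v] for v in component]
        if all(comm[i] == UNASSIGNED for i in idxs):
            root = min(idxs)
            comm[root] = root
            assignment.is_seed[root] = True
            core[root] = True

    order = _processing_order(scores)

    def best_label(v: int) -> int | None:
        votes: dict[int, float] = {}
        for u in adj[v]:
            label = comm[u]
            if label == UNASSIGNED:
                continue
            votes[label] = votes.get(label, 0.0) + strengths.w(v, u)
        if not votes:
            return None
        best = max(votes.values())
        return min(label for label, w in votes.items() if w == best)

    iterations = 0
    while (comm == UNASSIGNED).any():
        iterations += 1
        progressed = False
        for v in order:
            if comm[v] != UNASSIGNED:
                continue
            label = best_label(v)
            if label is not None:
                comm[v] = label
                progressed = True
        if not progressed:  # pragma: no cover - unreachable after seeding
            raise RuntimeError("label propagation stalled with unlabeled nodes")

    converged = False
    while iterations < max_iter:
        iterations += 1
        changed = False
        for v in order:
            if core[v]:
                continue
            label = best_label(v)
            if label is not None and label != comm[v]:
                comm[v] = label
                changed = True
        if not changed:
            converged = True
            break
    if not converged:
        logger.warning(
            "label propagation did not stabilise within %d sweeps", max_iter
        )
    return assignment.to_partition()


def run_cdce(
    graph: nx.Graph,
    min_size: int = DEFAULT_MIN_SIZE,
    log_base: float = DEFAULT_LOG_BASE,
    core_threshold: float = DEFAULT_CORE_THRESHOLD,
    max_iter: int = DEFAULT_MAX_ITER,
    seeds_only: bool = False,
    seed_centrality: SeedCentrality = "entropy",
) -> tuple[Partition, CentralityScores, CommunityAssignment, LinkStrengthMap]:
    """Execute the full pipeline on *graph*.

    ``seed_centrality`` selects which per-node score drives seed
    detection and propagation order: density-based entropy centrality
    (default), clique centrality, or degree centrality — the latter two
    exist for ablation comparisons.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    strengths, scores = compute_centralities(
        graph, min_size=min_size, log_base=log_base
    )
    seed_scores = {
        "entropy": scores.ce,
        "clique": scores.cc,
        "degree": scores.degree,
    }[seed_centrality]
    assignment = detect_seeds_and_cores(
        graph,
        seed_scores,
        strengths,
        core_threshold=core_threshold,
        seeds_only=seeds_only,
    )
    partition = propagate_labels(
        graph, assignment, strengths, seed_scores, max_iter=max_iter
    )
    return partition, scores, assignment, strengths
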