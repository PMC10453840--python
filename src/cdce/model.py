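"""Model/Results interface over the CDCE pipeline.

``CDCE`` holds a graph plus the pipeline configuration; ``fit()``
executes clique enumeration, link-strength weighting, centrality
computation, seed/core detection and label propagation, and returns a
``CDCEResults`` carrying the partition, the per-node scores and the
diagnostics, with a ``summary()`` table in the usual fitted-model style.
"""

from __future__ import annotations

from functools import cached_property
from typing import Hashable

import networkx as nx
import pandas as pd

from cdce import graph_io
from cdce.algorithm import (
    DEFAULT_CORE_THRESHOLD,
    DEFAULT_MAX_ITER,
    SeedCentrality,
    run_cdce,
)
from cdce.centrality import DEFAULT_LOG_BASE, CentralityScores, LinkStrengthMap
from cdce.cliques import DEFAULT_MIN_SIZE
from cdce.evaluation import QualityReport, evaluate, modularity
from cdce.graph_io import Partition


class CDCE:
    """Community detection by density-based entropy centrality.

    Parameters
    ----------
    graph:
        Simple undirected graph (``networkx.Graph``).
    min_clique_size:
        Smallest maximal-clique size contributing to edge weights; 3
        excludes bridge edges from clique weight (default), 2 counts
        every maximal edge.
    log_base:
        Base of the entropy logarithm (default 10).
    core_threshold:
        Fraction of the maximal incident link strength a neighbour must
        exceed to join a seed's core (default 0.9).
    max_iter:
        Cap on propagation/stabilisation sweeps.
    seeds_only:
        Skip core formation; seeds alone anchor propagation (ablation).
    seed_centrality:
        Score driving seed detection and propagation order:
        ``"entropy"`` (default), ``"clique"`` or ``"degree"``.
    """

    def __init__(
        self,
        graph: nx.Graph,
        min_clique_size: int = DEFAULT_MIN_SIZE,
        log_base: float = DEFAULT_LOG_BASE,
        core_threshold: float = DEFAULT_CORE_THRESHOLD,
        max_iter: int = DEFAULT_MAX_ITER,
        seeds_only: bool = False,
        seed_centrality: SeedCentrality = "entropy",
    ) -> None:
        if graph.number_of_nodes() == 0:
            raise ValueError("graph is empty")
        self.graph = graph
        self.min_clique_size = min_clique_size
        self.log_base = log_base
        self.core_threshold = core_threshold
        self.max_iter = max_iter
        self.seeds_only = seeds_only
        self.seed_centrality = seed_centrality

    @classmethod
    def from_edgelist(cls, path, **kwargs) -> "CDCE":
        return cls(graph_io.read_edgelist(path), **kwargs)

    @classmethod
    def from_gml(cls, path, **kwargs) -> "CDCE":
        return cls(graph_io.read_gml(path), **kwargs)

    @property
    def config(self) -> dict:
        return {
            "min_clique_size": self.min_clique_size,
            "log_base": self.log_base,
            "core_threshold": self.core_threshold,
            "max_iter": self.max_iter,
            "seeds_only": self.seeds_only,
            "seed_centrality": self.seed_centrality,
        }

    def fit(self) -> "CDCEResults":
        partition, scores, assignment, strengths = run_cdce(
            self.graph,
            min_size=self.min_clique_size,
            log_base=self.log_base,
            core_threshold=self.core_threshold,
            max_iter=self.max_iter,
            seeds_only=self.seeds_only,
            seed_centrality=self.seed_centrality,
        )
        return CDCEResults(self, partition, scores, assignment, strengths)


class CDCEResults:
    """Fitted partition plus per-node scores and diagnostics."""

    def __init__(self, model, partition, scores, assignment, strengths):
        self.model: CDCE = model
        self.partition: Partition = partition
        self.centrality: CentralityScores = scores
        self.assignment = assignment
        self.strengths: LinkStrengthMap = strengths

    @property
    def graph(self) -> nx.Graph:
        return self.model.graph

    @property
    def n_communities(self) -> int:
        return self.partition.n_communities

    @property
    def seeds(self) -> list[Hashable]:
        return [
            node
            for i, node in enumerate(self.assignment.nodes)
            if self.assignment.is_seed[i]
        ]

    @property
    def cores(self) -> list[Hashable]:
        return [
            node
            for i, node in enumerate(self.assignment.nodes)
            if self.assignment.is_core[i]
        ]

    @cached_property
    def modularity(self) -> float:
        return modularity(self.graph, self.partition)

    def evaluate(self, ground_truth: Partition | None = None) -> QualityReport:
        return evaluate(self.graph, self.partition, ground_truth)

    def to_frame(self) -> pd.DataFrame:
        """Per-node table: community id, seed/core flags, centralities."""
        frame = self.centrality.as_frame()
        frame["community"] = [
            self.partition[node] for node in self.centrality.nodes
        ]
        frame["is_seed"] = self.assignment.is_seed
        frame["is_core"] = self.assignment.is_core
        return frame

    def save_partition(self, path) -> None:
        graph_io.write_partition(self.partition, path)

    def summary(self) -> str:
        g = self.graph
        sizes = sorted(
            (len(m) for m in self.partition.communities.values()), reverse=True
        )
        top = self.to_frame().nlargest(5, "entropy_centrality")
        lines = [
            "CDCE community detection results",
            "=" * 48,
            f"Nodes:                {g.number_of_nodes()}",
            f"Edges:                {g.number_of_edges()}",
            f"Seed centrality:      {self.model.seed_centrality}",
            f"Min clique size:      {self.model.min_clique_size}",
            f"Entropy log base:     {self.model.log_base:g}",
            f"Core threshold:       {self.model.core_threshold:g}",
            f"Seeds / cores:        {self.assignment.n_seeds} / "
            f"{self.assignment.n_cores}",
            f"Communities:          {self.n_communities}",
            f"Community sizes:      {sizes}",
            f"Modularity Q:         {self.modularity:.3f}",
            "-" * 48,
            "Top nodes by entropy centrality:",
        ]
        for _, row in top.iterrows():
            lines.append(
                f"  {row['node']!s:>6}  CE={row['entropy_centrality']:.4f}  "
                f"CC={row['clique_centrality']:g}  community={row['community']}"
            )
        return "\n".join(lines)
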