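"""Partition-quality metrics: modularity Q, NMI, and best-match F1.

Modularity is always computed on the original unweighted graph — link
strengths play no role here — so values are comparable with those
reported for modularity-based and propagation-based baselines.

NMI uses the arithmetic-mean normalisation
``2 I(A;B) / (H(A) + H(B))``; F1 is the symmetric mean of the two
directional best-match averages (each detected community scored against
its best-overlapping truth community, and vice versa), with both
directional values exposed for transparency.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import networkx as nx
from sklearn.metrics import normalized_mutual_info_score

from cdce.graph_io import Partition


@dataclass
class QualityReport:
    """Bundle of quality metrics for one detected partition."""

    modularity: float
    n_communities: int
    nmi: float | None = None
    f1: float | None = None
    f1_detected_to_truth: float | None = None
    f1_truth_to_detected: float | None = None

    def as_dict(self) -> dict:
        return {k: v for k, v in asdict(self).items() if v is not None}


def modularity(graph: nx.Graph, partition: Partition) -> float:
    """Newman-Girvan modularity of *partition* on the unweighted *graph*.

    Q = sum_c [ e_c/m - (d_c / 2m)^2 ] with e_c the intra-community edge
    count and d_c the total degree of community c.
    """
    if graph.number_of_edges() < 1:
        raise ValueError("modularity is undefined on an edgeless graph")
    partition.validate(graph)
    communities = list(partition.communities.values())
    return float(nx.community.modularity(graph, communities, weight=None))


def _aligned_labels(a: Partition, b: Partition) -> tuple[list[int], list[int]]:
    if set(a.assignment) != set(b.assignment):
        raise ValueError("partitions cover different node sets")
    nodes = list(a.assignment)
    return [a[v] for v in nodes], [b[v] for v in nodes]


def nmi(partition_a: Partition, partition_b: Partition) -> float:
    """Normalized mutual information, arithmetic-mean normalisation.

    1 for identical partitions (up to relabeling); 0 when either side
    carries no information about the other.
    """
    la, lb = _aligned_labels(partition_a, partition_b)
    return float(normalized_mutual_info_score(la, lb, average_method="arithmetic"))


def _directional_f1(detected: Partition, truth: Partition) -> float:
    """Mean over detected communities of the best node-overlap F1
    against any truth community."""
    truth_comms = list(truth.communities.values())
    scores = []
    for comm in detected.communities.values():
        best = 0.0
        for t in truth_comms:
            overlap = len(comm & t)
            if overlap == 0:
                continue
            precision = overlap / len(comm)
            recall = overlap / len(t)
            best = max(best, 2 * precision * recall / (precision + recall))
        scores.append(best)
    return sum(scores) / len(scores)


def f1_score(
    partition: Partition, ground_truth: Partition, return_directional: bool = False
) -> float | tuple[float, float, float]:
    """Symmetric best-match F1 between a detected partition and ground
    truth: the mean of the detected->truth and truth->detected
    directional averages."""
    if not partition.assignment or not ground_truth.assignment:
        raise ValueError("cannot score an empty partition")
    _aligned_labels(partition, ground_truth)  # node-set check
    d2t = _directional_f1(partition, ground_truth)
    t2d = _directional_f1(ground_truth, partition)
    score = (d2t + t2d) / 2
    if return_directional:
        return score, d2t, t2d
    return score


def evaluate(
    graph: nx.Graph, partition: Partition, ground_truth: Partition | None = None
) -> QualityReport:
    """Compute all applicable metrics for *partition* on *graph*."""
    report = QualityReport(
        modularity=modularity(graph, partition),
        n_communities=partition.n_communities,
    )
    if ground_truth is not None:
        report.nmi = nmi(partition, ground_truth)
        score, d2t, t2d = f1_score(partition, ground_truth, return_directional=True)
        report.f1 = score
        report.f1_detected_to_truth = d2t
        report.f1_truth_to_detected = t2d
    return report
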