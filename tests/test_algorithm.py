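import networkx as nx
import numpy as np
import pytest

from cdce import algorithm
from cdce.algorithm import (
    UNASSIGNED,
    CommunityAssignment,
    detect_seeds_and_cores,
    propagate_labels,
    run_cdce,
)
from cdce.centrality import compute_centralities
from cdce.evaluation import nmi

from _oracles import random_graph


def stages(graph, min_size=3):
    strengths, scores = compute_centralities(graph, min_size=min_size)
    return strengths, scores


class TestSeedAndCoreDetection:
    def test_star_center_is_unique_seed_with_full_core(self):
        """Star, 2-cliques counted: every spoke has W=3; the centre
        dominates and absorbs all leaves (3 > 0.9 * 3)."""
        g = nx.star_graph(3)
        strengths, scores = stages(g, min_size=2)
        assignment = detect_seeds_and_cores(g, scores.ce, strengths)
        assert assignment.is_seed.tolist() == [True, False, False, False]
        assert assignment.is_core.all()
        assert len(set(assignment.comm_no.tolist())) == 1

    def test_two_cliques_with_bridge_give_two_full_cores(self):
        """Two K4s joined by a bridge: one seed per clique, each core
        covering its whole clique."""
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        g.add_edge(0, 4)
        strengths, scores = stages(g)
        assignment = detect_seeds_and_cores(g, scores.ce, strengths)
        assert assignment.n_seeds == 2
        assert assignment.is_core.all()
        comms = assignment.comm_no
        assert len(set(comms[:4])) == 1 and len(set(comms[4:])) == 1
        assert comms[0] != comms[4]

    def test_complete_graph_ties_collapse_to_one_community(self):
        """All-equal CE: every node qualifies, but maxSim adoption under
        the first-claim tie rule funnels everyone into one community."""
        g = nx.complete_graph(4)
        strengths, scores = stages(g)
        assignment = detect_seeds_and_cores(g, scores.ce, strengths)
        assert assignment.n_seeds == 4
        assert len(set(assignment.comm_no.tolist())) == 1

    def test_edgeless_graph_every_node_own_seed(self, caplog):
        g = nx.empty_graph(4)
        strengths, scores = stages(g)
        with caplog.at_level("WARNING"):
            assignment = detect_seeds_and_cores(g, scores.ce, strengths)
        assert assignment.is_seed.all()
        assert sorted(assignment.comm_no.tolist()) == [0, 1, 2, 3]

    def test_invalid_threshold(self):
        g = nx.complete_graph(3)
        strengths, scores = stages(g)
        with pytest.raises(ValueError):
            detect_seeds_and_cores(g, scores.ce, strengths, core_threshold=0)

    def test_every_seed_is_core_and_assigned(self):
        rng = np.random.default_rng(11)
        g = random_graph(rng, n=25, p=0.2)
        strengths, scores = stages(g)
        a = detect_seeds_and_cores(g, scores.ce, strengths)
        assert (a.is_core[a.is_seed]).all()
        assert (a.comm_no[a.is_core] != UNASSIGNED).all()


class TestPropagation:
    def test_fully_labeled_stable_input_is_fixed_point(self):
        g = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
        g.add_edge(0, 3)
        strengths, scores = stages(g)
        assignment = CommunityAssignment.empty(g)
        assignment.comm_no[:] = [0, 0, 0, 1, 1, 1]
        partition = propagate_labels(g, assignment, strengths, scores.ce)
        labels = [partition[v] for v in g.nodes()]
        assert labels == [0, 0, 0, 1, 1, 1]

    def test_barbell_nodes_join_their_own_clique(self):
        g = nx.barbell_graph(5, 0)
        partition, *_ = run_cdce(g)
        left = {partition[v] for v in range(5)}
        right = {partition[v] for v in range(5, 10)}
        assert len(left) == len(right) == 1
        assert left != right

    def test_component_without_core_gets_singleton_fallback(self):
        g = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
        strengths, scores = stages(g)
        assignment = CommunityAssignment.empty(g)  # no cores at all
        partition = propagate_labels(g, assignment, strengths, scores.ce)
        assert partition.n_communities == 2
        assert assignment.is_seed[0] and assignment.is_seed[3]

    def test_max_iter_validation(self):
        g = nx.complete_graph(3)
        strengths, scores = stages(g)
        with pytest.raises(ValueError):
            propagate_labels(
                g, CommunityAssignment.empty(g), strengths, scores.ce, max_iter=0
            )


class TestRunCdce:
    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError):
            run_cdce(nx.Graph())

    def test_partition_is_total(self):
        rng = np.random.default_rng(21)
        g = random_graph(rng, n=40, p=0.15)
        partition, *_ = run_cdce(g)
        assert set(partition.assignment) == set(g.nodes())

    def test_ring_of_triangles_recovers_triangles(self):
        from cdce.synthetic import generate_ring_of_cliques

        g, truth = generate_ring_of_cliques(6, 3)
        partition, *_ = run_cdce(g)
        assert partition.n_communities == 6
        assert nmi(partition, truth) == pytest.approx(1.0)

    def test_disjoint_clique_union_recovered_exactly(self):
        g = nx.Graph()
        sizes = [5, 3, 4, 6]
        start = 0
        expected = []
        for s in sizes:
            members = list(range(start, start + s))
            g.add_edges_from(
                (u, v) for u in members for v in members if u < v
            )
            expected.append(set(members))
            start += s
        partition, *_ = run_cdce(g)
        assert sorted(
            map(sorted, partition.communities.values())
        ) == sorted(map(sorted, expected))

    def test_deterministic_across_runs(self):
        rng = np.random.default_rng(33)
        g = random_graph(rng, n=30, p=0.2)
        first, *_ = run_cdce(g)
        for _ in range(4):
            again, *_ = run_cdce(g)
            assert again == first

    def test_equivariant_under_node_relabeling(self):
        rng = np.random.default_rng(34)
        g = random_graph(rng, n=20, p=0.25)
        partition, *_ = run_cdce(g)
        # relabel nodes but preserve insertion order (index structure),
        # so the deterministic tie-breaks are untouched
        mapping = {v: f"node-{v}" for v in g.nodes()}
        h = nx.relabel_nodes(g, mapping)
        hp, *_ = run_cdce(h)
        assert {mapping[v]: c for v, c in partition.assignment.items()} == hp.assignment

    def test_seeds_only_skips_core_absorption(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        g.add_edge(0, 4)
        _, _, full, _ = run_cdce(g)
        _, _, ablated, _ = run_cdce(g, seeds_only=True)
        assert ablated.n_cores < full.n_cores
        assert ablated.n_cores == ablated.n_seeds

    def test_karate_two_communities(self, karate):
        partition, scores, assignment, _ = run_cdce(karate)
        assert partition.n_communities == 2
        assert 1 in [n for i, n in enumerate(assignment.nodes) if assignment.is_seed[i]]
        assert partition[1] != partition[34]
        assert partition[33] == partition[34]


def test_processing_order_breaks_ties_by_index():
    order = algorithm._processing_order(np.array([0.5, 0.9, 0.5, 0.1]))
    assert order == [1, 0, 2, 3]
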