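# Methods

## Model and assumptions

`cdce` operates on simple, undirected, unweighted graphs. Self-loops and
parallel edges are normalised away on input (with logged warnings) because
every downstream quantity — maximal cliques, link strength, entropy — is
defined on simple graphs. Isolated nodes are retained and end up as
singleton communities, keeping the output partition total.

The driving assumption is that communities are *local* structures whose
centres sit inside dense, clique-rich neighbourhoods. Maximal cliques are
taken as the atomic evidence of density: an edge's weight is the sum of
the sizes of all maximal cliques containing both endpoints
(`ω`), and its link strength is `W = 1 + ω` so that even clique-free
edges dominate non-edges. A node's density-based entropy centrality
`CE(v)` is the Shannon entropy of its normalised incident strengths: it
is maximal (`log_b deg v`) when a node has many equally strong ties —
the signature of a community centre — and low when one or two ties
dominate, the signature of a peripheral or bridging node. `CE` is a
purely local score: it needs only the cliques within one neighbourhood,
so it scales to graphs where global centralities (betweenness,
closeness) are impractical, and it ranks nodes only *within* one
network, not across networks.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `min_clique_size` | 3 | smallest maximal-clique size contributing to `ω`; at 3, bridge edges outside any triangle keep `W = 1` |
| `log_base` | 10 | base of the entropy logarithm; rescales `CE` monotonically per degree class |
| `core_threshold` | 0.9 | fraction of a seed's maximal incident strength a neighbour must strictly exceed to be frozen into the core |
| `max_iter` | 100 | cap on propagation + stabilisation sweeps |
| `seed_centrality` | `"entropy"` | score driving seed detection and propagation order; `"clique"` and `"degree"` exist for ablation |
| `seeds_only` | `False` | ablation: skip neighbour absorption into cores |

The defaults for `min_clique_size` and `log_base` were fixed jointly by a
grid search over {2, 3} × {2, e, 10} against the published reference
centralities of the Zachary karate club (100·CE of 110, 108 and 95 for
members 1, 34 and 33): base 10 with cliques of size ≥ 3 is the unique
combination that reproduces all three, under rounding or truncation
alike. This choice also resolves an internal tension in the method's
definition — "link strength is 1 when the vertices do not belong to any
maximal clique" is only reachable if maximal 2-cliques are excluded,
i.e. `min_clique_size = 3`.

## Algorithmic conventions

Several orderings are left open by the method's informal description;
the package fixes them so that two runs can never disagree:

* Candidate seeds are processed in decreasing centrality, ties by
  ascending node index (input order).
* A node qualifies as a seed iff every neighbour either has no higher
  centrality or holds the node as its strict, unique strongest link.
  The qualification loop visits every node, regardless of any community
  membership acquired earlier in the pass, and may reassign it.
* A seed's strongest neighbour (`maxSim`, ties by ascending index) is
  absorbed into the seed's community if unlabeled; otherwise the seed
  *adopts* that neighbour's community — this is how adjacent local peaks
  (karate's members 33 and 34) merge. Neighbours with strength strictly
  above `core_threshold × maxLinkStrength` are absorbed as core.
* The `seeds_only` ablation skips both absorption steps but keeps the
  adoption rule; dropping adoption as well would split adjacent-peak
  communities (karate would come out as 3 communities at Q = 0.322
  instead of the reference 2 at Q = 0.372).
* Propagation sweeps unlabeled nodes in decreasing centrality with
  asynchronous updates; a node adopts the label with the largest summed
  incident link strength, ties to the smallest community id. After full
  labeling, stabilisation sweeps over non-core nodes run to a fixed
  point (or `max_iter`); seed/core labels are never overwritten.
  Components containing no core promote their lowest-index node to a
  singleton seed, guaranteeing totality and termination.
* Incident-strength sums use compensated summation (`math.fsum`), so
  equal-`CE` plateaus compare exactly across platforms.

Maximal cliques are enumerated with networkx's pivoting Bron–Kerbosch
implementation and canonicalised to sorted index tuples in lexicographic
order. Modularity is always computed on the original unweighted graph —
link strengths influence detection, never evaluation — so values are
comparable with modularity-optimising baselines. NMI uses the
arithmetic-mean normalisation `2I/(H_a+H_b)` (natural logs cancel); F1 is
the symmetric mean of the two directional best-match averages, with both
directions exposed because the literature uses either convention.

## Synthetic data: what it does and does not emulate

`generate_ring_of_cliques(n, k)` produces unambiguous communities
(complete graphs) joined by single triangle-free bridges — the clean
regime where correct recovery is exact, used for deterministic tests.

`generate_planted_partition` samples an equal-block stochastic block
model (independent Bernoulli edges, `p_in` within blocks, `p_out`
between; isolated nodes rewired to one random same-block neighbour),
bit-reproducible from an integer seed. It emulates homogeneous
communities with noisy boundaries but none of the heavy-tailed degree
and community-size distributions, overlapping membership, or degree
assortativity of real networks — passing recovery tests here shows the
pipeline handles noise, not that it matches real-world benchmark
performance.

At the reference setting (8 blocks × 16 nodes, `p_in = 0.3`,
`p_out = 0.01`) the expected within-block degree is 4.5 and only about
60 % of edges lie in any triangle, so much of the graph carries uniform
link strength `W = 1`. Recovery there is the package's known weak spot:
the measured median NMI over 20 seeds is ≈ 0.83 (modularity-optimising
Louvain reaches ≈ 0.95 on the same instances). This is a property of the
clique-driven scoring at that sparsity, not of the implementation — at
the same sizes every deterministic recovery check (clique unions, rings,
bridged cliques, karate) is exact.

## Problem sizes

Tests and the reproduction script run on desk-scale inputs: graphs up to
a few hundred nodes, exhaustive-subset clique oracles up to n = 12,
double-loop modularity oracles up to n = 30, and 20 planted-partition
instances of 128 nodes. The pipeline itself is near-linear in edges for
sparse graphs (clique enumeration is output-sensitive), and the CLI runs
unchanged on larger edge lists.

## Known limitations

* Strictly disjoint output: one label per node, no overlap scores.
* Clique-free regions (trees, very sparse graphs) carry uniform link
  strength, so seeds there are decided largely by tie-breaking order.
* `CE` values are comparable within one graph only.
* Directed or weighted input semantics are out of scope; directed GML is
  symmetrised on read.
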