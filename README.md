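# cdce — community detection by density-based entropy centrality

`cdce` finds the locally most important nodes of an undirected network and
grows communities around them. It is aimed at network analysts — in systems
biology (protein-interaction modules), social-network analysis, or any
domain where communities are local, densely knit structures — who want a
deterministic, parameter-light alternative to random-restart label
propagation.

## The method

Given a simple undirected graph `G = (V, E)`:

1. **Clique-sum edge weights.** Enumerate all maximal cliques of size ≥ 3
   (Bron–Kerbosch with pivoting). For each edge `(u, v)`, let
   `ω(u, v) = Σ ϑ(δ)` — the sum of the sizes `ϑ` of the maximal cliques `δ`
   containing both endpoints. The **link strength** is
   `W(u, v) = 1 + ω(u, v)`, so an edge in no clique still outranks a
   non-edge.
2. **Density-based entropy centrality.** For each node `v` with neighbours
   `N(v)`, normalise the incident strengths to a distribution
   `p_i = W(v, v_i) / Σ_j W(v, v_j)` and take its Shannon entropy,

   `CE(v) = − Σ_{v_i ∈ N(v)} p_i · log₁₀ p_i`.

   `CE` is high for nodes at the centre of dense subgraphs with many
   comparably strong ties; it is 0 for leaves. The sum of incident
   strengths, `CC(v) = Σ W(v, v_i)`, is the companion **clique
   centrality**, and `deg(v)/(n−1)` the usual degree centrality.
3. **CDCE.** Nodes whose `CE` dominates their neighbourhood become
   community **seeds**; each seed absorbs its strongest-linked neighbour
   and every neighbour within 90 % of that maximal strength into a frozen
   **core**; remaining nodes, visited in decreasing `CE`, adopt the label
   with the largest summed link strength among their labeled neighbours,
   with stabilisation sweeps to a fixed point. All tie-breaks are by node
   index, so runs are exactly reproducible.

Two conventions are deliberately fixed package-wide: maximal cliques count
only from size 3 upward (`min_clique_size=3`), and the entropy logarithm is
base 10. This is the unique pair under which the package reproduces the
published reference centralities of the karate-club network (see below);
both are exposed as parameters.

Quality metrics included: Newman–Girvan modularity `Q` (computed on the
unweighted graph), NMI with arithmetic-mean normalisation, and symmetric
best-match F1. Synthetic generators (planted partitions, rings of cliques)
make the whole pipeline testable without any download.

## Worked example

```python
from cdce import CDCE, datasets

karate = datasets.karate_club()          # 34 members, 78 ties
results = CDCE(karate).fit()
print(results.summary())
```

```
CDCE community detection results
================================================
Nodes:                34
Edges:                78
Seed centrality:      entropy
Min clique size:      3
Entropy log base:     10
Core threshold:       0.9
Seeds / cores:        3 / 4
Communities:          2
Community sizes:      [17, 17]
Modularity Q:         0.372
------------------------------------------------
Top nodes by entropy centrality:
       1  CE=1.1036  CC=110  community=0
      34  CE=1.0802  CC=95  community=1
      33  CE=0.9535  CC=78  community=1
       3  CE=0.8792  CC=62  community=0
       2  CE=0.8486  CC=67  community=0
```

The club's two factions are recovered exactly as a 17/17 split with
modularity 0.372; the instructor (node 1) and administrator (node 34) are
the two most central members (`100·CE` = 110 and 108, then node 33 at 95),
and each anchors one community. `results.partition`,
`results.to_frame()` and `results.evaluate(ground_truth)` expose the
node-level details and quality metrics.

The same pipeline is available from the shell:

```bash
cdce generate --ring 6 5 --output ring.edgelist --truth truth.tsv
cdce detect --input ring.edgelist --output part.tsv --report report.json
cdce evaluate --graph ring.edgelist --partition part.tsv --truth truth.tsv
cdce centrality --input ring.edgelist
```

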