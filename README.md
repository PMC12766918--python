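# netkin

Annotate networks by detecting communities, testing each community for
overrepresentation of annotation terms, scoring clustering quality on the
layout, and rendering contour-overlay figures.

`netkin` is aimed at systems biologists (and network scientists generally)
who have an interaction network — a yeast protein–protein or genetic
interaction map, a citation graph — plus a term→member annotation table
such as GO Biological Process, and want to know **which regions of the
network are enriched for which functions**. The workflow is:

1. **Import** the network (Cytoscape JSON, edge-list TSV/CSV, GraphML, or
   a pickled graph) and the annotation table (JSON / long-format CSV/TSV),
   building a sparse binary node×term membership matrix aligned to a
   canonical node order.
2. **Cluster** with native Louvain, label propagation, greedy modularity
   agglomeration, or Markov Clustering (Leiden, Spinglass, and Walktrap
   are delegated to igraph backends when installed).
3. **Test** every (cluster, term) pair for overrepresentation. For a
   cluster of size *n* in a universe of *N* nodes with *K* term-annotated
   nodes and overlap *k*, the tests are the upper-tail hypergeometric

   p = Σᵢ₌ₖ C(K,i)·C(N−K,n−i) / C(N,n),

   the upper-tail binomial at rate K/N, the one-sided 2×2 Pearson
   chi-squared, and a permutation test that shuffles node labels of the
   annotation matrix — evaluated for **all** pairs in one vectorized pass
   over sparse matrices (O(R·nnz) for R permutations; the only dense
   object is the clusters×terms count matrix, never node×term×R).
   Benjamini–Hochberg or Bonferroni correction is applied across all
   pairs; `correction="none"` reproduces raw-threshold conventions.
4. **Filter and label** significant clusters (domains), including a
   uniqueness filter that removes nodes claimed by two or more
   significant clusters.
5. **Evaluate** clustering quality on 2-D layout coordinates —
   compactness (mean intra-cluster pairwise distance), separation
   (minimum centroid distance), silhouette — and compare two clusterings
   with a Mann–Whitney U test.
6. **Visualize**: spring-embedded (Fruchterman–Reingold) or ForceAtlas2
   layouts, per-domain colors, Gaussian-KDE contour overlays, SVG/PNG/PDF
   export; byte-identical output for a fixed seed.

A synthetic benchmark module generates scale-free networks with twice as
many edges as nodes (triangle-seeded preferential attachment, so
|E| = 2n − 3 exactly for attachment degree 2), GO-BP-like null annotation
tables (1000 heavy-tailed terms by default), and planted-partition
fixtures with coherent annotation signal — so the whole pipeline is
testable without any external downloads.

## Worked example

```python
import netkin as nk

# planted benchmark: 4 blocks x 25 nodes, p_in=0.5, p_out=0.02,
# one coherent signal term per block (80% coverage) + 20 decoy terms
net, truth, matrix = nk.gen_planted(4, 25, 0.5, 0.02, seed=11,
                                    coherent_terms=True)
part = nk.louvain(net, seed=11)
print(nk.adjusted_rand_index(part, truth))   # 1.0  (blocks recovered)
print(part.k)                                # 4

tab = nk.run_overrep(matrix, part, test="hypergeom", alpha=0.01,
                     correction="bh")
best = tab.sort_values("p").head(4)[["cluster", "term", "k", "n", "K", "p"]]
print(best.to_string(index=False))
#  cluster     term  k  n  K            p
#        0 signal_0 20 25 20 9.912621e-17
#        1 signal_1 20 25 20 9.912621e-17
#        2 signal_2 20 25 20 9.912621e-17
#        3 signal_3 20 25 20 9.912621e-17

coords = nk.layout(net, seed=11)
mean_s, _ = nk.silhouette(coords, part)
print(round(mean_s, 3))                      # 0.586
```

Each of the four planted signal terms is the most enriched term of its
own recovered cluster (k = 20 of the cluster's n = 25 nodes carry the
term, versus K = 20 of N = 100 in the whole network), the hypergeometric
p-values survive BH correction by many orders of magnitude, and the
recovered clusters are well separated in the layout (silhouette 0.586).

The same pipeline from the shell:

```bash
netkin simulate --nodes 1000 --terms 1000 --seed 7 \
    --out-net net.cyjs --out-ann ann.json
netkin cluster --net net.cyjs --algorithm louvain --seed 42 --out part.tsv
netkin test --net net.cyjs --ann ann.json --partition part.tsv \
    --test hypergeom --alpha 0.01 --correction none --out overrep.tsv
netkin domains --overrep overrep.tsv --alpha 0.01 --out domains.tsv
netkin run --config run.yaml      # one-shot: all artifacts + manifest
```

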