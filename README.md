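# genenets

Discovery and statistical assessment of molecular interaction networks within
a candidate gene list.

## The problem

Transcriptional profiling (RNA-Seq, microarrays) typically ends in a list of
differentially expressed genes. The biological question that follows is
whether members of that list act together: do they form connected networks of
previously described genetic or physical interactions? `genenets` answers
this for any organism for which a curated pairwise-interaction table is
available (it was designed with the *C. elegans* interactome in mind). It is
aimed at bench scientists and bioinformaticians who want a reproducible,
scriptable alternative to manual database browsing.

## The method

Given an interaction database and a candidate list 𝕃:

1. **Filtering.** Interactions that are only computationally predicted are
   discarded; every retained edge is supported by at least one experimental
   publication. Duplicate records for the same unordered pair are merged, so
   an edge's *citation count* is its number of distinct publications.
2. **Basic graph.** A graph **G** = (V, E) is built over the list genes.
   Edges are *direct* (one curated interaction between two list genes) or
   *indirect* (two curated interactions through one non-list *linker* gene —
   a key player that the expression screen may have missed, e.g. a receptor
   regulated post-transcriptionally).
3. **Depth-limited search.** From each list gene in turn, all *d*-neighbours
   (nodes reachable in at most *d* steps, one direct **or** indirect edge per
   step) are collected; indirect edges are then replaced by their two legs
   plus a new node for the linker, giving a network **N** = (V_N, E_N). The
   procedure repeats with the remaining genes, and with the iteration depth
   lowered from *D* to 1 so that smaller nested networks also surface.
4. **Statistics.** Each network receives
   * a **score** = mean citation count over its edges (strength of
     experimental evidence), with a permutation p-value: the fraction of
     randomly simulated networks (|E_N| edges resampled from the database)
     scoring at least as high;
   * a **list-based p-value**: with k = |**N**¹ ∩ 𝕃| list genes inside the
     induced 1-neighbourhood **N**¹ of the network, k is hypergeometric with
     parameters N (gene universe), |**N**¹| and |𝕃| under the null that list
     membership is independent of **N**¹, and the p-value is the upper tail
     P(X ≥ k).

Results are ranked by score and emitted as a TSV table, per-network GraphViz
DOT files and gene lists, and a machine-readable JSON report.

## Worked example

A small insulin/IGF-signalling (IIS) demo network ships with the package:
six genes around the FoxO transcription factor *daf-16*, including the
insulin-receptor orthologue *daf-2* which is **not** on the candidate list
and is recovered as a linker. The *daf-16*–*daf-2* interaction is supported
by 135 publications; the other five edges by one each.

```sh
genenets --db src/genenets/data/iis_network.tsv \
         --genes src/genenets/data/iis_genes.txt \
         --out demo_out --depth 1 --seed 1
```

`demo_out/results.tsv`:

```text
rank	genes	nodes	edges	score	p_score	p_list
1	daf-16, daf-3, daf-36, myo-2, peb-1, daf-2	6	6	23.33	1.0000	1.0000
```

One network is found: 6 nodes (5 list genes + the linker *daf-2*), 6 edges,
score (135 + 1 + 1 + 1 + 1 + 1)/6 = 23.33. Both p-values are 1 here because
the demo database contains nothing but this network: every simulated network
reuses its own edges, and its neighbourhood already covers the whole
database. Against a genome-scale database the same network scores in the
extreme tail of both nulls. `demo_out/network_001.dot` draws list genes red,
the linker white, and the 135-citation edge bold — render it with
`dot -Tpng demo_out/network_001.dot`.

The same analysis is available as a library:

```python
import genenets as gn

db, genes = gn.load_iis_demo()
graph = gn.build_basic_graph(db, genes)
cfg = gn.SearchConfig(random_seed=1, max_depth=1)
(net,) = gn.find_networks(graph, genes, cfg)
gn.network_score(net)   # 23.333333333333332
```

Synthetic benchmarks (Erdős–Rényi backgrounds, heavy-tailed citation counts,
planted path/star/clique motifs with known ground truth) are generated by
`genenets.synthetic_data` — see `docs/methods.md`.

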