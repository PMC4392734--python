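# Methods

This note records the model, the algorithmic and numerical choices, and the
limits of what the synthetic benchmarks demonstrate.

## Input model

The interaction database is a five-column TSV (`gene_a`, `gene_b`,
`interaction_class` ∈ {genetic, physical}, `evidence_class` ∈ {experimental,
predicted}, `publications` as `|`-separated identifiers). This dialect is a
portable, loss-free stand-in for direct access to a curated resource: it
captures everything the method uses. Design choices at this layer:

* **Predicted-only interactions are excluded** before anything else; every
  retained edge must carry ≥ 1 publication. Predicted interactions (e.g.
  transferred from orthologues) have no experimental support in the organism
  under study and would also make the citation score meaningless.
* **Citations = distinct publications** after merging duplicate unordered
  pairs by set union. Counting rows instead of distinct publications would
  double-count re-submitted records.
* **Self-interactions are dropped**: they cannot connect two candidate genes
  and would inflate neighbourhood sizes in the enrichment test.
* **Edges are undirected.** Direction of genetic regulation is not modelled
  anywhere in the method.
* **Identifier matching** is exact after whitespace stripping; a case-folding
  flag exists but is off by default because silent case-folding can merge
  distinct loci.
* Genetic and physical interactions are treated identically throughout; the
  class is carried only as metadata.

## Graph construction

The basic graph G has one node per candidate gene present in the database.
Direct edges are database edges with both endpoints on the list. Indirect
edges are length-2 database paths whose midpoint (the *linker*) is not on the
list; chains of two or more consecutive non-list genes are not edges — an
indirect interaction is exactly one pair of interactions. All linkers between
a pair are retained (each is independent evidence); a cap option exists,
defaulting to unlimited, keeping lexicographically first linkers when set. A
pair may be connected both directly and indirectly, and keeps both: the
linker is materialised into the network whenever both endpoints are members,
which is what makes missed hub genes (the IIS demo's daf-2) visible in the
output even when the pair is also directly joined.

## Search

The iteration depth D bounds the number of steps from a start gene; one
direct or one indirect edge is one step. Linkers are never start genes and
are never traversed through — they exist only inside the indirect-edge
definition. For each d = D, …, 1 the candidate list is walked in input order;
genes absorbed into a computed neighbourhood are consumed for the current
depth pass whether or not a network was emitted, and consumption resets
between passes. Networks are deduplicated on their exact node set (list
members + linkers). Networks at lower depth that are strict subsets of a
deeper network are reported as long as their node set differs: overlapping
results at several scales are informative, and duplication is suppressed by
the node-set key. A network must connect at least `min_list_genes = 2`
candidate genes; singletons are never reported.

Final ordering: score descending, then list-based p-value ascending, then
node count descending, then lexicographically smallest node set. The
tie-break chain makes output deterministic. Note one consequence: when
several networks tie on score (e.g. nested sub-networks whose edges all carry
equal citation counts), the smaller one can rank first because its tighter
neighbourhood gives a smaller list-based p-value.

At d = diameter of a component, the emitted network equals the whole
connected component, so with D large the search degenerates to classical
connected components — the depth limit exists because candidate-gene
components in dense interactomes quickly become uninterpretably large. The
command-line default is D = 2; the worked example uses D = 1, which is the
appropriate choice when the goal is a ranked list of tight, high-evidence
modules.

## Network score and permutation null

Score(N) = (Σ_e citations(e)) / |E_N|. The null model for "a random network
of the same size" draws |E_N| edges uniformly **without replacement** from
the database's experimental edge set and scores them the same way. Rationale:
the score depends on nothing but the multiset of edge citation counts and
the edge count, so resampling edge counts is the minimal null that holds the
right quantity fixed; it is also exactly enumerable (all C(|E_db|, |E_N|)
subsets) on small databases, which the tests exploit. A
connectivity-preserving variant (random edge-growth of a connected subgraph)
is available behind a flag but is not the default: it conflates topology
with citation structure and is not enumerable.

The p-value is the literal fraction (# simulated scores ≥ observed) / n_sim,
which can return 0; an add-one-corrected option exists. Default
n_sim = 10,000, so the smallest reportable nonzero p is 0.0001 and smaller
values render as "<0.0001". The seed is mandatory in the search
configuration; all simulation uses `numpy.random.default_rng`. Exceedance is
tested with a 1e-12 tolerance so that ties (equal rational scores) count as
exceedances regardless of floating-point summation order.

## List-based (hypergeometric) enrichment

N¹ is computed on the **full database graph**, not on the list-restricted
graph: the null hypothesis compares the list against the whole gene universe,
which requires genome-scale neighbourhoods. N¹ includes the network's own
nodes (each is the 1-neighbour of a partner); an option excludes them. With
k = |N¹ ∩ 𝕃|, the p-value is the upper-tail sum of the hypergeometric
density from k to min(|N¹|, |𝕃|) (the upper end of the support — the only
bound for which the sum is defined). Implementation uses
`scipy.stats.hypergeom`; tests verify it against exhaustive subset
enumeration and term-by-term summation of the closed-form density.

The universe size N defaults to the number of genes in the database and can
be overridden with a genome-wide count. When N is the database itself, list
genes absent from the database are not universe members and |𝕃| is counted
as |𝕃 ∩ genes(db)|; with an explicit genome-wide N the full unique list
counts. Raw p-values are reported per network; the JSON report additionally
carries Benjamini–Hochberg-adjusted values as a clearly separated extension
(the ranked table shows raw values only).

## Synthetic data and what the benchmarks show

`synthetic_data` generates Erdős–Rényi background databases with citation
counts drawn from a constant, geometric, or two-point distribution. The
two-point spec (1 citation with probability 0.95, else 135) is the default
because curated interaction databases are heavy-tailed in exactly this way —
most interactions described once, a few famous ones described very many
times. Planted motifs (path / star / clique, with optional linkers excluded
from the generated list) get 1 + citation_boost citations per edge and their
exact post-expansion network is recorded as ground truth. Problem sizes used
in the benchmark suite — backgrounds of 100–150 genes, lists of 12–15,
100–1000 replicates — were chosen so the whole suite enumerates exactly
where it can and completes in seconds while leaving the statistical checks
well-powered.

What passing benchmarks do show: the search is exactly equivalent to
breadth-first search / connected components on the traversal graph; the
expansion rule reproduces planted ground truth node-for-node; both p-values
agree with exact enumeration where enumeration is feasible; the enrichment
p-value is super-uniform when N¹ is fixed and the list is drawn uniformly.

What they do not show: real interactomes are not Erdős–Rényi (no hubs, no
degree correlations beyond chance), citation counts are not literally
two-point, and identifier noise (synonyms, merged loci) is absent. Recovery
rates measured here therefore do not transfer quantitatively to real
databases.

## Known limitations

* **Small-network anti-conservativeness.** The enrichment test conditions on
  a network having been *discovered from the list*, so its ≥ 2 member genes
  are guaranteed to lie in N¹. For tiny networks in sparse databases — where
  N¹ barely exceeds the network itself — the p-value approaches
  C(|𝕃|, 2)/C(N, 2) by construction and can cross conventional thresholds
  without any biological signal. In realistic-density databases (mean degree
  ≥ ~5) N¹ is much larger than the network and the effect is mild — the
  pipeline-level calibration run (1000 uniform-list analyses at mean degree
  ≈ 6) keeps the fraction of networks below p = 0.01 at ≈ 0.03 — but
  2-node networks with small neighbourhoods should be read with care.
* The permutation null ignores topology by design; a network of famous
  edges in a famous neighbourhood is judged only on citation counts.
* Citation count is a measure of research attention, not interaction
  strength; heavily studied genes score high for sociological reasons.
* Linker expansion admits exactly one intermediate; pathways bridged by two
  unlisted genes are invisible at any depth.
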