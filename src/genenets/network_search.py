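"""Depth-limited network discovery over the basic candidate-gene graph.

The search seeds at the first candidate gene, collects its d-neighbours (every
node reachable in at most d steps, where one direct *or* one indirect edge is
one step), expands indirect edges into their two database legs plus the linker
node, and emits the resulting connected network. It then repeats with the
remaining candidate genes, and finally with the depth lowered from D down
to 1 to surface smaller networks nested inside large components. Emitted
networks are deduplicated on their exact node set and returned sorted by
network score (descending).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx

from .graph_builder import BasicGraph
from .interaction_db import GeneList, GenePair, gene_pair


@dataclass(frozen=True)
class SearchConfig:
    """Tuning knobs of the discovery algorithm.

    ``max_depth`` is the iteration depth D: the number of allowed steps from a
    start gene. ``min_list_genes`` is the smallest number of candidate genes a
    reported network must connect (singletons are never reported).
    ``random_seed`` and ``n_simulations`` parameterise the downstream
    permutation null; the seed is mandatory so runs are reproducible.
    """

    random_seed: int
    max_depth: int = 2
    min_list_genes: int = 2
    n_simulations: int = 10_000

    def __post_init__(self) -> None:
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.min_list_genes < 2:
            raise ValueError("min_list_genes must be >= 2")
        if self.n_simulations < 0:
            raise ValueError("n_simulations must be >= 0")


@dataclass(frozen=True)
class Network:
    """One discovered network N = (V_N, E_N) after linker expansion.

    ``members`` are candidate-list genes, ``linkers`` the non-list genes
    materialised from indirect edges. Edge values are citation counts.
    """

    members: frozenset[str]
    linkers: frozenset[str]
    edges: dict[GenePair, int] = field(hash=False)
    start_gene: str | None = None
    depth: int | None = None

    @property
    def all_nodes(self) -> frozenset[str]:
        return self.members | self.linkers

    @property
    def n_nodes(self) -> int:
        return len(self.all_nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def is_list_member(self, gene: str) -> bool:
        return gene in self.members

    def sorted_nodes(self) -> list[str]:
        """Candidate genes first, then linkers, each lexicographic."""
        return sorted(self.members) + sorted(self.linkers)


def d_neighbours(g: BasicGraph, start: str, d: int) -> set[str]:
    """All basic-graph nodes reachable from ``start`` in at most ``d`` steps.

    Direct and indirect edges each count as a single step. Linker genes are
    not nodes of G and are therefore not neighbours at this stage; they are
    materialised later by :func:`expand_network`.
    """
    if start not in g.nodes:
        raise KeyError(f"gene {start!r} is not a node of the basic graph")
    if d < 0:
        raise ValueError("d must be non-negative")
    reach = nx.single_source_shortest_path_length(g.adjacency(), start, cutoff=d)
    return set(reach)


def expand_network(
    g: BasicGraph,
    members: Iterable[str],
    start_gene: str | None = None,
    depth: int | None = None,
) -> Network:
    """Materialise the network over ``members``, replacing indirect edges.

    Every direct edge among the members is kept as-is; every indirect edge is
    replaced by its two database legs plus a new node for the linker gene. A
    pair joined both directly and indirectly keeps the direct edge *and* all
    linker paths. The resulting node set must be connected.
    """
    member_set = frozenset(members)
    if not member_set <= g.nodes:
        raise ValueError("members must be nodes of the basic graph")

    edges: dict[GenePair, int] = {}
    linkers: set[str] = set()
    for pair, citations in g.direct_edges.items():
        if pair[0] in member_set and pair[1] in member_set:
            edges[pair] = citations
    for (a, b), paths in g.indirect_edges.items():
        if a in member_set and b in member_set:
            for path in paths:
                linkers.add(path.linker)
                edges[gene_pair(a, path.linker)] = path.citations_a
                edges[gene_pair(path.linker, b)] = path.citations_b

    net = Network(
        members=member_set,
        linkers=frozenset(linkers),
        edges=edges,
        start_gene=start_gene,
        depth=depth,
    )
    if len(net.all_nodes) > 1:
        check = nx.Graph()
        check.add_nodes_from(net.all_nodes)
        check.add_edges_from(net.edges)
        if not nx.is_connected(check):
            raise ValueError("members do not form a connected network; pass one component")
    return net


def find_networks(g: BasicGraph, gene_list: GeneList, cfg: SearchConfig) -> list[Network]:
    """Run the full discovery procedure and return score-sorted networks.

    For each depth d = D, D-1, ..., 1 the candidate list is walked in input
    order; each gene not yet absorbed during the current depth pass seeds a
    d-neighbour search whose expansion is emitted if it connects at least
    ``min_list_genes`` candidate genes and its node set has not been emitted
    before. Final order: score descending, then list-based p-value ascending,
    then node count descending, then lexicographically smallest node set.
    """
    from .network_stats import list_enrichment_pvalue_for, network_score

    emitted: list[Network] = []
    seen: set[frozenset[str]] = set()
    for d in range(cfg.max_depth, 0, -1):
        consumed: set[str] = set()
        for gene in gene_list.members:
            if gene not in g.nodes or gene in consumed:
                continue
            members = d_neighbours(g, gene, d)
            consumed |= members
            if len(members) < cfg.min_list_genes:
                continue
            net = expand_network(g, members, start_gene=gene, depth=d)
            key = net.all_nodes
            if key in seen:
                continue
            seen.add(key)
            emitted.append(net)

    def sort_key(net: Network):
        return (
            -network_score(net),
            list_enrichment_pvalue_for(net, g.db, gene_list),
            -net.n_nodes,
            tuple(sorted(net.all_nodes)),
        )

    emitted.sort(key=sort_key)
    return emitted
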