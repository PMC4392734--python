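"""Construction of the basic candidate-gene graph with direct and indirect edges.

The basic graph G = (V, E) has one node per candidate-list gene found in the
interaction database. A *direct* edge joins two list genes that interact
directly; an *indirect* edge joins two list genes that are both partners of a
shared non-list *linker* gene — a pair of curated interactions through one
intermediate. Linker genes model true pathway members that were missed by the
upstream differential-expression screen (e.g. a receptor regulated
post-transcriptionally). Chains of two or more consecutive non-list genes are
not edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional

import networkx as nx

from .interaction_db import GeneList, GenePair, InteractionDatabase, gene_pair


@dataclass(frozen=True)
class LinkerPath:
    """One indirect connection: list gene A — linker — list gene B.

    ``citations_a`` supports the leg to the lexicographically smaller list
    gene of the pair, ``citations_b`` the other leg.
    """

    linker: str
    citations_a: int
    citations_b: int


@dataclass
class BasicGraph:
    """The list-aware graph G over candidate genes.

    ``direct_edges`` maps an unordered list-gene pair to its citation count;
    ``indirect_edges`` maps a pair to every linker path joining it. A pair may
    carry both kinds simultaneously. ``missing_genes`` records list genes not
    present in the database (diagnostics only).
    """

    nodes: frozenset[str]
    direct_edges: dict[GenePair, int]
    indirect_edges: dict[GenePair, tuple[LinkerPath, ...]]
    db: InteractionDatabase
    missing_genes: frozenset[str]
    _adjacency: Optional[nx.Graph] = field(default=None, repr=False, compare=False)

    def adjacency(self) -> nx.Graph:
        """Traversal view: one edge per connected pair, direct or indirect."""
        if self._adjacency is None:
            graph = nx.Graph()
            graph.add_nodes_from(self.nodes)
            graph.add_edges_from(self.direct_edges)
            graph.add_edges_from(self.indirect_edges)
            self._adjacency = graph
        return self._adjacency

    @property
    def n_edges(self) -> int:
        return len(set(self.direct_edges) | set(self.indirect_edges))


def build_basic_graph(
    db: InteractionDatabase,
    gene_list: GeneList,
    max_linkers_per_pair: Optional[int] = None,
) -> BasicGraph:
    """Build G from the database and the candidate list.

    Every database edge with both endpoints in the list becomes a direct edge.
    Every length-2 database path list-gene — non-list-gene — list-gene becomes
    an indirect edge; all linkers between a pair are retained (each is
    independent evidence) unless capped by ``max_linkers_per_pair``, in which
    case the lexicographically first linkers are kept.
    """
    list_set = set(gene_list.members)
    present = frozenset(list_set & db.genes)
    missing = frozenset(list_set - db.genes)
    if not present:
        warnings.warn("no candidate gene occurs in the interaction database", stacklevel=2)

    direct: dict[GenePair, int] = {}
    for pair, data in db.edges.items():
        if pair[0] in present and pair[1] in present:
            direct[pair] = data.citation_count

    indirect: dict[GenePair, list[LinkerPath]] = {}
    for linker in db.genes - list_set:
        partners = sorted(db.neighbours(linker) & present)
        for a, b in combinations(partners, 2):
            indirect.setdefault(gene_pair(a, b), []).append(
                LinkerPath(
                    linker=linker,
                    citations_a=db.citation_count(a, linker),
                    citations_b=db.citation_count(linker, b),
                )
            )

    capped: dict[GenePair, tuple[LinkerPath, ...]] = {}
    for pair, paths in indirect.items():
        paths.sort(key=lambda p: p.linker)
        if max_linkers_per_pair is not None:
            paths = paths[:max_linkers_per_pair]
        capped[pair] = tuple(paths)

    for pair, paths in capped.items():
        assert all(p.linker not in list_set for p in paths), "linker inside candidate list"

    return BasicGraph(
        nodes=present,
        direct_edges=direct,
        indirect_edges=capped,
        db=db,
        missing_genes=missing,
    )


def list_linkers(g: BasicGraph) -> set[str]:
    """All linker genes appearing in any indirect edge of G."""
    return {p.linker for paths in g.indirect_edges.values() for p in paths}


def basic_graph_to_dot(g: BasicGraph) -> str:
    """Debug dump of G as DOT text (direct edges solid, indirect dashed)."""
    lines = ["graph basic_graph {"]
    for node in sorted(g.nodes):
        lines.append(f'  "{node}";')
    for a, b in sorted(g.direct_edges):
        lines.append(f'  "{a}" -- "{b}";')
    for (a, b), paths in sorted(g.indirect_edges.items()):
        linkers = ",".join(p.linker for p in paths)
        lines.append(f'  "{a}" -- "{b}" [style=dashed, label="{linkers}"];')
    lines.append("}")
    return "\n".join(lines) + "\n"
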