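"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive (explicit loops, exhaustive
enumeration) and shares no code with the package under test.
"""

from __future__ import annotations

from itertools import combinations
from math import comb


def bfs_reachable(adjacency: dict[str, set[str]], start: str, d: int) -> set[str]:
    """Plain breadth-first search: nodes within d steps of start."""
    frontier = {start}
    seen = {start}
    for _ in range(d):
        nxt = set()
        for node in frontier:
            for nb in adjacency.get(node, set()):
                if nb not in seen:
                    seen.add(nb)
                    nxt.add(nb)
        frontier = nxt
        if not frontier:
            break
    return seen


def two_path_indirect_edges(
    db_pairs: set[tuple[str, str]], list_genes: set[str]
) -> dict[tuple[str, str], set[str]]:
    """All (listA, listB) pairs joined via a single non-list midpoint."""
    adjacency: dict[str, set[str]] = {}
    for a, b in db_pairs:
        adjacency.setdefault(a, set()).add(b)
        adjacency.setdefault(b, set()).add(a)
    out: dict[tuple[str, str], set[str]] = {}
    for mid, partners in adjacency.items():
        if mid in list_genes:
            continue
        in_list = sorted(p for p in partners if p in list_genes)
        for a, b in combinations(in_list, 2):
            out.setdefault((min(a, b), max(a, b)), set()).add(mid)
    return out


class UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def connected_components(nodes: set[str], edges: set[tuple[str, str]]) -> set[frozenset[str]]:
    """Union-find connected components."""
    uf = UnionFind(nodes)
    for a, b in edges:
        uf.union(a, b)
    groups: dict[str, set[str]] = {}
    for n in nodes:
        groups.setdefault(uf.find(n), set()).add(n)
    return {frozenset(g) for g in groups.values()}


def hypergeom_pmf_enumeration(k: int, universe: int, neighbourhood: int, list_size: int) -> float:
    """P(|S ∩ [0, neighbourhood)| = k) for S a uniform list_size-subset of [0, universe)."""
    hits = 0
    total = 0
    marked = set(range(neighbourhood))
    for subset in combinations(range(universe), list_size):
        total += 1
        if len(marked.intersection(subset)) == k:
            hits += 1
    return hits / total if total else 0.0


def hypergeom_tail_by_summation(k: int, universe: int, neighbourhood: int, list_size: int) -> float:
    """Upper tail as an explicit term-by-term sum of the closed-form density."""
    n_max = min(neighbourhood, list_size)
    total = 0.0
    denom = comb(universe, list_size)
    for kk in range(k, n_max + 1):
        total += comb(universe - neighbourhood, list_size - kk) * comb(neighbourhood, kk) / denom
    return total


def exact_score_pvalue(db_counts: list[int], n_edges: int, observed: float) -> float:
    """Exact permutation p: fraction of all edge subsets of size n_edges whose
    mean citation count is at least the observed score."""
    hits = 0
    total = 0
    for subset in combinations(db_counts, n_edges):
        total += 1
        if sum(subset) / n_edges >= observed - 1e-12:
            hits += 1
    return hits / total
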