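"""Synthetic interaction databases, gene lists and planted networks.

Every other module is testable without any download: this module generates
Erdős–Rényi background databases whose edge citation counts follow a chosen
distribution, plants connected motifs (path / star / clique) with known node
and edge sets, and draws candidate gene lists that contain the planted list
genes but never the planted linkers.

The default citation distribution is two-point — most interactions described
in a single publication, a few described many times — which mimics the
heavy-tailed citation regime of curated interaction databases (one famous
135-citation interaction among unit-citation edges). A small, fully worked
insulin/IGF-signalling (IIS) demo network around daf-16 and its linker daf-2
ships as packaged data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from itertools import combinations
from pathlib import Path
from typing import Union

import numpy as np

from .interaction_db import (
    ConfigurationError,
    EdgeData,
    GeneList,
    GenePair,
    InteractionDatabase,
    gene_pair,
    read_gene_list,
    read_interaction_table,
    filter_experimental,
    build_database,
)


@dataclass(frozen=True)
class ConstantCitations:
    """Every edge supported by exactly ``count`` publications."""

    count: int = 1

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.count < 1:
            raise ConfigurationError("constant citation count must be >= 1")
        return np.full(size, self.count, dtype=int)


@dataclass(frozen=True)
class GeometricCitations:
    """Citation counts geometric on {1, 2, ...} with the given mean."""

    mean: float = 3.0

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.mean < 1:
            raise ConfigurationError("geometric citation mean must be >= 1")
        return rng.geometric(1.0 / self.mean, size=size)


@dataclass(frozen=True)
class TwoPointCitations:
    """1 citation with probability ``p_low``, else ``high`` citations."""

    p_low: float = 0.95
    high: int = 135

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if not (0.0 <= self.p_low <= 1.0) or self.high < 1:
            raise ConfigurationError("invalid two-point citation spec")
        low = rng.random(size) < self.p_low
        return np.where(low, 1, self.high).astype(int)


CitationSpec = Union[ConstantCitations, GeometricCitations, TwoPointCitations]

MOTIF_SHAPES = ("path", "star", "clique")


@dataclass(frozen=True)
class PlantedNetwork:
    """Ground truth for one planted motif, recorded post-expansion."""

    members: frozenset[str]
    linkers: frozenset[str]
    edges: dict[GenePair, int] = field(hash=False)

    @property
    def all_nodes(self) -> frozenset[str]:
        return self.members | self.linkers


@dataclass
class SyntheticTruth:
    """Everything a recovery test needs to know about a generated instance."""

    planted_networks: list[PlantedNetwork]
    background_params: dict
    list_spec: dict | None
    seed: int


def _synthetic_publications(count: int, tag: str) -> frozenset[str]:
    return frozenset(f"SYN:{tag}:{i:04d}" for i in range(count))


def generate_database(
    n_genes: int,
    edge_probability: float,
    citation_dist: CitationSpec = TwoPointCitations(),
    seed: int = 0,
) -> tuple[InteractionDatabase, SyntheticTruth]:
    """Erdős–Rényi background database with synthetic publication IDs.

    Publication identifiers are materialised so that each edge's publication
    set has exactly the drawn cardinality; the emitted database therefore
    satisfies every invariant of a parsed one. Deterministic under ``seed``.
    """
    if n_genes < 2:
        raise ConfigurationError("n_genes must be >= 2")
    if not (0.0 <= edge_probability <= 1.0):
        raise ConfigurationError("edge_probability must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    genes = [f"g{i:04d}" for i in range(n_genes)]
    pairs = list(combinations(genes, 2))
    mask = rng.random(len(pairs)) < edge_probability
    kept = [p for p, m in zip(pairs, mask) if m]
    counts = citation_dist.draw(rng, len(kept))

    edges: dict[GenePair, EdgeData] = {}
    for (a, b), count in zip(kept, counts):
        edges[gene_pair(a, b)] = EdgeData(
            interaction_classes=frozenset({"physical"}),
            publications=_synthetic_publications(int(count), f"{a}-{b}"),
        )
    db_genes = frozenset(g for pair in edges for g in pair)
    # isolated genes are not database genes but still count toward the universe
    db = InteractionDatabase(
        edges=edges, genes=db_genes, universe_size=n_genes, universe_is_default=False
    )
    truth = SyntheticTruth(
        planted_networks=[],
        background_params={
            "n_genes": n_genes,
            "edge_probability": edge_probability,
            "citation_dist": repr(citation_dist),
        },
        list_spec=None,
        seed=seed,
    )
    return db, truth


def _motif_edges(shape: str, members: list[str], linkers: list[str]) -> list[GenePair]:
    if shape == "path":
        if len(linkers) > len(members) - 1:
            raise ConfigurationError("a path motif fits at most n_list_nodes - 1 linkers")
        chain: list[str] = []
        remaining = list(linkers)
        for m in members:
            chain.append(m)
            if remaining:
                chain.append(remaining.pop(0))
        # any trailing linker would dangle; interleave consumed all by the check above
        return [gene_pair(chain[i], chain[i + 1]) for i in range(len(chain) - 1)]
    if shape == "star":
        if len(members) < 3:
            raise ConfigurationError("a star motif needs at least 3 list nodes")
        hub = members[0]
        edges = [gene_pair(hub, leaf) for leaf in members[1:]]
        for i, linker in enumerate(linkers):
            leaf = members[1 + (i % (len(members) - 1))]
            edges.append(gene_pair(hub, linker))
            edges.append(gene_pair(linker, leaf))
        return sorted(set(edges))
    if shape == "clique":
        if len(members) < 2:
            raise ConfigurationError("a clique motif needs at least 2 list nodes")
        edges = [gene_pair(a, b) for a, b in combinations(members, 2)]
        for linker in linkers:
            edges.append(gene_pair(members[0], linker))
            edges.append(gene_pair(linker, members[1]))
        return sorted(set(edges))
    raise ConfigurationError(f"unknown motif shape {shape!r}; choose from {MOTIF_SHAPES}")


def plant_network(
    db: InteractionDatabase,
    truth: SyntheticTruth,
    shape: str,
    n_list_nodes: int,
    n_linkers: int = 0,
    citation_boost: int = 10,
    seed: int = 0,
) -> tuple[InteractionDatabase, SyntheticTruth]:
    """Insert a connected motif on fresh gene IDs and record its ground truth.

    Motif edges carry ``1 + citation_boost`` citations so that, on a
    unit-citation background, the planted network outscores background noise.
    The truth entry records the exact network expected after linker expansion.
    """
    del seed  # motif wiring is deterministic; kept for interface symmetry
    index = len(truth.planted_networks) + 1
    members = [f"pl{index}m{i:02d}" for i in range(n_list_nodes)]
    linkers = [f"pl{index}x{i:02d}" for i in range(n_linkers)]
    clash = (set(members) | set(linkers)) & db.genes
    if clash:
        raise ConfigurationError(f"planted gene IDs collide with the database: {sorted(clash)}")

    citations = 1 + int(citation_boost)
    motif = _motif_edges(shape, members, linkers)
    new_edges = dict(db.edges)
    truth_edges: dict[GenePair, int] = {}
    for pair in motif:
        new_edges[pair] = EdgeData(
            interaction_classes=frozenset({"genetic"}),
            publications=_synthetic_publications(citations, f"pl{index}:{pair[0]}-{pair[1]}"),
        )
        truth_edges[pair] = citations

    genes = frozenset(db.genes | set(members) | set(linkers))
    universe = len(genes) if db.universe_is_default else max(db.universe_size, len(genes))
    new_db = InteractionDatabase(
        edges=new_edges,
        genes=genes,
        universe_size=universe,
        universe_is_default=db.universe_is_default,
    )
    entry = PlantedNetwork(
        members=frozenset(members), linkers=frozenset(linkers), edges=truth_edges
    )
    new_truth = SyntheticTruth(
        planted_networks=truth.planted_networks + [entry],
        background_params=dict(truth.background_params),
        list_spec=truth.list_spec,
        seed=truth.seed,
    )
    return new_db, new_truth


def generate_list(
    db: InteractionDatabase,
    truth: SyntheticTruth,
    list_size: int,
    planted_fraction: float = 1.0,
    seed: int = 0,
) -> GeneList:
    """Candidate list containing planted list genes, never planted linkers.

    Up to ``planted_fraction * list_size`` planted member genes are included;
    the rest is padded with genes sampled uniformly from the full synthetic
    universe (including genes without interactions, as in a real
    differential-expression list). The final order is a deterministic shuffle
    under ``seed``.
    """
    rng = np.random.default_rng(seed)
    planted_members = sorted({g for p in truth.planted_networks for g in p.members})
    planted_linkers = {g for p in truth.planted_networks for g in p.linkers}
    quota = min(len(planted_members), int(round(planted_fraction * list_size)))
    chosen = planted_members[:quota]

    n_background = int(truth.background_params.get("n_genes", 0))
    universe = {f"g{i:04d}" for i in range(n_background)} | set(db.genes)
    pool = sorted(universe - set(planted_members) - planted_linkers)
    n_pad = list_size - len(chosen)
    if n_pad < 0:
        raise ConfigurationError("list_size smaller than the planted quota")
    if n_pad > len(pool):
        raise ConfigurationError("list_size exceeds the number of available genes")
    pad = list(rng.choice(pool, size=n_pad, replace=False)) if n_pad else []
    members = chosen + [str(g) for g in pad]
    order = rng.permutation(len(members))
    return GeneList(members=tuple(members[i] for i in order), source_path="<synthetic>")


def write_truth(truth: SyntheticTruth, path: str | Path) -> None:
    """Serialise ground truth as JSON."""
    payload = {
        "seed": truth.seed,
        "background_params": truth.background_params,
        "list_spec": truth.list_spec,
        "planted_networks": [
            {
                "members": sorted(p.members),
                "linkers": sorted(p.linkers),
                "edges": [[a, b, c] for (a, b), c in sorted(p.edges.items())],
            }
            for p in truth.planted_networks
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def iis_demo_paths() -> tuple[Path, Path]:
    """Filesystem paths of the packaged IIS demo database and gene list."""
    base = resources.files("genenets.data")
    return Path(str(base.joinpath("iis_network.tsv"))), Path(str(base.joinpath("iis_genes.txt")))


def load_iis_demo() -> tuple[InteractionDatabase, GeneList]:
    """The packaged IIS demo: a six-gene network around daf-16 with linker daf-2.

    Six edges with citation counts {135, 1, 1, 1, 1, 1}: daf-16 interacts with
    daf-3, peb-1, myo-2 and daf-36 (one publication each) and with daf-2 (135
    publications); daf-2 also interacts with daf-36, making daf-2 a linker
    between daf-16 and daf-36. The candidate list holds the five genes other
    than daf-2. The exact wiring of the unit edges is one admissible choice:
    node count, edge count and score depend only on the citation multiset.
    """
    db_path, list_path = iis_demo_paths()
    records = filter_experimental(read_interaction_table(db_path))
    return build_database(records), read_gene_list(list_path)


def database_to_records_table(db: InteractionDatabase, path: str | Path) -> None:
    """Emit a database in the interaction TSV dialect (round-trip compatible)."""
    from .interaction_db import write_interaction_table

    write_interaction_table(db, path)
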