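"""Reading, filtering and canonicalising pairwise molecular-interaction tables.

The on-disk dialect is a five-column, UTF-8, tab-separated table with a header
row naming the columns ``gene_a``, ``gene_b``, ``interaction_class``
(``genetic`` or ``physical``), ``evidence_class`` (``experimental`` or
``predicted``) and ``publications`` (supporting publication identifiers joined
by ``|``; may be empty only for predicted interactions).

Canonicalisation merges duplicate unordered gene pairs by unioning their
publication sets and interaction classes, drops self-interactions, and counts
one citation per *distinct* supporting publication. Interactions that are only
computationally predicted (e.g. transferred from orthologous interactions) are
removed before any network is built; every retained edge therefore carries at
least one experimental publication.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

INTERACTION_CLASSES = frozenset({"genetic", "physical"})
EVIDENCE_CLASSES = frozenset({"experimental", "predicted"})
REQUIRED_COLUMNS = ("gene_a", "gene_b", "interaction_class", "evidence_class", "publications")

GenePair = tuple[str, str]


class TableFormatError(ValueError):
    """The interaction table violates the five-column dialect."""


class RowError(ValueError):
    """A single data row could not be parsed; the message names the line."""


class ConfigurationError(ValueError):
    """An invalid parameter combination (e.g. universe smaller than the database)."""


def gene_pair(a: str, b: str) -> GenePair:
    """Canonical unordered key for a gene pair."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class InteractionRecord:
    """One curated pairwise interaction as read from the table.

    The order of ``gene_a``/``gene_b`` carries no meaning: interactions are
    undirected. ``publications`` may be empty only for predicted evidence.
    """

    gene_a: str
    gene_b: str
    interaction_class: str
    evidence_class: str
    publications: frozenset[str]

    def __post_init__(self) -> None:
        if not self.gene_a or not self.gene_b:
            raise ValueError("gene identifiers must be non-empty")
        if self.interaction_class not in INTERACTION_CLASSES:
            raise ValueError(f"unknown interaction class {self.interaction_class!r}")
        if self.evidence_class not in EVIDENCE_CLASSES:
            raise ValueError(f"unknown evidence class {self.evidence_class!r}")
        if not self.publications and self.evidence_class == "experimental":
            raise ValueError("experimental record without supporting publications")


@dataclass(frozen=True)
class EdgeData:
    """Merged evidence for one unordered gene pair."""

    interaction_classes: frozenset[str]
    publications: frozenset[str]

    @property
    def citation_count(self) -> int:
        return len(self.publications)


@dataclass(frozen=True)
class GeneList:
    """An ordered, duplicate-free candidate gene list (e.g. differentially expressed genes).

    Order is preserved from the input file because the network search seeds
    from the first gene onward.
    """

    members: tuple[str, ...]
    source_path: str = ""

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise ValueError("gene list contains duplicates after normalisation")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.members)

    @classmethod
    def from_iterable(cls, genes: Iterable[str], source_path: str = "") -> "GeneList":
        seen: dict[str, None] = {}
        for g in genes:
            g = g.strip()
            if g and g not in seen:
                seen[g] = None
        return cls(members=tuple(seen), source_path=source_path)


@dataclass
class InteractionDatabase:
    """Deduplicated undirected edge set with citation counts.

    ``universe_size`` is the total number of genes N against which list
    enrichment is tested; it defaults to the number of genes in the database
    but can be overridden with a genome-wide count.
    """

    edges: dict[GenePair, EdgeData]
    genes: frozenset[str]
    universe_size: int
    universe_is_default: bool = True
    _adjacency: Optional[dict[str, set[str]]] = field(default=None, repr=False, compare=False)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def citation_count(self, a: str, b: str) -> int:
        return self.edges[gene_pair(a, b)].citation_count

    def citation_counts(self) -> list[int]:
        """Citation counts of all edges, in canonical pair order."""
        return [self.edges[p].citation_count for p in sorted(self.edges)]

    def neighbours(self, gene: str) -> set[str]:
        """All genes joined to ``gene`` by one database edge."""
        if self._adjacency is None:
            adj: dict[str, set[str]] = {g: set() for g in self.genes}
            for a, b in self.edges:
                adj[a].add(b)
                adj[b].add(a)
            self._adjacency = adj
        return set(self._adjacency.get(gene, set()))

    def with_universe(self, universe_size: int) -> "InteractionDatabase":
        if universe_size < len(self.genes):
            raise ConfigurationError(
                f"universe_size {universe_size} is smaller than the "
                f"{len(self.genes)} genes present in the database"
            )
        return replace(self, universe_size=universe_size, universe_is_default=False, _adjacency=None)


def normalise_gene(name: str, casefold: bool = False) -> str:
    name = name.strip()
    return name.casefold() if casefold else name


def read_interaction_table(
    path: str | Path,
    pub_delimiter: str = "|",
    lenient: bool = False,
    casefold: bool = False,
) -> list[InteractionRecord]:
    """Parse the five-column TSV dialect into interaction records.

    Rows are validated individually; by default a malformed row raises
    :class:`RowError` naming its line number, under ``lenient=True`` it is
    skipped with a warning. Deduplication happens later in
    :func:`build_database`.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise TableFormatError(f"missing required column(s): {', '.join(missing)}")

    records: list[InteractionRecord] = []
    for i, row in enumerate(frame.itertuples(index=False)):
        line_no = i + 2  # header is line 1
        pubs = frozenset(
            p.strip() for p in str(getattr(row, "publications")).split(pub_delimiter) if p.strip()
        )
        try:
            records.append(
                InteractionRecord(
                    gene_a=normalise_gene(str(getattr(row, "gene_a")), casefold),
                    gene_b=normalise_gene(str(getattr(row, "gene_b")), casefold),
                    interaction_class=str(getattr(row, "interaction_class")).strip(),
                    evidence_class=str(getattr(row, "evidence_class")).strip(),
                    publications=pubs,
                )
            )
        except ValueError as exc:
            if lenient:
                warnings.warn(f"{path.name}:{line_no}: skipped row ({exc})", stacklevel=2)
                continue
            raise RowError(f"{path.name}:{line_no}: {exc}") from exc
    return records


def filter_experimental(records: Sequence[InteractionRecord]) -> list[InteractionRecord]:
    """Drop interactions that are only computationally predicted."""
    return [r for r in records if r.evidence_class == "experimental"]


def build_database(
    records: Sequence[InteractionRecord],
    universe_size: Optional[int] = None,
) -> InteractionDatabase:
    """Merge records into a deduplicated undirected edge map.

    Self-interactions are dropped (they cannot connect two candidate genes and
    would distort neighbourhood sizes). Duplicate unordered pairs are merged by
    set union, so the citation count of an edge is the number of distinct
    supporting publications.
    """
    merged_pubs: dict[GenePair, set[str]] = {}
    merged_classes: dict[GenePair, set[str]] = {}
    for rec in records:
        if rec.gene_a == rec.gene_b:
            continue
        key = gene_pair(rec.gene_a, rec.gene_b)
        merged_pubs.setdefault(key, set()).update(rec.publications)
        merged_classes.setdefault(key, set()).update({rec.interaction_class})

    edges = {
        key: EdgeData(
            interaction_classes=frozenset(merged_classes[key]),
            publications=frozenset(pubs),
        )
        for key, pubs in merged_pubs.items()
    }
    genes = frozenset(g for pair in edges for g in pair)
    if universe_size is None:
        return InteractionDatabase(edges=edges, genes=genes, universe_size=len(genes))
    if universe_size < len(genes):
        raise ConfigurationError(
            f"universe_size {universe_size} is smaller than the {len(genes)} genes in the database"
        )
    return InteractionDatabase(
        edges=edges, genes=genes, universe_size=universe_size, universe_is_default=False
    )


def write_interaction_table(db: InteractionDatabase, path: str | Path, pub_delimiter: str = "|") -> None:
    """Serialise a database back to the TSV dialect (one row per pair and class)."""
    rows = []
    for (a, b) in sorted(db.edges):
        data = db.edges[(a, b)]
        pubs = pub_delimiter.join(sorted(data.publications))
        for klass in sorted(data.interaction_classes):
            rows.append((a, b, klass, "experimental", pubs))
    frame = pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))
    frame.to_csv(path, sep="\t", index=False)


def read_gene_list(path: str | Path, casefold: bool = False) -> GeneList:
    """Read a candidate gene list: one identifier per line, ``#`` comments ignored."""
    path = Path(path)
    genes = []
    for line in path.read_text(encoding="utf-8").splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            genes.append(normalise_gene(line, casefold))
    return GeneList.from_iterable(genes, source_path=str(path))
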