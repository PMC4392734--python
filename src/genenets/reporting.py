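"""Result serialisation: ranked table, DOT graphics, JSON report, gene lists.

Scores are rendered with two decimals (half-away-from-zero); p-values with
four decimals, with values below the permutation resolution 1/n_sim rendered
as ``<`` that bound. Full-precision values are kept in the JSON report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

from .interaction_db import gene_pair
from .network_search import Network
from .network_stats import NetworkStats, benjamini_hochberg

TABLE_COLUMNS = ("rank", "genes", "nodes", "edges", "score", "p_score", "p_list")


@dataclass(frozen=True)
class ResultRow:
    rank: int
    genes_involved: tuple[str, ...]
    n_nodes: int
    n_edges: int
    score: float
    score_pvalue: str
    list_pvalue: str


def round_half_up(value: float, decimals: int = 2) -> float:
    """Round half away from zero, as in printed result tables."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def format_pvalue(p: Optional[float], n_sim: int = 0) -> str:
    """Render a p-value at 4 decimals; below the permutation resolution as '<bound'."""
    if p is None:
        return "NA"
    if n_sim > 0:
        bound = 1.0 / n_sim
        if p < bound:
            return f"<{bound:g}" if bound < 1e-4 else f"<{bound:.4f}"
    elif p < 1e-4 and p > 0:
        return "<0.0001"
    return f"{p:.4f}"


def rows_from_results(
    networks: Sequence[Network], stats: Sequence[NetworkStats], n_sim: int
) -> list[ResultRow]:
    """Build the ranked table rows; gene order is list members first, then linkers."""
    rows = []
    for rank, (net, st) in enumerate(zip(networks, stats), start=1):
        rows.append(
            ResultRow(
                rank=rank,
                genes_involved=tuple(net.sorted_nodes()),
                n_nodes=net.n_nodes,
                n_edges=net.n_edges,
                score=round_half_up(st.score, 2),
                score_pvalue=format_pvalue(st.score_pvalue, n_sim),
                list_pvalue=format_pvalue(st.list_pvalue, n_sim),
            )
        )
    return rows


def write_results_table(rows: Sequence[ResultRow], path: str | Path) -> None:
    """Write the TSV results table (header always present)."""
    lines = ["\t".join(TABLE_COLUMNS)]
    for row in rows:
        lines.append(
            "\t".join(
                [
                    str(row.rank),
                    ", ".join(row.genes_involved),
                    str(row.n_nodes),
                    str(row.n_edges),
                    f"{row.score:.2f}",
                    row.score_pvalue,
                    row.list_pvalue,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def network_to_dot(
    n: Network,
    stats: Optional[NetworkStats] = None,
    name: str = "network",
    direction: Optional[dict[str, str]] = None,
) -> str:
    """Render one network as deterministic DOT text.

    Candidate-list genes are filled red (or blue when a per-gene direction map
    says ``down``); linker genes are white. Edges supported by a single
    publication are thin and grey; multiply-described edges are bold and
    labelled with their citation count.
    """
    direction = direction or {}
    lines = [f'graph "{name}" {{']
    if stats is not None:
        label = f"score={round_half_up(stats.score, 2):.2f}"
        lines.append(f'  label="{label}";')
    for node in sorted(n.all_nodes):
        if n.is_list_member(node):
            colour = "lightblue" if direction.get(node) == "down" else "red"
        else:
            colour = "white"
        lines.append(f'  "{node}" [style=filled, fillcolor={colour}];')
    for a, b in sorted(n.edges):
        citations = n.edges[(a, b)]
        if citations > 1:
            lines.append(f'  "{a}" -- "{b}" [style=bold, label="{citations}"];')
        else:
            lines.append(f'  "{a}" -- "{b}" [color=grey];')
    lines.append("}")
    return "\n".join(lines) + "\n"


def write_network_gene_list(n: Network, path: str | Path) -> None:
    """Plain gene-list file for one network, ready for any enrichment service."""
    Path(path).write_text("\n".join(n.sorted_nodes()) + "\n", encoding="utf-8")


def write_json_report(
    path: str | Path,
    networks: Sequence[Network],
    stats: Sequence[NetworkStats],
    config: dict,
) -> None:
    """Single machine-readable report with full-precision statistics.

    Raw list-based p-values are complemented with Benjamini–Hochberg-adjusted
    values (``list_pvalue_bh``), an extension over the per-network raw values.
    """
    bh = benjamini_hochberg([st.list_pvalue for st in stats])
    payload = {
        "config": dict(config),
        "networks": [
            {
                "rank": rank,
                "members": sorted(net.members),
                "linkers": sorted(net.linkers),
                "start_gene": net.start_gene,
                "depth": net.depth,
                "edges": [[a, b, net.edges[(a, b)]] for a, b in sorted(net.edges)],
                "stats": {
                    "score": st.score,
                    "score_pvalue": st.score_pvalue,
                    "n_simulations_used": st.n_simulations_used,
                    "induced_neighbourhood_size": st.induced_neighbourhood_size,
                    "list_overlap": st.list_overlap,
                    "list_pvalue": st.list_pvalue,
                    "list_pvalue_bh": bh[rank - 1],
                },
            }
            for rank, (net, st) in enumerate(zip(networks, stats), start=1)
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def load_json_report(path: str | Path) -> tuple[dict, list[tuple[Network, NetworkStats]]]:
    """Reload a JSON report into in-memory networks and statistics."""
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    results = []
    for entry in payload["networks"]:
        net = Network(
            members=frozenset(entry["members"]),
            linkers=frozenset(entry["linkers"]),
            edges={gene_pair(a, b): c for a, b, c in entry["edges"]},
            start_gene=entry["start_gene"],
            depth=entry["depth"],
        )
        s = entry["stats"]
        stats = NetworkStats(
            score=s["score"],
            score_pvalue=s["score_pvalue"],
            n_simulations_used=s["n_simulations_used"],
            induced_neighbourhood_size=s["induced_neighbourhood_size"],
            list_overlap=s["list_overlap"],
            list_pvalue=s["list_pvalue"],
        )
        results.append((net, stats))
    return payload["config"], results


def report_schema() -> dict:
    """The shipped JSON schema describing the report document."""
    text = resources.files("genenets.data").joinpath("report.schema.json").read_text("utf-8")
    return json.loads(text)


def validate_report(document: dict, schema: Optional[dict] = None, _path: str = "$") -> None:
    """Structural validation against the shipped schema (type/required/properties/items).

    Raises ``ValueError`` naming the offending path. Covers the subset of JSON
    Schema the report schema uses.
    """
    if schema is None:
        schema = report_schema()
    expected = schema.get("type")
    type_map = {
        "object": dict,
        "array": list,
        "string": str,
        "integer": int,
        "number": (int, float),
        "boolean": bool,
    }
    if expected is not None:
        allowed = expected if isinstance(expected, list) else [expected]
        if document is None:
            if "null" not in allowed:
                raise ValueError(f"{_path}: null not permitted")
        else:
            ok = any(
                isinstance(document, type_map[t]) and not (t in ("integer", "number") and isinstance(document, bool))
                for t in allowed
                if t != "null"
            )
            if not ok:
                raise ValueError(f"{_path}: expected {expected}, got {type(document).__name__}")
    if isinstance(document, dict):
        for key in schema.get("required", []):
            if key not in document:
                raise ValueError(f"{_path}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in document:
                validate_report(document[key], sub, f"{_path}.{key}")
    if isinstance(document, list) and "items" in schema:
        for i, item in enumerate(document):
            validate_report(item, schema["items"], f"{_path}[{i}]")
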