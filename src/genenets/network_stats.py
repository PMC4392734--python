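"""Statistical assessment of discovered networks.

Two complementary tests are computed per network:

* The **network score** is the mean number of distinct publications (citations)
  supporting its edges — a measure of the strength of experimental evidence.
  Its **score-based p-value** comes from a permutation null: the score is
  recomputed for randomly simulated networks and the p-value is the fraction
  of simulated scores at least as large as the observed one. The default null
  draws |E_N| edges uniformly without replacement from the database's
  experimental edge set; this preserves the only quantity the score uses (the
  edge count) and is exactly enumerable on small databases. A
  connectivity-preserving variant is available behind a flag.

* The **list-based p-value** asks whether candidate-list genes are
  over-represented in the network's induced 1-neighbourhood N¹ (every database
  gene at distance one from a network node, together with the network's own
  nodes). Under the null that list membership is independent of N¹, the
  overlap k = |N¹ ∩ L| is hypergeometric with parameters N (gene universe),
  |N¹| and |L|, and the p-value is the upper tail P(X >= k).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Optional

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .interaction_db import GeneList, InteractionDatabase

if TYPE_CHECKING:  # circular at runtime only
    from .network_search import Network, SearchConfig


class UndefinedScoreError(ValueError):
    """A network without edges has no score."""


class SimulationError(ValueError):
    """The database is too small to simulate networks of the requested size."""


@dataclass(frozen=True)
class NetworkStats:
    """Score and significance summary for one network."""

    score: float
    score_pvalue: Optional[float]
    n_simulations_used: int
    induced_neighbourhood_size: int
    list_overlap: int
    list_pvalue: float


def network_score(n: "Network") -> float:
    """Mean citation count over the network's edges."""
    if n.n_edges == 0:
        raise UndefinedScoreError("network has no edges; score undefined")
    return float(np.mean(list(n.edges.values())))


def simulate_null_scores(
    db: InteractionDatabase,
    n_edges: int,
    n_sim: int,
    seed: int,
    connected: bool = False,
) -> np.ndarray:
    """Scores of ``n_sim`` randomly simulated networks of ``n_edges`` edges."""
    if n_edges < 1:
        raise SimulationError("cannot simulate networks without edges")
    if db.n_edges < n_edges:
        raise SimulationError(
            f"database has {db.n_edges} edges; cannot draw networks of {n_edges} edges"
        )
    rng = np.random.default_rng(seed)
    if connected:
        return _simulate_connected(db, n_edges, n_sim, rng)
    counts = np.asarray(db.citation_counts(), dtype=float)
    n_db = counts.size
    # chunked argsort sampling: each row is a uniform draw without replacement
    chunk = max(1, int(2e7 // max(n_db, 1)))
    out = np.empty(n_sim, dtype=float)
    done = 0
    while done < n_sim:
        size = min(chunk, n_sim - done)
        idx = np.argsort(rng.random((size, n_db)), axis=1)[:, :n_edges]
        out[done : done + size] = counts[idx].mean(axis=1)
        done += size
    return out


def _simulate_connected(
    db: InteractionDatabase, n_edges: int, n_sim: int, rng: np.random.Generator
) -> np.ndarray:
    """Grow a random connected edge set of the requested size per replicate."""
    pairs = sorted(db.edges)
    scores = np.empty(n_sim, dtype=float)
    for i in range(n_sim):
        for _attempt in range(100):
            start = pairs[rng.integers(len(pairs))]
            chosen = {start}
            nodes = set(start)
            while len(chosen) < n_edges:
                frontier = [
                    (g, nb)
                    for g in nodes
                    for nb in db.neighbours(g)
                    if (min(g, nb), max(g, nb)) not in chosen
                ]
                if not frontier:
                    break
                g, nb = frontier[rng.integers(len(frontier))]
                chosen.add((min(g, nb), max(g, nb)))
                nodes.add(nb)
            if len(chosen) == n_edges:
                break
        else:
            raise SimulationError("could not grow a connected simulated network")
        scores[i] = float(np.mean([db.edges[p].citation_count for p in chosen]))
    return scores


def score_pvalue(
    n: "Network",
    db: InteractionDatabase,
    n_sim: int,
    seed: int,
    add_one: bool = False,
    connected: bool = False,
) -> float:
    """Fraction of simulated network scores at least as large as the observed score.

    The literal estimator (default) can return 0; ``add_one=True`` applies the
    (#exceedances + 1) / (n_sim + 1) correction.
    """
    observed = network_score(n)
    sims = simulate_null_scores(db, n.n_edges, n_sim, seed, connected=connected)
    hits = int(np.count_nonzero(sims >= observed - 1e-12))
    if add_one:
        return (hits + 1) / (n_sim + 1)
    return hits / n_sim


def induced_neighbourhood(
    n: "Network", db: InteractionDatabase, include_network: bool = True
) -> set[str]:
    """The induced sub-network N¹: database genes one edge away from any network node.

    Every member of a connected network with at least one edge is itself the
    1-neighbour of a partner node, so the network's own nodes belong to N¹;
    ``include_network=False`` restricts to strict outsiders.
    """
    out: set[str] = set()
    for node in n.all_nodes:
        out |= db.neighbours(node)
    if include_network:
        out |= set(n.all_nodes)
    else:
        out -= set(n.all_nodes)
    return out


def hypergeometric_pmf(k: int, universe: int, neighbourhood: int, list_size: int) -> float:
    """P(X = k) for X ~ Hypergeom(N=universe, |N¹|=neighbourhood, |L|=list_size)."""
    _check_hypergeom_args(k, universe, neighbourhood, list_size)
    return float(hypergeom.pmf(k, universe, neighbourhood, list_size))


def list_pvalue(k: int, universe: int, neighbourhood: int, list_size: int) -> float:
    """Upper-tail P(X >= k): probability of at least k list genes inside N¹ by chance."""
    _check_hypergeom_args(k, universe, neighbourhood, list_size)
    return float(hypergeom.sf(k - 1, universe, neighbourhood, list_size))


def _check_hypergeom_args(k: int, universe: int, neighbourhood: int, list_size: int) -> None:
    if universe < 1:
        raise ValueError("universe size must be positive")
    if not (0 <= neighbourhood <= universe):
        raise ValueError("neighbourhood size must lie in [0, universe]")
    if not (0 <= list_size <= universe):
        raise ValueError("list size must lie in [0, universe]")
    if not (0 <= k <= min(neighbourhood, list_size)):
        raise ValueError("k must lie in [0, min(neighbourhood, list size)]")


def effective_list_size(db: InteractionDatabase, gene_list: GeneList) -> int:
    """Number of candidate genes that are members of the test universe.

    With the default universe (the genes of the database itself) candidate
    genes absent from the database are outside the universe and are not
    counted; with an explicit genome-wide universe the whole list counts.
    """
    if db.universe_is_default:
        return len(set(gene_list.members) & db.genes)
    return len(set(gene_list.members))


def list_enrichment_pvalue_for(
    n: "Network", db: InteractionDatabase, gene_list: GeneList
) -> float:
    """Convenience wrapper: list-based p-value of one network against the database."""
    hood = induced_neighbourhood(n, db)
    k = len(hood & set(gene_list.members))
    return list_pvalue(k, db.universe_size, len(hood), effective_list_size(db, gene_list))


def evaluate_network(
    n: "Network",
    db: InteractionDatabase,
    gene_list: GeneList,
    cfg: "SearchConfig",
    connected_null: bool = False,
) -> NetworkStats:
    """Compute the full statistics record for one network.

    With ``cfg.n_simulations == 0`` the permutation test is skipped and the
    score-based p-value is reported as not computed (``None``).
    """
    score = network_score(n)
    if cfg.n_simulations > 0:
        p_score: Optional[float] = score_pvalue(
            n, db, cfg.n_simulations, cfg.random_seed, connected=connected_null
        )
    else:
        p_score = None
    hood = induced_neighbourhood(n, db)
    k = len(hood & set(gene_list.members))
    p_list = list_pvalue(k, db.universe_size, len(hood), effective_list_size(db, gene_list))
    return NetworkStats(
        score=score,
        score_pvalue=p_score,
        n_simulations_used=cfg.n_simulations,
        induced_neighbourhood_size=len(hood),
        list_overlap=k,
        list_pvalue=p_list,
    )


def benjamini_hochberg(pvalues: list[float]) -> list[float]:
    """BH-adjusted p-values (an extension over the raw per-network values)."""
    if not pvalues:
        return []
    return list(multipletests(pvalues, method="fdr_bh")[1])
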