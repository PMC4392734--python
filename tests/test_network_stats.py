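from __future__ import annotations

import numpy as np
import pytest

from genenets.graph_builder import build_basic_graph
from genenets.interaction_db import GeneList
from genenets.network_search import Network, SearchConfig, expand_network, find_networks
from genenets.network_stats import (
    SimulationError,
    UndefinedScoreError,
    benjamini_hochberg,
    evaluate_network,
    hypergeometric_pmf,
    induced_neighbourhood,
    list_pvalue,
    network_score,
    score_pvalue,
)
from genenets.synthetic_data import ConstantCitations, generate_database, generate_list, plant_network

from conftest import db_from_pairs
from oracles import (
    exact_score_pvalue,
    hypergeom_pmf_enumeration,
    hypergeom_tail_by_summation,
)


def make_network(edge_triples, members=None):
    edges = {(min(a, b), max(a, b)): c for a, b, c in edge_triples}
    nodes = {g for pair in edges for g in pair}
    members = frozenset(members) if members is not None else frozenset(nodes)
    return Network(members=members, linkers=frozenset(nodes - members), edges=edges)


class TestNetworkScore:
    def test_iis_citation_multiset_scores_23_33(self):
        net = make_network(
            [("a", "b", 135), ("a", "c", 1), ("a", "d", 1), ("a", "e", 1), ("a", "f", 1), ("b", "f", 1)]
        )
        assert round(network_score(net), 2) == 23.33

    def test_single_unit_edge_scores_one(self):
        assert network_score(make_network([("a", "b", 1)])) == 1.0

    def test_mean_of_two_edges(self):
        assert network_score(make_network([("a", "b", 3), ("b", "c", 5)])) == 4.0

    def test_zero_edges_is_undefined(self):
        net = Network(members=frozenset({"a", "b"}), linkers=frozenset(), edges={})
        with pytest.raises(UndefinedScoreError):
            network_score(net)


class TestScorePvalue:
    def test_all_unit_citation_database_gives_exactly_one(self):
        db = db_from_pairs([("a", "b", 1), ("b", "c", 1), ("c", "d", 1)])
        net = make_network([("a", "b", 1), ("b", "c", 1)])
        assert score_pvalue(net, db, n_sim=500, seed=4) == 1.0

    def test_single_strong_edge_matches_exact_quarter(self):
        db = db_from_pairs([("a", "b", 9), ("c", "d", 1), ("e", "f", 1), ("g", "h", 1)])
        net = make_network([("a", "b", 9)])
        exact = exact_score_pvalue([9, 1, 1, 1], 1, 9.0)
        assert exact == 0.25
        p = score_pvalue(net, db, n_sim=10_000, seed=8)
        se = np.sqrt(exact * (1 - exact) / 10_000)
        assert abs(p - exact) <= 3 * se

    def test_monte_carlo_matches_enumeration_on_small_databases(self):
        rng = np.random.default_rng(23)
        for case in range(10):
            n_edges_db = int(rng.integers(4, 9))
            counts = [int(rng.integers(1, 10)) for _ in range(n_edges_db)]
            pairs = [(f"a{i}", f"b{i}", c) for i, c in enumerate(counts)]
            db = db_from_pairs(pairs)
            m = int(rng.integers(1, 4))
            chosen = list(rng.choice(n_edges_db, size=m, replace=False))
            net = make_network([pairs[i] for i in chosen])
            exact = exact_score_pvalue(counts, m, network_score(net))
            p = score_pvalue(net, db, n_sim=10_000, seed=100 + case)
            se = np.sqrt(exact * (1 - exact) / 10_000)
            assert abs(p - exact) <= 4 * se + 1e-12

    def test_add_one_correction_never_returns_zero(self):
        db = db_from_pairs([("a", "b", 50), ("c", "d", 1), ("e", "f", 1)])
        net = make_network([("a", "b", 50), ("c", "d", 1)])
        # enumeration: only {50,1} subsets reach the observed mean 25.5 -> p=2/3... exact check:
        exact = exact_score_pvalue([50, 1, 1], 2, 25.5)
        p_plain = score_pvalue(net, db, n_sim=100, seed=1)
        p_corrected = score_pvalue(net, db, n_sim=100, seed=1, add_one=True)
        assert p_corrected > 0
        assert abs(p_plain - exact) < 0.2

    def test_database_smaller_than_network_cannot_simulate(self):
        db = db_from_pairs([("a", "b", 1)])
        net = make_network([("a", "b", 1), ("b", "c", 1)])
        with pytest.raises(SimulationError):
            score_pvalue(net, db, n_sim=10, seed=0)

    def test_reproducible_under_seed(self):
        db = db_from_pairs([(f"a{i}", f"b{i}", i + 1) for i in range(6)])
        net = make_network([("a3", "b3", 4), ("a4", "b4", 5)])
        assert score_pvalue(net, db, 2000, seed=42) == score_pvalue(net, db, 2000, seed=42)

    def test_connected_null_variant_runs_and_agrees_on_degenerate_database(self):
        db = db_from_pairs([("a", "b", 1), ("b", "c", 1), ("c", "d", 1)])
        net = make_network([("a", "b", 1), ("b", "c", 1)])
        assert score_pvalue(net, db, n_sim=200, seed=3, connected=True) == 1.0


class TestInducedNeighbourhood:
    def test_extends_one_database_edge_beyond_the_network(self):
        db = db_from_pairs([("a", "b", 1), ("b", "c", 1)])
        net = make_network([("a", "b", 1)])
        assert induced_neighbourhood(net, db) == {"a", "b", "c"}

    def test_isolated_component_is_its_own_closure(self):
        db = db_from_pairs([("a", "b", 1), ("x", "y", 1)])
        net = make_network([("a", "b", 1)])
        assert induced_neighbourhood(net, db) == {"a", "b"}

    def test_star_hub_pulls_in_all_spokes(self):
        db = db_from_pairs([("h", f"x{i}", 1) for i in range(1, 6)])
        net = make_network([("h", "x1", 1)])
        assert induced_neighbourhood(net, db) == {"h", "x1", "x2", "x3", "x4", "x5"}

    def test_exclude_network_option_keeps_only_outsiders(self):
        db = db_from_pairs([("a", "b", 1), ("b", "c", 1)])
        net = make_network([("a", "b", 1)])
        assert induced_neighbourhood(net, db, include_network=False) == {"c"}


class TestHypergeometric:
    def test_saturated_neighbourhood_forces_full_overlap(self):
        assert hypergeometric_pmf(3, 10, 10, 3) == pytest.approx(1.0)

    def test_pmf_matches_subset_enumeration(self):
        assert hypergeometric_pmf(2, 10, 4, 5) == pytest.approx(
            hypergeom_pmf_enumeration(2, 10, 4, 5), abs=1e-12
        )

    def test_pmf_normalises_to_one(self):
        for universe, hood, lst in [(10, 4, 5), (50, 12, 20), (200, 30, 60)]:
            total = sum(
                hypergeometric_pmf(k, universe, hood, lst) for k in range(min(hood, lst) + 1)
            )
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            hypergeometric_pmf(5, 10, 4, 4)  # k beyond support
        with pytest.raises(ValueError):
            hypergeometric_pmf(1, 10, 11, 4)  # neighbourhood beyond universe
        with pytest.raises(ValueError):
            list_pvalue(1, 10, 4, 11)

    def test_tail_at_zero_is_one(self):
        assert list_pvalue(0, 30, 7, 9) == pytest.approx(1.0)

    def test_tail_at_support_end_is_single_pmf_term(self):
        k = min(6, 8)
        assert list_pvalue(k, 20, 6, 8) == pytest.approx(hypergeometric_pmf(k, 20, 6, 8))

    def test_tail_matches_term_by_term_summation(self):
        assert list_pvalue(4, 20, 6, 8) == pytest.approx(
            hypergeom_tail_by_summation(4, 20, 6, 8), rel=1e-12
        )

    def test_tail_is_monotone_nonincreasing_in_k(self):
        for universe, hood, lst in [(20, 6, 8), (100, 25, 40)]:
            values = [list_pvalue(k, universe, hood, lst) for k in range(min(hood, lst) + 1)]
            assert all(a >= b - 1e-12 for a, b in zip(values, values[1:]))

    def test_pvalue_is_superuniform_under_random_lists(self):
        """With the list drawn uniformly from the universe, P(p <= alpha) <= alpha
        (up to Monte-Carlo error)."""
        rng = np.random.default_rng(31)
        universe, hood, lst = 100, 10, 15
        n_draws = 10_000
        marked = set(range(hood))
        pvals = np.empty(n_draws)
        for i in range(n_draws):
            draw = rng.choice(universe, size=lst, replace=False)
            k = len(marked.intersection(draw))
            pvals[i] = list_pvalue(k, universe, hood, lst)
        for alpha in (0.01, 0.05):
            frac = float(np.mean(pvals <= alpha))
            se = np.sqrt(alpha * (1 - alpha) / n_draws)
            assert frac <= alpha + 3 * se


class TestEvaluateNetwork:
    def test_skip_mode_reports_score_only(self, iis_demo):
        db, gl = iis_demo
        g = build_basic_graph(db, gl)
        net = expand_network(g, set(gl.members))
        stats = evaluate_network(net, db, gl, SearchConfig(random_seed=0, n_simulations=0))
        assert round(stats.score, 2) == 23.33
        assert stats.score_pvalue is None
        assert stats.n_simulations_used == 0

    def test_all_unit_citation_network_is_fully_degenerate(self):
        db = db_from_pairs([("a", "b", 1), ("b", "c", 1), ("c", "d", 1)])
        gl = GeneList.from_iterable(["a", "b", "c", "d"])
        g = build_basic_graph(db, gl)
        cfg = SearchConfig(random_seed=5, max_depth=2, n_simulations=300)
        (net, *_) = find_networks(g, gl, cfg)
        stats = evaluate_network(net, db, gl, cfg)
        assert stats.score == 1.0 and stats.score_pvalue == 1.0

    def test_overlap_never_exceeds_neighbourhood_or_list(self, iis_demo):
        db, gl = iis_demo
        g = build_basic_graph(db, gl)
        net = expand_network(g, set(gl.members))
        stats = evaluate_network(net, db, gl, SearchConfig(random_seed=0, n_simulations=0))
        assert stats.list_overlap <= min(stats.induced_neighbourhood_size, len(gl))

    def test_planted_enrichment_is_detected_in_most_replicates(self):
        """The planted motif's list p-value falls below 0.01 in >= 95 of 100
        seeded replicates on a sparse background."""
        hits = 0
        for seed in range(100):
            db, truth = generate_database(120, 0.01, ConstantCitations(1), seed=seed)
            db, truth = plant_network(db, truth, "path", n_list_nodes=4, n_linkers=1,
                                      citation_boost=10, seed=seed)
            gl = generate_list(db, truth, list_size=12, planted_fraction=1.0, seed=seed + 1)
            planted = truth.planted_networks[0]
            net = Network(members=planted.members, linkers=planted.linkers,
                          edges=dict(planted.edges))
            stats = evaluate_network(net, db, gl, SearchConfig(random_seed=0, n_simulations=0))
            if stats.list_pvalue < 0.01:
                hits += 1
        assert hits >= 95


def test_benjamini_hochberg_is_monotone_and_bounded():
    raw = [0.001, 0.02, 0.04, 0.5, 0.9]
    adj = benjamini_hochberg(raw)
    assert len(adj) == len(raw)
    assert all(0 <= p <= 1 for p in adj)
    assert all(a >= r for a, r in zip(adj, raw))
    assert benjamini_hochberg([]) == []
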