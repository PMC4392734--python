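from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from genenets.interaction_db import (
    GeneList,
    InteractionRecord,
    build_database,
)
from genenets.synthetic_data import load_iis_demo


@pytest.fixture(scope="session")
def iis_demo():
    """The packaged six-edge IIS demo: (database, candidate list)."""
    return load_iis_demo()


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_record(a, b, pubs, klass="physical", evidence="experimental"):
    return InteractionRecord(
        gene_a=a,
        gene_b=b,
        interaction_class=klass,
        evidence_class=evidence,
        publications=frozenset(pubs),
    )


def db_from_pairs(pairs_with_counts, universe_size=None):
    """Build a database from [(a, b, n_citations), ...] with synthetic publication IDs."""
    records = [
        make_record(a, b, {f"{a}-{b}:{i}" for i in range(n)}) for a, b, n in pairs_with_counts
    ]
    return build_database(records, universe_size=universe_size)


def random_db(rng, n_genes, edge_probability, max_citations=5, universe_size=None):
    """Small random database for oracle comparisons (independent of synthetic_data)."""
    genes = [f"n{i}" for i in range(n_genes)]
    triples = []
    for i in range(n_genes):
        for j in range(i + 1, n_genes):
            if rng.random() < edge_probability:
                triples.append((genes[i], genes[j], int(rng.integers(1, max_citations + 1))))
    return db_from_pairs(triples, universe_size=universe_size), genes


@pytest.fixture
def gene_list_factory():
    def make(genes):
        return GeneList.from_iterable(genes)

    return make
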