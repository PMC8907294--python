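import random
from pathlib import Path

import pytest

from ontosim.obo_graph import OntologyGraph, RelationType, Term
from ontosim.synth_fixtures import SyntheticOntologySpec, make_random_dag, make_toy_ontology

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def toy5():
    """R <- {C1, C2}; C1 <- {A, B}; all is_a."""
    return make_toy_ontology()


@pytest.fixture(scope="session")
def toy6():
    """Toy graph plus D below both A and B."""
    return make_toy_ontology(include_descendant=True)


@pytest.fixture(scope="session")
def diamond():
    """X is_a P1, X is_a P2, P1 is_a R, P2 is_a P1 — two root paths."""
    ns = "molecular_function"
    terms = [Term(t, t, ns) for t in ["R", "P1", "P2", "X"]]
    edges = [
        ("X", "P1", RelationType.IS_A),
        ("X", "P2", RelationType.IS_A),
        ("P1", "R", RelationType.IS_A),
        ("P2", "P1", RelationType.IS_A),
    ]
    return OntologyGraph(terms, edges)


def random_dag(seed, max_layers=5, max_per_layer=6):
    """Seeded random layered DAG with mixed edge types (<= 31 nodes)."""
    rnd = random.Random(seed)
    spec = SyntheticOntologySpec(
        n_layers=rnd.randint(2, max_layers),
        terms_per_layer=rnd.randint(2, max_per_layer),
        edge_density=rnd.uniform(0.1, 0.5),
        seed=seed,
    )
    return make_random_dag(spec)


def term_pairs(g, seed, k):
    """k seeded term pairs (with replacement across draws, a==b allowed)."""
    rnd = random.Random(seed)
    nodes = sorted(g.terms)
    return [(rnd.choice(nodes), rnd.choice(nodes)) for _ in range(k)]
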