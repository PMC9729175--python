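import numpy as np
import pandas as pd
import pytest

from emrgraph.bipartite import BipartiteGraph, FeatureSchema, build_bipartite, build_features
from emrgraph.cohort import CohortCriteria, label_outcome, select_cohort
from emrgraph.datasets import journey_demo_tables
from emrgraph.synthetic import GeneratorConfig, generate_emr


@pytest.fixture(scope="session")
def journey_tables():
    return journey_demo_tables()


@pytest.fixture(scope="session")
def journey_cohort(journey_tables):
    cohort = select_cohort(journey_tables, CohortCriteria())
    return label_outcome(cohort, journey_tables.events)


@pytest.fixture(scope="session")
def small_tables():
    """300 generated patients, enough for structural tests."""
    return generate_emr(GeneratorConfig(n_patients=300, seed=13))


@pytest.fixture(scope="session")
def small_cohort(small_tables):
    return label_outcome(select_cohort(small_tables), small_tables.events)


@pytest.fixture(scope="session")
def small_bipartite(small_cohort, small_tables):
    pat, diag = build_features(small_cohort, small_tables, FeatureSchema())
    return build_bipartite(small_cohort, pat, diag)


@pytest.fixture(scope="session")
def large_cohort_50k():
    """Labeled cohort from 50,000 generated patients at default settings."""
    tables = generate_emr(GeneratorConfig(n_patients=50_000, seed=50))
    return label_outcome(select_cohort(tables), tables.events)


def random_bipartite(rng, n_patients=None, n_diag=None, dp=3, dd=4) -> BipartiteGraph:
    """Small random bipartite multigraph for fuzz tests."""
    P = n_patients or int(rng.integers(2, 9))
    D = n_diag or int(rng.integers(1, 6))
    pat = pd.DataFrame(rng.normal(size=(P, dp)), index=[f"p_{i}" for i in range(P)])
    diag = pd.DataFrame(rng.normal(size=(D, dd)), index=[f"d_{i}" for i in range(D)])
    n_edges = int(rng.integers(P, P + 6))
    src = [f"p_{i}" for i in range(P)] + [f"p_{int(rng.integers(0, P))}" for _ in range(n_edges - P)]
    tgt = [f"d_{int(rng.integers(0, D))}" for _ in range(n_edges)]
    edges = pd.DataFrame({"source": src, "target": tgt, "outcome": rng.integers(0, 2, size=n_edges)})
    graph = BipartiteGraph(pat, diag, edges)
    graph.validate()
    return graph
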