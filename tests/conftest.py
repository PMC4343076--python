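import numpy as np
import pytest

from annsim import GeneratorConfig, gen_annotations, gen_ontology


def random_dag_edges(rng, n_nodes, max_parents=2):
    """Small random single-root DAG as a (child, parent) edge list."""
    edges = []
    for i in range(1, n_nodes):
        k = min(int(rng.integers(1, max_parents + 1)), i)
        for p in sorted(int(q) for q in rng.choice(i, size=k, replace=False)):
            edges.append((f"n{i:02d}", f"n{p:02d}"))
    return edges


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_annotation_graph():
    cfg = GeneratorConfig(seed=11, n_terms=80, n_entities=12,
                          annotation_size_range=(1, 6))
    G = gen_ontology(cfg)
    return gen_annotations(G, cfg)
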