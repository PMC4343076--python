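"""Fixed, bit-reproducible worked-example fixtures.

Four tiny configurations whose expected values are known in closed form;
they double as documentation of what each measure rewards:

* :func:`deep_lca_fixture` -- a chain with two length-2 branches below a
  shared ancestor at root distance 3; the pair scores 0.60 under
  ``1 - d_tax`` and 0.43 under ``1 - d_ps`` (2 d.p.).
* :func:`shortcut_fixture` -- siblings under an LCA one edge above each,
  with a shortcut making the root distances 4 and 3; ``1 - d_tax`` is
  1 - 2/7 = 0.714 (3 d.p.).
* :func:`disjoint_hetero_fixture` -- two entities with disjoint term
  sets (sizes 3 and 7); HeteSim along (annotates, identity,
  annotated_by) is exactly 0.0, however close the terms may sit in an
  ontology.
* :func:`gold_standard_clustering_fixture` -- entities clustered
  together exactly when their category sets are identical; the average
  Category-based Score is 1.0 by construction.
"""

from __future__ import annotations

from .hetesim import HeteroGraph, RelevancePath
from .ontology import OntologyDAG
from .synthetic import GeneratorConfig, clustering_from_categories, gen_categories

__all__ = [
    "deep_lca_fixture",
    "shortcut_fixture",
    "disjoint_hetero_fixture",
    "gold_standard_clustering_fixture",
    "reference_fixtures",
]


def deep_lca_fixture() -> tuple[OntologyDAG, str, str]:
    """Chain root->v1->v2->L with branches L->x1->x and L->y1->y.

    Returns ``(ontology, "x", "y")``.  Geometry: lca(x, y) = L,
    d(L, x) = d(L, y) = 2, d(root, x) = d(root, y) = 5, d(root, L) = 3,
    hence d_tax = 4/10 and d_ps = 1 - 3/7.
    """
    edges = [
        ("v1", "root"), ("v2", "v1"), ("L", "v2"),
        ("x1", "L"), ("x", "x1"),
        ("y1", "L"), ("y", "y1"),
    ]
    return OntologyDAG(edges), "x", "y"


def shortcut_fixture() -> tuple[OntologyDAG, str, str]:
    """Chain root->a->b->L with leaves L->x, L->y and a shortcut b->y.

    Returns ``(ontology, "x", "y")``.  Geometry: lca(x, y) = L (depth 3),
    d(L, x) = d(L, y) = 1, d(root, x) = 4 but d(root, y) = 3 via the
    shortcut, hence d_tax = 2/7 and 1 - d_tax = 0.714 at 3 d.p.
    """
    edges = [
        ("a", "root"), ("b", "a"), ("L", "b"),
        ("x", "L"), ("y", "L"), ("y", "b"),
    ]
    return OntologyDAG(edges), "x", "y"


def disjoint_hetero_fixture() -> tuple[HeteroGraph, str, str, RelevancePath]:
    """Two entities with disjoint annotation sets of sizes 3 and 7.

    Returns ``(graph, "s", "t", path)`` with the annotation meta-path
    (annotates, identity, annotated_by).  The walkers can never meet at
    a shared term, so HeteSim(s, t) = 0.0 exactly.
    """
    s_terms = [f"S{i}" for i in range(3)]
    t_terms = [f"U{i}" for i in range(7)]
    ann = {"s": s_terms, "t": t_terms}

    class _Raw:  # minimal annotation mapping; no ontology needed here
        @staticmethod
        def items():
            return ann.items()

    H = HeteroGraph.from_annotation_graph(_Raw())
    path = RelevancePath(["annotates", "identity", "annotated_by"], H)
    return H, "s", "t", path


def gold_standard_clustering_fixture(
    seed: int = 0,
) -> tuple[dict[str, frozenset[str]], dict[str, str]]:
    """Twenty entities, seeded random category sets, identical-set clustering.

    Returns ``(categories, clustering)``.  The clustering groups entities
    exactly when their category sets are identical, so it contains at
    least one multi-member cluster (guaranteed by the generator) and
    typically many singletons; its average Category-based Score is 1.0.
    """
    cfg = GeneratorConfig(seed=seed, n_entities=20, n_categories=12,
                          category_sets_per_entity=(1, 3), n_families=4)
    categories = gen_categories(cfg)
    return categories, clustering_from_categories(categories)


def reference_fixtures() -> dict[str, tuple]:
    """All fixed fixtures keyed by short names."""
    return {
        "deep_lca": deep_lca_fixture(),
        "shortcut": shortcut_fixture(),
        "disjoint_hetero": disjoint_hetero_fixture(),
        "gold_standard_clustering": gold_standard_clustering_fixture(),
    }
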