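"""Seeded synthetic ontologies, annotation graphs, categories and features.

Every generator is a pure function of a :class:`GeneratorConfig` (seed
included): identical configs give bit-identical outputs, and no global
random state is touched.  Scales are desk-scale by default -- a few
hundred terms and a few dozen entities -- standing in for real
controlled vocabularies (tens of thousands to hundreds of thousands of
terms) whose *shape* is emulated: a single root, limited multiple
inheritance, a guaranteed backbone depth, and per-entity annotation
counts spanning an order of magnitude.

Entity "families" make relatedness structure controllable: each family
owns a focus subtree of the ontology and, with probability
``family_bias``, a family member draws its annotation terms from that
subtree.  Families with ``family_bias`` near 1 therefore contain entities
that an annotation-aware similarity should score as mutually close,
while cross-family pairs stay distant -- a miniature analogue of drug
families annotated with related diseases.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .annotation import AnnotationGraph
from .errors import AnnSimError
from .ontology import OntologyDAG

__all__ = [
    "GeneratorConfig",
    "gen_ontology",
    "gen_annotations",
    "gen_entity_families",
    "gen_categories",
    "clustering_from_categories",
    "gen_features",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs for the synthetic generators (all outputs are seed-determined).

    Parameters mirror the shape of realistic annotation studies at desk
    scale: ``n_terms`` ontology terms with up to ``max_parents`` parents
    each and a backbone of ``target_depth`` edges; ``n_entities`` entities
    whose annotation-set sizes are uniform on ``annotation_size_range``
    (real annotation counts span 1 to 100+; the default 1..12 keeps the
    same order-of-magnitude spread); ``n_categories`` category labels
    with ``category_sets_per_entity`` labels per entity.
    """

    seed: int = 0
    n_terms: int = 200
    max_parents: int = 2
    target_depth: int = 8
    n_entities: int = 24
    annotation_size_range: tuple[int, int] = (1, 12)
    n_categories: int = 10
    category_sets_per_entity: tuple[int, int] = (1, 3)
    n_families: int = 3
    family_bias: float = 0.9

    def __post_init__(self):
        counts = {
            "n_terms": self.n_terms,
            "max_parents": self.max_parents,
            "target_depth": self.target_depth,
            "n_entities": self.n_entities,
            "n_categories": self.n_categories,
            "n_families": self.n_families,
        }
        for name, value in counts.items():
            if value < 1:
                raise AnnSimError(f"{name} must be positive, got {value}")
        if self.n_terms < 2:
            raise AnnSimError("an ontology needs at least 2 terms (root + child)")
        for name in ("annotation_size_range", "category_sets_per_entity"):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi):
                raise AnnSimError(f"{name} must satisfy 1 <= min <= max, got {(lo, hi)}")
        if not 0.0 <= self.family_bias <= 1.0:
            raise AnnSimError("family_bias must lie in [0, 1]")

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=seed)


def _rng(cfg: GeneratorConfig, stream: int) -> np.random.Generator:
    # Independent, reproducible streams per generator.
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, stream]))


def _term_id(i: int) -> str:
    return f"T{i:04d}"


def gen_ontology(cfg: GeneratorConfig) -> OntologyDAG:
    """Generate a single-root DAG of ``cfg.n_terms`` terms.

    Term ``T0000`` is the root.  A backbone chain of
    ``min(target_depth, n_terms - 1)`` terms guarantees depth; every
    remaining term draws 1..``max_parents`` distinct parents uniformly
    from strictly earlier terms, so the graph is acyclic by construction
    and every term reaches the root.
    """
    rng = _rng(cfg, 0)
    edges: list[tuple[str, str]] = []
    backbone = min(cfg.target_depth, cfg.n_terms - 1)
    for i in range(1, backbone + 1):
        edges.append((_term_id(i), _term_id(i - 1)))
    for i in range(backbone + 1, cfg.n_terms):
        k = int(rng.integers(1, cfg.max_parents + 1))
        k = min(k, i)
        parents = rng.choice(i, size=k, replace=False)
        for p in sorted(int(p) for p in parents):
            edges.append((_term_id(i), _term_id(p)))
    return OntologyDAG(edges)


def _entity_id(i: int) -> str:
    return f"E{i:03d}"


def gen_entity_families(cfg: GeneratorConfig) -> dict[str, int]:
    """Deterministic entity -> family assignment (round-robin)."""
    return {_entity_id(i): i % cfg.n_families for i in range(cfg.n_entities)}


def _family_subtrees(G: OntologyDAG, cfg: GeneratorConfig,
                     rng: np.random.Generator) -> list[list[str]]:
    """Pick one focus term per family whose subtree can cover a full annotation set."""
    _, size_max = cfg.annotation_size_range
    candidates = [
        t for t in sorted(G.terms)
        if len(G.descendants(t)) >= size_max and len(G.descendants(t)) < len(G)
    ]
    if not candidates:  # tiny ontologies: fall back to the whole vocabulary
        return [sorted(G.terms) for _ in range(cfg.n_families)]
    picks = rng.choice(len(candidates), size=cfg.n_families, replace=True)
    return [sorted(G.descendants(candidates[int(p)])) for p in picks]


def gen_annotations(G: OntologyDAG, cfg: GeneratorConfig) -> AnnotationGraph:
    """Generate seeded annotations, biased toward per-family focus subtrees.

    Each entity's set size is uniform on ``annotation_size_range``; each
    term is drawn (without replacement) from the entity's family subtree
    with probability ``family_bias`` and from the whole vocabulary
    otherwise.  ``family_bias=0`` gives unstructured annotations.
    """
    size_min, size_max = cfg.annotation_size_range
    if size_max > len(G):
        raise AnnSimError(
            f"annotation_size_range max {size_max} exceeds ontology size {len(G)}"
        )
    rng = _rng(cfg, 1)
    families = gen_entity_families(cfg)
    subtrees = _family_subtrees(G, cfg, rng)
    vocabulary = sorted(G.terms)
    annotations: dict[str, set[str]] = {}
    for entity in sorted(families):
        subtree = subtrees[families[entity]]
        size = int(rng.integers(size_min, size_max + 1))
        chosen: set[str] = set()
        while len(chosen) < size:
            pool = subtree if rng.random() < cfg.family_bias else vocabulary
            chosen.add(pool[int(rng.integers(len(pool)))])
        annotations[entity] = chosen
    return AnnotationGraph(annotations, G)


def gen_categories(cfg: GeneratorConfig) -> dict[str, frozenset[str]]:
    """Seeded entity -> category-set map with guaranteed duplicate sets.

    Entities in the same family share a family-specific pool of
    categories, and the first two entities of family 0 receive identical
    sets, so a clustering by identical category sets always has at least
    one multi-member cluster.
    """
    rng = _rng(cfg, 2)
    families = gen_entity_families(cfg)
    lo, hi = cfg.category_sets_per_entity
    labels = [f"C{i:02d}" for i in range(cfg.n_categories)]
    pools = [
        sorted(rng.choice(labels, size=max(hi, min(cfg.n_categories, hi + 2)),
                          replace=False))
        for _ in range(cfg.n_families)
    ]
    out: dict[str, frozenset[str]] = {}
    for entity in sorted(families):
        pool = pools[families[entity]]
        size = int(rng.integers(lo, min(hi, len(pool)) + 1))
        picks = rng.choice(len(pool), size=size, replace=False)
        out[entity] = frozenset(pool[int(i)] for i in picks)
    members_f0 = [e for e, f in sorted(families.items()) if f == 0]
    if len(members_f0) >= 2:
        out[members_f0[1]] = out[members_f0[0]]
    return out


def clustering_from_categories(
    categories: dict[str, frozenset[str]],
) -> dict[str, str]:
    """Group entities into one cluster per distinct category set.

    This is the gold-standard construction: its average Category-based
    Score is 1.0 by definition, since every within-cluster pair has
    identical category sets.
    """
    labels: dict[frozenset[str], str] = {}
    for catset in sorted(set(categories.values()), key=sorted):
        labels[catset] = f"K{len(labels):03d}"
    return {entity: labels[catset] for entity, catset in categories.items()}


def gen_features(
    C: dict[str, str],
    cfg: GeneratorConfig,
    dim: int = 4,
    center_scale: float = 10.0,
    spread: float = 1.0,
) -> pd.DataFrame:
    """Gaussian-blob feature vectors around one random center per cluster."""
    rng = _rng(cfg, 3)
    labels = sorted(set(C.values()))
    centers = {lab: rng.normal(0.0, center_scale, size=dim) for lab in labels}
    rows = {
        entity: centers[C[entity]] + rng.normal(0.0, spread, size=dim)
        for entity in sorted(C)
    }
    return pd.DataFrame.from_dict(rows, orient="index")
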