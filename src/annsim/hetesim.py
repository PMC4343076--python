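"""HeteSim: meeting-probability similarity along a relevance path.

A heterogeneous graph has typed nodes and named, typed relations.  A
*relevance path* is a sequence of relation names ``R1 .. Rl`` whose types
chain (target type of ``Ri`` equals source type of ``Ri+1``).  HeteSim
measures how likely a source node walking forward along the path and a
target node walking backward will meet at the same node:

* empty path: ``1`` if the nodes are equal else ``0``;
* single relation ``R``: ``|O(s|R) ∩ I(t|R)| / (|O(s|R)| · |I(t|R)|)``;
* longer paths: the average of HeteSim over the inner path for every
  pair of first-step out-neighbours of ``s`` and last-step in-neighbours
  of ``t``.

Empty neighbour sets give 0 (sparsely connected nodes score low, they do
not error).  Because meeting requires an *exact* node match, two entities
annotated with disjoint -- however ontologically close -- term sets score
exactly 0; this is the behaviour AnnSim is designed to improve on.

The canonical annotation meta-path is ``(annotates, identity,
annotated_by)``: entity -> term, term -> same term, term -> entity.
:meth:`HeteroGraph.from_annotation_graph` builds that graph directly.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from pathlib import Path

from .errors import HeteroGraphError

__all__ = ["Relation", "HeteroGraph", "RelevancePath", "hetesim", "load_hetero_graph"]

IDENTITY = "identity"


@dataclass
class Relation:
    """A named, directed, typed edge set."""

    name: str
    source_type: str
    target_type: str
    edges: set[tuple[str, str]] = field(default_factory=set)
    out_adj: dict[str, set[str]] = field(default_factory=dict)
    in_adj: dict[str, set[str]] = field(default_factory=dict)


class HeteroGraph:
    """Typed-node, typed-relation graph over which HeteSim is evaluated."""

    def __init__(self):
        self.node_types: dict[str, str] = {}
        self.relations: dict[str, Relation] = {}
        self.inverses: dict[str, str] = {}

    def add_node(self, node: str, node_type: str) -> None:
        existing = self.node_types.get(node)
        if existing is not None and existing != node_type:
            raise HeteroGraphError(
                f"node {node!r} already declared with type {existing!r}"
            )
        self.node_types[node] = node_type

    def add_relation(self, name: str, source_type: str, target_type: str) -> None:
        if name in self.relations:
            raise HeteroGraphError(f"relation {name!r} already declared")
        self.relations[name] = Relation(name, source_type, target_type)

    def add_edge(self, relation: str, source: str, target: str) -> None:
        rel = self._relation(relation)
        for node, expected in ((source, rel.source_type), (target, rel.target_type)):
            actual = self.node_types.get(node)
            if actual is None:
                raise HeteroGraphError(f"edge endpoint {node!r} is not a declared node")
            if actual != expected:
                raise HeteroGraphError(
                    f"edge ({source!r}, {target!r}) of relation {relation!r}: "
                    f"node {node!r} has type {actual!r}, expected {expected!r}"
                )
        rel.edges.add((source, target))
        rel.out_adj.setdefault(source, set()).add(target)
        rel.in_adj.setdefault(target, set()).add(source)

    def add_identity_relation(self, node_type: str, name: str = IDENTITY) -> None:
        """Declare the identity relation of a type: exactly its self-loops."""
        self.add_relation(name, node_type, node_type)
        for node, t in self.node_types.items():
            if t == node_type:
                self.add_edge(name, node, node)
        self.declare_inverse(name, name)

    def declare_inverse(self, name: str, inverse: str) -> None:
        """Record that two relations are mutual inverses (for path reversal)."""
        self._relation(name)
        self._relation(inverse)
        self.inverses[name] = inverse
        self.inverses[inverse] = name

    def _relation(self, name: str) -> Relation:
        try:
            return self.relations[name]
        except KeyError:
            raise HeteroGraphError(f"unknown relation {name!r}") from None

    def out_neighbors(self, node: str, relation: str) -> frozenset[str]:
        return frozenset(self._relation(relation).out_adj.get(node, ()))

    def in_neighbors(self, node: str, relation: str) -> frozenset[str]:
        return frozenset(self._relation(relation).in_adj.get(node, ()))

    @classmethod
    def from_annotation_graph(
        cls,
        AG,
        entity_type: str = "entity",
        term_type: str = "term",
    ) -> "HeteroGraph":
        """Lift an annotation graph into a heterogeneous graph.

        Creates relations ``annotates`` (entity -> term), ``annotated_by``
        (term -> entity, its inverse) and the term ``identity`` relation,
        ready for the meta-path ``(annotates, identity, annotated_by)``.
        """
        H = cls()
        terms = set()
        for entity, ts in AG.items():
            H.add_node(entity, entity_type)
            terms.update(ts)
        for term in terms:
            H.add_node(term, term_type)
        H.add_relation("annotates", entity_type, term_type)
        H.add_relation("annotated_by", term_type, entity_type)
        H.declare_inverse("annotates", "annotated_by")
        H.add_identity_relation(term_type)
        for entity, ts in AG.items():
            for term in ts:
                H.add_edge("annotates", entity, term)
                H.add_edge("annotated_by", term, entity)
        return H


class RelevancePath:
    """A type-compatible sequence of relation names ``R1 .. Rl`` (l >= 1)."""

    def __init__(self, relations: Sequence[str] | Iterable[str], H: HeteroGraph):
        names = list(relations)
        if not names:
            raise HeteroGraphError("a relevance path needs at least one relation")
        rels = [H._relation(n) for n in names]
        for left, right in zip(rels, rels[1:]):
            if left.target_type != right.source_type:
                raise HeteroGraphError(
                    f"relations {left.name!r} -> {right.name!r} are not "
                    f"type-compatible ({left.target_type!r} != {right.source_type!r})"
                )
        self.relations: tuple[str, ...] = tuple(names)
        self.source_type = rels[0].source_type
        self.target_type = rels[-1].target_type

    def __len__(self) -> int:
        return len(self.relations)

    def reversed(self, H: HeteroGraph) -> "RelevancePath":
        """The inverse path, available when every relation declares an inverse."""
        try:
            inv = [H.inverses[name] for name in reversed(self.relations)]
        except KeyError as exc:
            raise HeteroGraphError(
                f"relation {exc.args[0]!r} has no declared inverse"
            ) from None
        return RelevancePath(inv, H)


def hetesim(
    H: HeteroGraph,
    s: str,
    t: str,
    path: RelevancePath | Sequence[str],
) -> float:
    """HeteSim(s, t | path) -- see the module docstring for the recursion."""
    if not isinstance(path, RelevancePath):
        path = RelevancePath(path, H)
    for node, expected, role in (
        (s, path.source_type, "source"),
        (t, path.target_type, "target"),
    ):
        actual = H.node_types.get(node)
        if actual is None:
            raise HeteroGraphError(f"{role} node {node!r} is not in the graph")
        if actual != expected:
            raise HeteroGraphError(
                f"{role} node {node!r} has type {actual!r} but the path "
                f"requires {expected!r}"
            )
    return _hetesim(H, s, t, path.relations)


def _hetesim(H: HeteroGraph, s: str, t: str, rels: tuple[str, ...]) -> float:
    if not rels:
        return 1.0 if s == t else 0.0
    if len(rels) == 1:
        out = H.out_neighbors(s, rels[0])
        inn = H.in_neighbors(t, rels[0])
        if not out or not inn:
            return 0.0
        return len(out & inn) / (len(out) * len(inn))
    out = H.out_neighbors(s, rels[0])
    inn = H.in_neighbors(t, rels[-1])
    if not out or not inn:
        return 0.0
    inner = rels[1:-1]
    total = sum(_hetesim(H, u, v, inner) for u in sorted(out) for v in sorted(inn))
    return total / (len(out) * len(inn))


def load_hetero_graph(path: str | Path) -> HeteroGraph:
    """Load a heterogeneous graph from a TSV file with a declaration header.

    Directive lines (tab-separated)::

        @node<TAB>ID<TAB>type
        @relation<TAB>name<TAB>source_type<TAB>target_type
        @inverse<TAB>name<TAB>name
        @identity<TAB>type[<TAB>name]

    Data lines: ``relation<TAB>source<TAB>target``.  ``#`` starts a comment.
    """
    path = Path(path)
    H = HeteroGraph()
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            try:
                if cols[0] == "@node":
                    H.add_node(cols[1], cols[2])
                elif cols[0] == "@relation":
                    H.add_relation(cols[1], cols[2], cols[3])
                elif cols[0] == "@inverse":
                    H.declare_inverse(cols[1], cols[2])
                elif cols[0] == "@identity":
                    H.add_identity_relation(cols[1], *cols[2:3])
                elif len(cols) == 3:
                    H.add_edge(cols[0], cols[1], cols[2])
                else:
                    raise HeteroGraphError(
                        f"expected relation<TAB>source<TAB>target, got {len(cols)} columns"
                    )
            except (IndexError, HeteroGraphError) as exc:
                raise HeteroGraphError(f"{path}:{lineno}: {exc}") from None
    return H
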