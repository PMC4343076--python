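"""Rooted ontology DAGs: loading, depth, ancestor distances and LCA queries.

Terms are opaque, case-sensitive string identifiers.  Edges always point
child -> parent (the ``is_a`` direction), so following edges moves *up*
the ontology toward more general terms.  Roots are the terms with no
parent.

Two depth-like notions coexist and both are needed by the taxonomic
distance measures:

* :meth:`OntologyDAG.depth` -- length of the **longest** directed path
  from a root down to a term; this is the "depth" used to select the
  lowest common ancestor.
* :meth:`OntologyDAG.ancestor_distance` / :meth:`OntologyDAG.root_distance`
  -- **shortest** directed path lengths; these are the ``d(.,.)`` values
  entering the distance formulas.

Multi-root vocabularies (MeSH-like) are supported by treating the roots
as if joined under a virtual super-root: root distances minimise over the
real roots, and LCA queries succeed whenever a real common ancestor
exists.  A virtual root node is never materialised.
"""

from __future__ import annotations

import functools
from collections.abc import Iterable
from pathlib import Path

import networkx as nx

from .errors import CycleError, NoCommonAncestorError, OntologyError, UnknownTermError

__all__ = [
    "OntologyDAG",
    "load_ontology_edges",
    "load_ontology_obo",
]


class OntologyDAG:
    """A validated rooted DAG of ontology terms.

    Parameters
    ----------
    edges
        Iterable of ``(child, parent)`` pairs.  Duplicates are collapsed;
        self-loops and directed cycles raise :class:`CycleError`.
    terms
        Optional extra term identifiers with no incident edges
        (isolated terms are their own roots).
    labels
        Optional mapping term -> human-readable name.

    The instance is immutable after construction; depth and ancestor
    tables are memoised internally.
    """

    def __init__(
        self,
        edges: Iterable[tuple[str, str]],
        terms: Iterable[str] = (),
        labels: dict[str, str] | None = None,
    ):
        g = nx.DiGraph()
        g.add_nodes_from(terms)
        for child, parent in edges:
            if child == parent:
                raise CycleError(child)
            g.add_edge(child, parent)
        if not nx.is_directed_acyclic_graph(g):
            member = nx.find_cycle(g)[0][0]
            raise CycleError(member)
        self._g = g
        self.labels: dict[str, str] = dict(labels or {})
        self._depth: dict[str, int] | None = None

    # -- basic structure ------------------------------------------------

    @property
    def terms(self) -> frozenset[str]:
        return frozenset(self._g.nodes)

    @property
    def edges(self) -> frozenset[tuple[str, str]]:
        """The (child, parent) edge set."""
        return frozenset(self._g.edges)

    @property
    def roots(self) -> frozenset[str]:
        """Terms with no parent.  Non-empty for any non-empty ontology."""
        return frozenset(n for n in self._g.nodes if self._g.out_degree(n) == 0)

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    def __contains__(self, term: str) -> bool:
        return term in self._g

    def _require(self, term: str) -> None:
        if term not in self._g:
            raise UnknownTermError(f"term {term!r} is not in the ontology")

    def parents(self, term: str) -> frozenset[str]:
        self._require(term)
        return frozenset(self._g.successors(term))

    def children(self, term: str) -> frozenset[str]:
        self._require(term)
        return frozenset(self._g.predecessors(term))

    def ancestors(self, term: str) -> frozenset[str]:
        """All terms reachable child->parent from ``term``, including itself."""
        self._require(term)
        return frozenset(nx.descendants(self._g, term)) | {term}

    def descendants(self, term: str) -> frozenset[str]:
        """All terms below ``term`` (terms that have it as an ancestor), incl. itself."""
        self._require(term)
        return frozenset(nx.ancestors(self._g, term)) | {term}

    # -- depth / distances ----------------------------------------------

    def _depth_table(self) -> dict[str, int]:
        if self._depth is None:
            depth: dict[str, int] = {}
            for node in nx.topological_sort(self._g.reverse(copy=False)):
                ps = list(self._g.successors(node))
                depth[node] = 1 + max(depth[p] for p in ps) if ps else 0
            self._depth = depth
        return self._depth

    def depth(self, term: str) -> int:
        """Length (edge count) of the longest root-to-term directed path."""
        self._require(term)
        return self._depth_table()[term]

    def ancestor_distance(self, ancestor: str, term: str) -> int:
        """Shortest directed path length from ``ancestor`` down to ``term``.

        Every term is its own ancestor at distance 0.  Raises
        :class:`OntologyError` if ``ancestor`` is not an ancestor of ``term``.
        """
        self._require(ancestor)
        self._require(term)
        try:
            return nx.shortest_path_length(self._g, term, ancestor)
        except nx.NetworkXNoPath:
            raise OntologyError(
                f"{ancestor!r} is not an ancestor of {term!r}"
            ) from None

    @functools.lru_cache(maxsize=None)
    def _up_lengths(self, term: str) -> dict[str, int]:
        return dict(nx.single_source_shortest_path_length(self._g, term))

    def root_distance(self, term: str) -> int:
        """Minimum shortest-path distance from any root down to ``term``.

        Equals the distance from the virtual super-root minus the virtual
        edge when the ontology has several roots.
        """
        self._require(term)
        lengths = self._up_lengths(term)
        return min(lengths[r] for r in self.roots if r in lengths)

    def lca(self, x: str, y: str) -> str:
        """Lowest common ancestor: the common ancestor of greatest depth.

        Ties at maximal depth are broken by minimising
        ``d(a, x) + d(a, y)`` (shortest distances), then by lexicographic
        term identifier; the rule is symmetric in ``x`` and ``y``.
        """
        self._require(x)
        self._require(y)
        up_x = self._up_lengths(x)
        up_y = self._up_lengths(y)
        common = up_x.keys() & up_y.keys()
        if not common:
            raise NoCommonAncestorError(f"{x!r} and {y!r} share no ancestor")
        depth = self._depth_table()
        return min(common, key=lambda a: (-depth[a], up_x[a] + up_y[a], a))


def load_ontology_edges(path: str | Path) -> OntologyDAG:
    """Load an ontology from a child<TAB>parent edge-list file.

    Lines starting with ``#`` are comments.  A line with a single column
    declares an isolated term.  Duplicate edges are collapsed.
    """
    path = Path(path)
    edges: list[tuple[str, str]] = []
    singles: list[str] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) == 1:
                singles.append(cols[0])
            elif len(cols) == 2:
                edges.append((cols[0], cols[1]))
            else:
                raise OntologyError(
                    f"{path}:{lineno}: expected 1 or 2 tab-separated columns, "
                    f"got {len(cols)}"
                )
    return OntologyDAG(edges, terms=singles)


def load_ontology_obo(path: str | Path) -> OntologyDAG:
    """Load an ontology from an OBO 1.2-style file.

    Only ``[Term]`` stanzas are interpreted, and of those only the ``id``,
    ``name``, ``is_a`` and ``is_obsolete`` tags; each ``is_a`` becomes a
    (child, parent) edge, obsolete terms are skipped, and other relation
    types (``part_of``, ``regulates``, ...) are ignored.
    """
    import obonet

    path = Path(path)
    try:
        multigraph = obonet.read_obo(path, ignore_obsolete=True)
    except Exception as exc:  # noqa: BLE001 - wrap parser failures uniformly
        raise OntologyError(f"cannot parse OBO file {path}: {exc}") from exc
    edges = [
        (child, parent)
        for child, parent, key in multigraph.edges(keys=True)
        if key == "is_a"
    ]
    labels = {
        node: data["name"]
        for node, data in multigraph.nodes(data=True)
        if "name" in data
    }
    return OntologyDAG(edges, terms=multigraph.nodes, labels=labels)
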