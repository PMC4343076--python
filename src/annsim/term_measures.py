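"""Taxonomic term distances d_tax and d_ps and their similarity transforms.

Both distances live in [0, 1] and are built from the geometry of a term
pair around its lowest common ancestor (LCA):

.. math::

    d_{tax}(x, y) = \\frac{d(lca, x) + d(lca, y)}{d(root, x) + d(root, y)}

    d_{ps}(x, y)  = 1 - \\frac{d(root, lca)}{d(root, lca) + d(lca, x) + d(lca, y)}

where every ``d`` is a shortest directed path length (edge count) and the
LCA is the common ancestor of greatest longest-path depth.  The similarity
of a pair is ``1 - d``: terms that sit close to a deep shared ancestor are
similar; terms whose only shared ancestor is near the root are not.

Degenerate 0/0 cases are pinned down explicitly: ``d_tax(root, root) = 0``
(self-distance must be 0) and ``d_ps(root, root) = 1`` (the root is the
most general term, maximally unspecific).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .errors import AnnSimError
from .ontology import OntologyDAG

__all__ = [
    "TermPairGeometry",
    "term_pair_geometry",
    "d_tax",
    "d_ps",
    "term_similarity",
    "MEASURES",
    "round_half_up",
]

#: Supported taxonomic distance measures.
MEASURES = ("tax", "ps")


@dataclass(frozen=True)
class TermPairGeometry:
    """Shortest-path geometry of a term pair around its LCA."""

    x: str
    y: str
    lca: str
    d_lca_x: int
    d_lca_y: int
    d_root_x: int
    d_root_y: int
    d_root_lca: int


def term_pair_geometry(G: OntologyDAG, x: str, y: str) -> TermPairGeometry:
    """Compute LCA and all shortest distances entering the two formulas."""
    a = G.lca(x, y)
    return TermPairGeometry(
        x=x,
        y=y,
        lca=a,
        d_lca_x=G.ancestor_distance(a, x),
        d_lca_y=G.ancestor_distance(a, y),
        d_root_x=G.root_distance(x),
        d_root_y=G.root_distance(y),
        d_root_lca=G.root_distance(a),
    )


def d_tax(G: OntologyDAG, x: str, y: str) -> float:
    """Taxonomic distance: LCA detour relative to the pair's root distances.

    On multi-parent DAGs the raw ratio can exceed 1: the greatest-depth
    LCA may sit far above a term that also has a short independent route
    to the root, making the numerator larger than the denominator (on
    trees this cannot happen).  The value is capped at 1 -- "maximally
    dissimilar" -- to keep the distance, and the similarity ``1 - d``,
    inside [0, 1].
    """
    geo = term_pair_geometry(G, x, y)
    den = geo.d_root_x + geo.d_root_y
    if den == 0:  # x = y = a root
        return 0.0
    return min(1.0, (geo.d_lca_x + geo.d_lca_y) / den)


def d_ps(G: OntologyDAG, x: str, y: str) -> float:
    """Path-sharing distance: fraction of the joint path not shared via the LCA."""
    geo = term_pair_geometry(G, x, y)
    den = geo.d_root_lca + geo.d_lca_x + geo.d_lca_y
    if den == 0:  # x = y = a root
        return 1.0
    return 1.0 - geo.d_root_lca / den


_DISTANCES = {"tax": d_tax, "ps": d_ps}


def term_similarity(G: OntologyDAG, x: str, y: str, measure: str = "tax") -> float:
    """Similarity ``1 - d_measure(x, y)`` for ``measure`` in ``{"tax", "ps"}``."""
    try:
        dist = _DISTANCES[measure]
    except KeyError:
        raise AnnSimError(
            f"unsupported measure {measure!r}; expected one of {MEASURES}"
        ) from None
    return 1.0 - dist(G, x, y)


def round_half_up(value: float, ndigits: int) -> float:
    """Round half away from zero at ``ndigits`` decimals (reporting convention)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
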