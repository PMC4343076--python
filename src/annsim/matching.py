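"""AnnSim: Dice-normalised 1-1 maximum-weight bipartite matching.

Given two entities with annotation sets ``A1`` and ``A2``, a complete
weighted bipartite graph is built over the Cartesian product
``A1 x A2`` with term-similarity weights in [0, 1].  An *exact* 1-1
maximum-weight matching saturating the smaller side is solved, and the
score is its total weight normalised Dice-style:

.. math::

    AnnSim(c_1, c_2) = \\frac{2 \\sum_{(a_1,a_2) \\in M} sim(a_1, a_2)}
                             {|A_1| + |A_2|}

The measure is symmetric, lies in [0, 1], reaches 1 exactly when the two
sets have equal cardinality and every matched weight is 1, and penalises
cardinality differences: unmatched terms contribute nothing to the
numerator but still count in the denominator, so
``AnnSim <= 2 min(|A1|,|A2|) / (|A1|+|A2|)``.

The solver is scipy's exact rectangular assignment
(:func:`scipy.optimize.linear_sum_assignment`); the optimal *total weight*
is unique and part of the contract, the particular optimal pairing is not.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .annotation import AnnotationGraph
from .errors import AnnSimError
from .ontology import OntologyDAG
from .term_measures import term_similarity

__all__ = [
    "WeightedBipartiteGraph",
    "Matching",
    "build_bipartite",
    "max_weight_matching",
    "annsim_score",
    "annsim_sets",
    "annsim",
    "pairwise_annsim",
]


@dataclass(frozen=True)
class WeightedBipartiteGraph:
    """Complete bipartite similarity graph between two annotation sets.

    ``weights[i, j]`` is the similarity of ``left[i]`` and ``right[j]``;
    left/right are sorted term identifiers so construction is
    deterministic.
    """

    left: tuple[str, ...]
    right: tuple[str, ...]
    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(self.left), len(self.right)):
            raise AnnSimError(
                f"weight matrix shape {w.shape} does not match "
                f"({len(self.left)}, {len(self.right)})"
            )
        if w.size and (w.min() < -1e-9 or w.max() > 1 + 1e-9):
            raise AnnSimError("bipartite weights must lie in [0, 1]")
        object.__setattr__(self, "weights", w)


@dataclass(frozen=True)
class Matching:
    """A 1-1 matching: index pairs into (left, right) plus its total weight."""

    pairs: tuple[tuple[int, int], ...]
    total_weight: float


def build_bipartite(
    A1: Iterable[str],
    A2: Iterable[str],
    G: OntologyDAG,
    measure: str = "tax",
) -> WeightedBipartiteGraph:
    """Build the complete term-similarity bipartite graph over ``A1 x A2``."""
    left = tuple(sorted(set(A1)))
    right = tuple(sorted(set(A2)))
    if not left or not right:
        raise AnnSimError("annotation sets must be non-empty to build a bipartite graph")
    weights = np.empty((len(left), len(right)))
    cache: dict[tuple[str, str], float] = {}
    for i, a in enumerate(left):
        for j, b in enumerate(right):
            key = (a, b) if a <= b else (b, a)
            if key not in cache:
                cache[key] = term_similarity(G, a, b, measure)
            weights[i, j] = cache[key]
    return WeightedBipartiteGraph(left, right, weights)


def max_weight_matching(BG: WeightedBipartiteGraph) -> Matching:
    """Exact 1-1 maximum-weight matching saturating the smaller side.

    All weights are non-negative, so a maximum-weight matching of full
    rank on the smaller side is always optimal; scipy's rectangular
    assignment solver returns it exactly.
    """
    rows, cols = linear_sum_assignment(BG.weights, maximize=True)
    pairs = tuple(sorted(zip(rows.tolist(), cols.tolist())))
    return Matching(pairs=pairs, total_weight=float(BG.weights[rows, cols].sum()))


def annsim_score(M: Matching, n1: int, n2: int) -> float:
    """Dice normalisation ``2 * total_weight / (n1 + n2)`` of a matching."""
    if n1 + n2 == 0:
        raise AnnSimError("both annotation sets are empty: AnnSim is undefined")
    return 2.0 * M.total_weight / (n1 + n2)


def annsim_sets(
    A1: Iterable[str],
    A2: Iterable[str],
    G: OntologyDAG,
    measure: str = "tax",
) -> float:
    """AnnSim between two explicit term sets (see module docstring)."""
    s1, s2 = set(A1), set(A2)
    if not s1 and not s2:
        raise AnnSimError("both annotation sets are empty: AnnSim is undefined")
    if not s1 or not s2:
        return 0.0  # empty numerator over a non-empty denominator
    # Canonical argument order makes symmetry exact to the last bit
    # (float summation order would otherwise differ on the transpose).
    if sorted(s2) < sorted(s1):
        s1, s2 = s2, s1
    BG = build_bipartite(s1, s2, G, measure)
    return annsim_score(max_weight_matching(BG), len(s1), len(s2))


def annsim(c1: str, c2: str, AG: AnnotationGraph, measure: str = "tax") -> float:
    """AnnSim between two annotated entities of an annotation graph."""
    return annsim_sets(AG[c1], AG[c2], AG.ontology, measure)


def pairwise_annsim(
    AG: AnnotationGraph,
    entities: Sequence[str] | None = None,
    measure: str = "tax",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs AnnSim matrix plus per-entity mean/std summaries.

    Returns
    -------
    matrix : DataFrame
        Symmetric entity-by-entity AnnSim matrix (diagonal is the
        self-score, 1.0 whenever term self-similarity is 1).
    summary : DataFrame
        Per entity, the mean and sample standard deviation of its
        similarity to the *other* entities (the "avg; std" summary).
    """
    names = sorted(AG.entities) if entities is None else list(entities)
    for e in names:
        AG[e]  # raises on unknown entities
    n = len(names)
    mat = np.ones((n, n))
    for i in range(n):
        mat[i, i] = annsim(names[i], names[i], AG, measure)
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = annsim(names[i], names[j], AG, measure)
    matrix = pd.DataFrame(mat, index=names, columns=names)
    off = mat.copy()
    np.fill_diagonal(off, np.nan)
    summary = pd.DataFrame(
        {
            "mean": np.nanmean(off, axis=1) if n > 1 else np.nan,
            "std": np.nanstd(off, axis=1, ddof=1) if n > 2 else np.nan,
        },
        index=names,
    )
    return matrix, summary
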