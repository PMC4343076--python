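"""Evaluation statistics for similarity measures and clusterings.

Ranking agreement (nDCG), correlation (Pearson / Spearman with a Fisher-z
significance test for comparing correlations), set agreement (Jaccard,
average Category-based Score), partition agreement (pair-counting Jaccard
clustering index), and cluster-geometry validity (Davies-Bouldin in two
variants, and the Coupling measure).

Containers are deliberately lightweight: a clustering is any mapping
``entity -> cluster label``, category assignments are a mapping
``entity -> set of categories``, and feature matrices are pandas
DataFrames indexed by entity.
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from collections.abc import Set as AbstractSet
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EvaluationError

__all__ = [
    "ndcg",
    "correlation",
    "fisher_z_statistic",
    "fisher_z_test",
    "jaccard_set",
    "category_score",
    "jaccard_clustering",
    "davies_bouldin",
    "coupling",
]

Clustering = Mapping[str, str]


# -- ranking ------------------------------------------------------------


def _dcg(gains: Sequence[float]) -> float:
    # First position undiscounted; log2(i) discount from rank 2 on.
    return sum(
        g if i == 1 else g / math.log2(i) for i, g in enumerate(gains, start=1)
    )


def ndcg(
    items: Sequence[str],
    scores: Sequence[float],
    relevance: Sequence[float],
    exponential: bool = False,
) -> float:
    """Normalised discounted cumulative gain of the score-induced ranking.

    Items are ranked by descending score (ties broken by item identifier);
    the DCG of their graded relevances is divided by the DCG of the ideal
    (relevance-sorted) ranking.  Linear gain by default -- the graded
    ground truths this serves are panel scores on a linear scale -- with
    the exponential ``2^rel - 1`` form behind ``exponential=True``.
    """
    if not (len(items) == len(scores) == len(relevance)):
        raise EvaluationError("items, scores and relevance must have equal length")
    if not items:
        raise EvaluationError("cannot rank an empty item list")
    rel = {i: r for i, r in zip(items, relevance)}
    if any(r < 0 for r in relevance):
        raise EvaluationError("relevance grades must be non-negative")
    if all(r == 0 for r in relevance):
        raise EvaluationError("all-zero relevance: nDCG is undefined")
    gain = (lambda r: 2.0**r - 1.0) if exponential else (lambda r: r)
    score = {i: s for i, s in zip(items, scores)}
    by_score = sorted(items, key=lambda i: (-score[i], i))
    ideal = sorted(items, key=lambda i: (-rel[i], i))
    return _dcg([gain(rel[i]) for i in by_score]) / _dcg([gain(rel[i]) for i in ideal])


# -- correlation --------------------------------------------------------


def correlation(x: Sequence[float], y: Sequence[float], method: str = "pearson") -> float:
    """Pearson product-moment or Spearman rank correlation (mid-ranks on ties)."""
    xa, ya = np.asarray(x, float), np.asarray(y, float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise EvaluationError("x and y must be equal-length 1-D vectors")
    if xa.size < 3:
        raise EvaluationError("correlation needs at least 3 observations")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise EvaluationError("correlation is undefined for a constant vector")
    if method == "pearson":
        return float(stats.pearsonr(xa, ya).statistic)
    if method == "spearman":
        return float(stats.spearmanr(xa, ya).statistic)
    raise EvaluationError(f"unknown correlation method {method!r}")


def fisher_z_statistic(r_obs: float, r_ref: float, n: int) -> float:
    """z = (atanh(r_obs) - atanh(r_ref)) * sqrt(n - 3)."""
    for r in (r_obs, r_ref):
        if not -1.0 < r < 1.0:
            raise EvaluationError("correlations must lie strictly inside (-1, 1)")
    if n <= 3:
        raise EvaluationError("the Fisher z test needs n > 3")
    return (math.atanh(r_obs) - math.atanh(r_ref)) * math.sqrt(n - 3)


def fisher_z_test(r_obs: float, r_ref: float, n: int) -> float:
    """Two-sided p-value for observing correlation ``r_obs`` under ``r_ref``.

    One-sample z test for a correlation coefficient via the Fisher
    variance-stabilising transform; used to ask whether one measure's
    correlation with a gold standard genuinely exceeds another's.
    """
    z = fisher_z_statistic(r_obs, r_ref, n)
    return float(2.0 * stats.norm.sf(abs(z)))


# -- set and partition agreement ---------------------------------------


def jaccard_set(a: AbstractSet, b: AbstractSet) -> float:
    """|a ∩ b| / |a ∪ b|; both-empty is undefined."""
    union = len(a | b)
    if union == 0:
        raise EvaluationError("Jaccard index of two empty sets is undefined")
    return len(a & b) / union


def category_score(
    C: Clustering,
    categories: Mapping[str, AbstractSet],
) -> float:
    """Average Category-based Score of a clustering.

    The mean Jaccard index of the category sets over all unordered
    within-cluster entity pairs, pooled across clusters.  Singleton
    clusters contribute no pairs; a clustering with no multi-entity
    cluster is an error.  Equals 1.0 exactly for a clustering that only
    groups entities with identical category sets.
    """
    clusters: dict[str, list[str]] = {}
    for entity, label in C.items():
        clusters.setdefault(label, []).append(entity)
    values = [
        jaccard_set(categories[a], categories[b])
        for members in clusters.values()
        for a, b in combinations(sorted(members), 2)
    ]
    if not values:
        raise EvaluationError("no cluster contains two or more entities")
    return float(np.mean(values))


def jaccard_clustering(C1: Clustering, C2: Clustering) -> float:
    """Pair-counting Jaccard agreement between two partitions.

    ``n11 / (n11 + n10 + n01)`` over all unordered entity pairs, where
    n11 counts pairs co-clustered in both partitions and n10/n01 pairs
    co-clustered in exactly one.  When no pair is co-clustered anywhere
    (all-singleton partitions) the value is 1.0 by convention, preserving
    reflexivity.
    """
    if set(C1) != set(C2):
        raise EvaluationError("the two clusterings cover different entities")
    n11 = n10 = n01 = 0
    for a, b in combinations(sorted(C1), 2):
        same1 = C1[a] == C1[b]
        same2 = C2[a] == C2[b]
        n11 += same1 and same2
        n10 += same1 and not same2
        n01 += same2 and not same1
    if n11 + n10 + n01 == 0:
        return 1.0
    return n11 / (n11 + n10 + n01)


# -- cluster geometry ---------------------------------------------------


def _clusters_of(F: pd.DataFrame, C: Clustering) -> dict[str, np.ndarray]:
    missing = set(C) - set(F.index)
    if missing:
        raise EvaluationError(f"entities missing from the feature matrix: {sorted(missing)[:5]}")
    groups: dict[str, list[str]] = {}
    for entity, label in C.items():
        groups.setdefault(label, []).append(entity)
    return {
        label: F.loc[sorted(members)].to_numpy(float)
        for label, members in sorted(groups.items())
    }


def davies_bouldin(F: pd.DataFrame, C: Clustering, variant: str = "printed") -> float:
    """Davies-Bouldin cluster-validity index; smaller is better.

    Centroids are per-cluster component means and ``d_i`` is the mean
    Euclidean distance of cluster *i*'s points to its own centroid.  The
    separation term ``d_ij`` differs by variant:

    * ``"printed"`` -- mean Euclidean distance of cluster *i*'s points to
      centroid *j* (the formula as literally stated alongside the
      clustering experiments this package serves);
    * ``"standard"`` -- Euclidean distance between centroids *i* and *j*
      (the classical definition).

    The index is ``(1/k) * sum_i max_{j != i} (d_i + d_j) / d_ij``.
    """
    if variant not in ("printed", "standard"):
        raise EvaluationError(f"unknown Davies-Bouldin variant {variant!r}")
    groups = _clusters_of(F, C)
    labels = list(groups)
    k = len(labels)
    if k < 2:
        raise EvaluationError("Davies-Bouldin needs at least two clusters")
    centroids = {lab: pts.mean(axis=0) for lab, pts in groups.items()}
    scatter = {
        lab: float(np.linalg.norm(pts - centroids[lab], axis=1).mean())
        for lab, pts in groups.items()
    }

    def separation(i: str, j: str) -> float:
        if variant == "standard":
            return float(np.linalg.norm(centroids[i] - centroids[j]))
        return float(np.linalg.norm(groups[i] - centroids[j], axis=1).mean())

    total = 0.0
    for i in labels:
        ratios = []
        for j in labels:
            if i == j:
                continue
            d_ij = separation(i, j)
            if d_ij == 0:
                raise EvaluationError(
                    f"degenerate cluster pair ({i!r}, {j!r}): zero separation"
                )
            ratios.append((scatter[i] + scatter[j]) / d_ij)
        total += max(ratios)
    return total / k


def coupling(F: pd.DataFrame, C: Clustering) -> float:
    """Mean cosine similarity over all unordered centroid pairs; lower is better."""
    groups = _clusters_of(F, C)
    if len(groups) < 2:
        raise EvaluationError("the Coupling measure needs at least two clusters")
    centroids = {lab: pts.mean(axis=0) for lab, pts in groups.items()}
    norms = {lab: float(np.linalg.norm(c)) for lab, c in centroids.items()}
    zero = [lab for lab, nrm in norms.items() if nrm == 0]
    if zero:
        raise EvaluationError(f"zero-norm centroid for cluster {zero[0]!r}")
    sims = [
        float(centroids[a] @ centroids[b]) / (norms[a] * norms[b])
        for a, b in combinations(sorted(groups), 2)
    ]
    return float(np.mean(sims))
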