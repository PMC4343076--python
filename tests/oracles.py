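"""Independent brute-force oracles used to cross-check the implementation.

Everything here works on raw primitives (edge lists, adjacency dicts,
weight matrices) with exhaustive enumeration, and deliberately shares no
code with the package under test.
"""

from __future__ import annotations

from itertools import permutations


# -- DAG geometry by path enumeration -----------------------------------


def _parents_map(edges):
    out = {}
    for child, parent in edges:
        out.setdefault(child, set()).add(parent)
        out.setdefault(parent, set())
    return out


def enumerate_up_paths(edges, start):
    """All simple child->parent paths from ``start`` (as node lists)."""
    parents = _parents_map(edges)
    paths = []

    def walk(node, acc):
        paths.append(list(acc))
        for p in sorted(parents.get(node, ())):
            walk(p, acc + [p])

    walk(start, [start])
    return paths


def brute_roots(edges, nodes=()):
    parents = _parents_map(edges)
    for n in nodes:
        parents.setdefault(n, set())
    return {n for n, ps in parents.items() if not ps}


def brute_depth(edges, x):
    """Longest path length from any root down to x (= longest up-path from x)."""
    roots = brute_roots(edges)
    return max(
        len(p) - 1 for p in enumerate_up_paths(edges, x) if p[-1] in roots
    )


def brute_ancestor_distance(edges, a, x):
    """Shortest up-path length from x to a; None if a is not an ancestor."""
    best = None
    for p in enumerate_up_paths(edges, x):
        if p[-1] == a and (best is None or len(p) - 1 < best):
            best = len(p) - 1
    return best


def brute_root_distance(edges, x):
    roots = brute_roots(edges)
    return min(
        len(p) - 1 for p in enumerate_up_paths(edges, x) if p[-1] in roots
    )


def brute_ancestors(edges, x):
    return {p[-1] for p in enumerate_up_paths(edges, x)}


def brute_lca(edges, x, y):
    """Greatest-depth common ancestor; ties by distance sum then term id."""
    common = brute_ancestors(edges, x) & brute_ancestors(edges, y)
    if not common:
        return None
    return min(
        common,
        key=lambda a: (
            -brute_depth(edges, a),
            brute_ancestor_distance(edges, a, x) + brute_ancestor_distance(edges, a, y),
            a,
        ),
    )


def brute_d_tax(edges, x, y):
    a = brute_lca(edges, x, y)
    num = brute_ancestor_distance(edges, a, x) + brute_ancestor_distance(edges, a, y)
    den = brute_root_distance(edges, x) + brute_root_distance(edges, y)
    if den == 0:
        return 0.0
    return min(1.0, num / den)


def brute_d_ps(edges, x, y):
    a = brute_lca(edges, x, y)
    dr = brute_root_distance(edges, a)
    den = dr + brute_ancestor_distance(edges, a, x) + brute_ancestor_distance(edges, a, y)
    if den == 0:
        return 1.0
    return 1.0 - dr / den


# -- assignment by exhaustive injection ---------------------------------


def brute_max_matching_weight(weights):
    """Maximum total weight over all injections of the smaller side."""
    rows = len(weights)
    cols = len(weights[0]) if rows else 0
    transposed = rows > cols
    w = [list(col) for col in zip(*weights)] if transposed else [list(r) for r in weights]
    n, m = len(w), len(w[0])
    return max(
        sum(w[i][perm[i]] for i in range(n)) for perm in permutations(range(m), n)
    )


# -- HeteSim as a meeting-probability walk enumeration ------------------


def brute_hetesim(out_adj, in_adj, s, t, relations):
    """Meeting probability of a forward walker from ``s`` and a backward
    walker from ``t``.

    ``out_adj[rel][node]`` / ``in_adj[rel][node]`` are neighbour sets.
    The forward walker traverses the first ceil(l/2) relations choosing
    uniformly among out-neighbours; the backward walker traverses the
    last ceil(l/2) relations in reverse, uniformly among in-neighbours.
    For odd l the two halves share the middle relation: the single-
    relation meeting rule steps *both* walkers through it.  A dead end
    contributes probability 0.  The result equals the pairwise-average
    recursion by induction, but is computed here by explicit enumeration
    of weighted walk endpoints.
    """
    l = len(relations)
    fwd_rels = relations[: (l + 1) // 2]
    bwd_rels = relations[l // 2:]

    def forward(dist, rel):
        new = {}
        for node, p in dist.items():
            nbrs = sorted(out_adj.get(rel, {}).get(node, ()))
            for nb in nbrs:
                new[nb] = new.get(nb, 0.0) + p / len(nbrs)
        return new

    def backward(dist, rel):
        new = {}
        for node, p in dist.items():
            nbrs = sorted(in_adj.get(rel, {}).get(node, ()))
            for nb in nbrs:
                new[nb] = new.get(nb, 0.0) + p / len(nbrs)
        return new

    fwd = {s: 1.0}
    for rel in fwd_rels:
        fwd = forward(fwd, rel)
    bwd = {t: 1.0}
    for rel in reversed(bwd_rels):
        bwd = backward(bwd, rel)
    return sum(p * bwd.get(node, 0.0) for node, p in fwd.items())


# -- evaluation statistics, spreadsheet style ---------------------------


def brute_ndcg(items, scores, relevance):
    import math

    rel = dict(zip(items, relevance))
    score = dict(zip(items, scores))

    def dcg(order):
        total = 0.0
        for i, item in enumerate(order, start=1):
            total += rel[item] if i == 1 else rel[item] / math.log2(i)
        return total

    ranked = sorted(items, key=lambda i: (-score[i], i))
    ideal = sorted(items, key=lambda i: (-rel[i], i))
    return dcg(ranked) / dcg(ideal)


def brute_spearman(x, y):
    """Spearman via Pearson on mid-ranks, written out long-hand."""

    def midranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks

    rx, ry = midranks(list(x)), midranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    dx = sum((a - mx) ** 2 for a in rx) ** 0.5
    dy = sum((b - my) ** 2 for b in ry) ** 0.5
    return num / (dx * dy)
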