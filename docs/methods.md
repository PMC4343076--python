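# Methods

This note records the model conventions, parameter choices and numerical
decisions behind the package, and what the synthetic experiments do and
do not demonstrate.

## Ontology model and geometry

An ontology is a rooted DAG of opaque, case-sensitive term identifiers
with child→parent (`is_a`) edges. Only `is_a` is interpreted; `part_of`
and other relations are out of scope, as are OWL constructs and
versioning. Two path notions coexist deliberately:

- **depth** — the *longest* root-to-term path; used only to select the
  lowest common ancestor (the common ancestor of greatest depth);
- **d(·,·)** — *shortest* directed path lengths; used for every distance
  entering the similarity formulas.

LCA ties at maximal depth are broken by minimising `d(a,x) + d(a,y)`,
then by lexicographic term id. The rule is deterministic and symmetric,
and favours the ancestor that makes the pair look most related.

**Multiple roots.** The distance measures need a single root. When a
vocabulary has several (MeSH-like), the package behaves as if a virtual
super-root were connected to every real root: root distances minimise
over real roots, and no virtual node is materialised. LCA queries fail
with a clear error only when two terms genuinely share no ancestor.

**Degenerate cases.** Every term is its own ancestor at distance 0, so
`d_tax(x,x) = 0` and self-similarity is 1. The 0/0 corner cases are
pinned: `d_tax(root,root) = 0` (self-distance must vanish) and
`d_ps(root,root) = 1` (the root is the most general term).

**Range cap on d_tax.** On multi-parent DAGs the raw ratio
`(d(lca,x)+d(lca,y)) / (d(root,x)+d(root,y))` can exceed 1: the
greatest-depth LCA may sit far above a term that also has a short
independent route to the root. On trees this cannot happen. The distance
is capped at 1 so that both the distance and the similarity `1 − d` stay
in [0,1]; the cap is the package's own resolution of a corner the
formulas leave open, and the brute-force test oracle applies the same
rule. Related: `d_tax` is often described as a metric; the triangle
inequality is verified empirically on random *trees* in the test suite
and is not asserted for general DAGs.

## AnnSim

The bipartite graph over `A1 × A2` is complete by construction with
weights in [0,1]; left/right term orders are sorted ids, so construction
is deterministic. The matching solver is scipy's exact rectangular
assignment (Hungarian family). The graph is bipartite, so general
matching machinery (blossom algorithms) is unnecessary; any exact solver
satisfies the optimality contract, and only the optimal *total weight*
is part of the contract — ties among optimal pairings are resolved
arbitrarily but reported deterministically via sorted index pairs.

Unequal set sizes need no explicit dummy padding: the smaller side is
saturated, unmatched terms add 0 to the numerator and their cardinality
inflates the denominator — exactly what the Dice normalisation encodes.
One empty annotation set gives score 0 (forced by `2·0/(0+n)`); two
empty sets are an error (0/0). Entities are untyped: drugs, proteins and
conditions are all plain ids, which is what makes the measure
general-purpose.

Symmetry is exact to the last bit, not merely up to float rounding: the
two sets are put into a canonical order before the matrix is built, so
swapping the arguments cannot change the summation order.

`pairwise_annsim` reports per-entity mean and *sample* standard
deviation (ddof = 1) over the other entities; population std would
change the third decimal at these n and the choice is otherwise
inconsequential.

## HeteSim

The recursion implemented is the un-normalised meeting form: a forward
walker from `s` and a backward walker from `t`, stepping uniformly over
typed neighbourhoods; a single relation contributes
`|O(s|R) ∩ I(t|R)| / (|O||I|)`, longer paths average the inner value
over all first/last-step neighbour pairs, and an empty neighbourhood
yields 0 rather than an error (sparsely connected nodes score low).
Odd-length paths resolve through the single-middle-relation meeting
rule, with both walkers traversing the middle relation — the annotation
meta-path `(annotates, identity, annotated_by)` is the canonical case.
The cosine-normalised variant is deliberately not implemented.

Two consequences worth knowing: self-similarity is `1/|A|` for an
entity with `|A|` annotations (not 1), and adding a shared annotation to
*both* sets can lower the value when they already overlap (the
denominator grows faster); at fixed set sizes the value is `k/(n·m)`,
monotone in the overlap `k`. The tests assert these true properties
rather than folklore ones.

## Evaluation statistics

- **nDCG** uses the classical form: gain of the top item undiscounted,
  `rel_i / log2(i)` from rank 2, linear gain by default (the graded
  ground truths it serves are linear panel scores, e.g. 1.0–4.0);
  `2^rel − 1` gain is available behind a flag. Score ties are broken by
  item id, making the statistic permutation-invariant.
- **Spearman** uses mid-ranks; annotation-derived score lists tie
  heavily, so mid-ranks are the only defensible convention.
- The **Fisher z test** is the one-sample, two-sided comparison
  `z = (atanh r_obs − atanh r_ref)·√(n−3)` against the standard normal.
- **Category-based Score** pools the per-pair Jaccard of category sets
  over all within-cluster pairs; singleton clusters contribute no pairs.
  Under this convention — and only under it — a gold-standard clustering
  that groups entities exactly when their category sets are identical
  scores exactly 1.0 while containing many singletons.
- The pair-counting **Jaccard clustering index** defines the vacuous
  case (no co-clustered pair in either partition) as 1.0, preserving
  reflexivity for all-singleton partitions.
- **Davies–Bouldin** ships in two variants because the separation term
  admits two readings: `standard` (centroid-to-centroid distance, the
  classical index, cross-checked against scikit-learn in the tests) and
  `printed` (mean distance of cluster-i points to centroid j, as the
  formula is sometimes stated alongside clustering experiments);
  `printed` is the default for fidelity, `standard` for comparability.
  Coincident centroids (zero separation) raise an error naming the pair.
- **Coupling** is the mean cosine similarity over unordered centroid
  pairs; zero-norm centroids are an error.

Clusterings are plain `entity → label` mappings and feature matrices are
pandas DataFrames; the package consumes cluster assignments and feature
vectors, it does not run EM or k-means itself, and it never infers
feature vectors from a similarity matrix.

## Synthetic data: what it emulates, what it does not

Generators are pure functions of a `GeneratorConfig` (seed included),
using per-generator `SeedSequence` streams; no global random state.
Defaults are desk-scale and chosen to mirror the *shape* of real
annotation studies rather than their size: 200 terms (real
vocabularies run to hundreds of thousands — emulating that size is a
non-goal), up to 2 parents per term, a guaranteed backbone depth of 8,
24 entities, annotation counts uniform on 1–12 (real counts span 1 to
100+; the spread, not the maximum, is what matters for the Dice
penalty), 3 entity families with subtree bias 0.9.

The family mechanism gives each family a focus subtree (a term whose
descendant set can cover a full annotation set) and draws each
annotation from that subtree with probability `family_bias`, else from
the whole vocabulary. This creates groups of entities whose annotations
are ontologically close without being identical — the regime where an
exact-match baseline collapses to ~0 and a matching-based measure does
not. With the default configuration, within-family mean pairwise AnnSim
exceeds the cross-family mean in 20 of 20 replicate seeds (the test
requires ≥ 18).

What passing these tests does *not* show: behaviour on real
vocabularies with their idiosyncratic depth profiles and annotation
biases, on annotation sets of hundreds of terms, or under annotation
noise (wrong or missing terms). The generators produce clean,
well-formed data by construction; the unknown-term policy machinery
exists precisely because real inputs are not.

## Numerical conventions

- Internal values are full precision; reporting rounds half away from
  zero at the requested decimals (`round_half_up`), matching how 2–3
  d.p. values are conventionally printed.
- Test comparisons on matching weights use absolute tolerance 1e−9;
  property assertions involving sums allow 1e−12 slack.
- Ontologies are immutable after construction; depth tables and upward
  shortest-path maps are memoised per instance.
- Term ids are never normalised (no CURIE handling, no case folding).

## Known limitations

- Only 1–1 matching: many-to-many matching between annotation sets is
  out of scope.
- IC-based term measures (Resnik/Lin/Jiang–Conrath and set variants)
  are out of scope; the term-similarity interface accepts only
  `tax` and `ps`.
- The OBO reader handles the `[Term]`/`id`/`name`/`is_a`/`is_obsolete`
  subset via obonet; parse failures are wrapped with the file name but
  line numbers are only as precise as the underlying parser reports.
- HeteSim is exact-match only; no transition-probability or
  PathSim-style commuting-matrix formulations.
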