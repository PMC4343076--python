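"""AnnSim between annotated entities on synthetic data.

Generates a seeded ontology and annotation graph with three entity
families (each biased toward its own focus subtree), computes the full
pairwise AnnSim matrix, and contrasts within-family and cross-family
mean similarity.
"""

import numpy as np

from annsim import (
    GeneratorConfig,
    gen_annotations,
    gen_entity_families,
    gen_ontology,
    pairwise_annsim,
)

cfg = GeneratorConfig(seed=7, n_entities=12)
G = gen_ontology(cfg)
AG = gen_annotations(G, cfg)
families = gen_entity_families(cfg)

matrix, summary = pairwise_annsim(AG, measure="tax")
print("per-entity mean / std of AnnSim against the other entities:")
print(summary.round(3).to_string())

names = sorted(AG.entities)
within, cross = [], []
for i, a in enumerate(names):
    for b in names[i + 1:]:
        (within if families[a] == families[b] else cross).append(matrix.loc[a, b])
print(f"\nmean AnnSim within families: {np.mean(within):.3f}")
print(f"mean AnnSim across families: {np.mean(cross):.3f}")

# Entities drawing annotations from the same ontology subtree score
# visibly higher: AnnSim rewards annotation sets whose terms sit close
# to deep shared ancestors even when no term is shared exactly.
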