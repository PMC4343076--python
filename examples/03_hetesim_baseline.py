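"""HeteSim as the exact-match baseline AnnSim improves on.

Two entities annotated with disjoint term sets (sizes 3 and 7) get
HeteSim exactly 0 along the annotation meta-path, regardless of how
close their terms sit in an ontology; a pair sharing one of two terms
gets 0.5.
"""

from annsim import HeteroGraph, hetesim
from annsim.fixtures import disjoint_hetero_fixture

H, s, t, path = disjoint_hetero_fixture()
print(f"disjoint sets (3 vs 7 terms):  HeteSim({s}, {t}) = {hetesim(H, s, t, path)}")


class _Ann:  # a plain {entity: terms} mapping is all the lifting needs
    data = {"u": ["T1"], "v": ["T1", "T2"]}

    @classmethod
    def items(cls):
        return cls.data.items()


H2 = HeteroGraph.from_annotation_graph(_Ann)
print("one shared of two terms:       HeteSim(u, v) =",
      hetesim(H2, "u", "v", ["annotates", "identity", "annotated_by"]))

# 0.0 vs 0.5: HeteSim only credits *identical* annotations (the walkers
# must meet at the same term node), so entities treating similar but
# non-identical conditions look maximally dissimilar to it.
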