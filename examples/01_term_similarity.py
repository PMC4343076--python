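"""Taxonomic term similarity on a small ontology.

Builds the deep-LCA chain ontology (two disease-like terms two edges
below a shared ancestor at root distance 3) and prints both taxonomic
similarities for the pair.
"""

from annsim import d_ps, d_tax, term_pair_geometry, term_similarity
from annsim.fixtures import deep_lca_fixture

G, x, y = deep_lca_fixture()
geo = term_pair_geometry(G, x, y)

print(f"pair ({x}, {y}): lca={geo.lca}, "
      f"d(lca,x)={geo.d_lca_x}, d(lca,y)={geo.d_lca_y}, "
      f"d(root,x)={geo.d_root_x}, d(root,y)={geo.d_root_y}")
print(f"d_tax = {d_tax(G, x, y):.3f}   1 - d_tax = {term_similarity(G, x, y, 'tax'):.2f}")
print(f"d_ps  = {d_ps(G, x, y):.3f}   1 - d_ps  = {term_similarity(G, x, y, 'ps'):.2f}")

# 1 - d_tax = 0.60: the pair shares 3 of the 5 edges separating each term
# from the root.  1 - d_ps = 0.43: the shared path to the LCA covers 3 of
# the 7 edges in the joint root-lca-x/y configuration.  Both say
# "related, not interchangeable"; d_ps penalises a shallow LCA harder.
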