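"""Isolation by distance around the basin: straight-line vs ring distances.

Uses the bundled published tables for the 12 *Phoebe zhennan* sites: the
pairwise F_ST matrix is linearised to F_ST/(1-F_ST) and correlated
(Mantel test) with great-circle distances and with ring distances routed
through the reference point R1 — dispersal along the habitat ring rather
than across the uninhabitable basin interior.
"""

from ringdiv import datasets
from ringdiv.diversity import linearize_fst
from ringdiv.geography import (mantel_test, ring_distance_matrix,
                               straight_distance_matrix)

sites = datasets.site_table(arcs="cluster")
fst = datasets.pairwise_fst()

straight = straight_distance_matrix(sites)
ring = ring_distance_matrix(sites)
order = straight.values.index
gen = linearize_fst(fst.loc[order, order].to_numpy(), clamp_negative=True)

r_s, p_s = mantel_test(gen, straight, n_perm=1000, seed=1)
r_r, p_r = mantel_test(gen, ring, n_perm=1000, seed=1)
print(f"straight-line distances: Mantel r = {r_s:.3f} (p = {p_s:.3f})")
print(f"ring distances:          Mantel r = {r_r:.3f} (p = {p_r:.3f})")
print("\nGenetic distance barely tracks straight-line geography but "
      "correlates strongly with distance along the habitat ring — the "
      "signature of ring-shaped diversification around a barrier.")
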