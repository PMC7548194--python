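"""Fit a geographic cline along a synthetic habitat ring.

Generates ring sites with a barrier gap, lays a sigmoid cline (centre
435 km, width 50 km) over their 1-D ring positions with site noise, and
fits the tail-model family by maximum likelihood with AIC comparison
against a no-cline null.
"""

import ringdiv as rd
from ringdiv.geography import fit_cline, ring_positions

sites = rd.generate_ring_sites(60, radius_km=150.0, gap_arc=30.0)
traits = rd.generate_clinal_trait(sites, center_km=435.0, width_km=50.0,
                                  p_min=0.0, p_max=1.0, noise_sd=0.02,
                                  seed=11)
pos = ring_positions(sites, origin="S01")

best, table = fit_cline(pos.to_numpy(), traits.loc[pos.index].to_numpy(),
                        n_starts=6, seed=3, extreme_quantile=0.1)
print("per-variant comparison (lower AIC is better):")
print(table.round(2).to_string(index=False))
lo, hi = best.support_center
print(f"\nbest model: '{best.variant}' tails")
print(f"  centre = {best.center:.1f} km  (2-lnL support {lo:.1f}-{hi:.1f})")
print(f"  width  = {best.width:.1f} km")
print("\nThe centre is the ring position of steepest genetic turnover; the "
      "width is the inverse of the maximum slope — a narrow width flags an "
      "abrupt transition (contact zone) rather than smooth isolation by "
      "distance.")
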