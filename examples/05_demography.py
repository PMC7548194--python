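"""SFS-based demographic model comparison at a reduced scale.

Simulates genotypes under a two-divergence history (East splits first,
then West1/West2), builds the observed joint folded SFS with the
lowest-MAF-per-locus SNP choice, fits the generating topology against a
trifurcation alternative by composite likelihood, and converts the
fitted divergence times to years.
"""

import ringdiv as rd
from ringdiv.scenarios import trifurcation_scenario, two_divergence_scenario
from ringdiv.sfs import fold_joint_sfs

truth = {"N_cur_East": 8e3, "N_cur_West1": 4e3, "N_cur_West2": 6e3,
         "N_Anc_pair": 3e3, "N_Anc_all": 8e3, "T_1": 2.4e4, "T_2": 8e3}
generator = two_divergence_scenario("East", "none", "truth").with_values(truth)
for p in generator.params.values():
    p.fixed = True

config = rd.SimulationConfig(gene_copies={"East": 16, "West1": 12,
                                          "West2": 12},
                             n_loci=1500, mu=1e-7, seed=3)
matrix, popmap = rd.simulate_genotypes(generator, config)
snp = rd.select_snp_per_locus(matrix, "lowest_maf")
observed = fold_joint_sfs(snp, popmap, {"East": ["East"],
                                        "West1": ["West1"],
                                        "West2": ["West2"]})
print(f"observed folded joint SFS over {observed.copies} gene copies, "
      f"{observed.n_snps:.0f} SNPs (one per locus)")

fits = []
for sc in (two_divergence_scenario("East", "none", "two_divergence"),
           trifurcation_scenario("none", "trifurcation")):
    fit = rd.fit_scenario(observed, sc, n_runs=2, n_cycles=3,
                          sims_per_eval=120, seed=5)
    fits.append(fit)
    print(f"  {fit.scenario:>15}: lnL = {fit.log_likelihood:.1f}, "
          f"k = {fit.k}, AIC = {fit.aic:.1f}")

table = rd.model_select(fits)
best = table.iloc[0]
print(f"\nbest model by AIC: {best['scenario']} "
      f"(delta-AIC to runner-up = {table['AIC'].iloc[1] - best['AIC']:.1f})")
winner = fits[[f.scenario for f in fits].index(best["scenario"])]
if "T_2" in winner.params:
    ratio = winner.params["T_1"] / winner.params["T_2"]
    print(f"fitted T_1/T_2 ratio = {ratio:.1f} (truth "
          f"{truth['T_1'] / truth['T_2']:.1f}); the default relative "
          "likelihood identifies the shape of the history, not its "
          "absolute scale — absolute times need mode='absolute' with a "
          "mutation rate")
ma = rd.years_to_ma(rd.generations_to_years(1_005_501, 15))
print(f"for scale: the published deep divergence, 1,005,501 generations, "
      f"is {ma} Ma at a 15-year generation time")
print("\nThe composite likelihood compares SFS shapes; AIC penalises the "
      "extra divergence-time parameter, so the two-divergence model wins "
      "only when the data carry a real second split.")
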