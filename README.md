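# ringdiv

Population-genomic analysis of **ring diversification**: species whose
populations encircle a patch of uninhabitable terrain, so that gene flow
follows the ring while straight-line geography misleads.  The motivating
system is the endangered golden-thread nanmu tree (*Phoebe zhennan*),
sampled at 12 sites around the Sichuan Basin; the package bundles the
published site coordinates, pairwise F_ST and demographic point estimates
for that system and reproduces its isolation-by-distance analysis from
those tables alone.

The library is aimed at population geneticists working with RAD-seq SNP
matrices who want, in one importable toolkit:

* **Filtering** — locus presence across populations, one SNP per locus
  (`first` or `lowest_maf`), inclusive MAF threshold, Hardy–Weinberg
  exact-test removal (per-population or pooled scope).
* **Diversity & differentiation** — %P, private alleles, H_O,
  unbiased H_E, π and F_IS in all-nucleotide and SNP panels; pairwise
  F_ST from AMOVA variance components with permutation p-values;
  Nm = (1−F_ST)/(4F_ST); hierarchical AMOVA (F_CT, F_SC, F_ST); PCA.
* **Ring geography** — haversine and ring distance matrices (cross-arc
  pairs routed through a reference point), Mantel tests on linearised
  F_ST/(1−F_ST), 1-D ring positions, and maximum-likelihood geographic
  clines Φ(x) = (1 + tanh(2(x−c)/w))/2 with exponential-tail variants
  compared by AIC.
* **Demographic inference** — joint folded SFS construction, a
  20-scenario model space for three lineages (two-divergence,
  admixture-origin, trifurcation families), expected SFS by coalescent
  simulation (branch-mode spectra via msprime), composite-likelihood
  fitting by cycles of conditional one-parameter maximisation, AIC model
  selection, parametric-bootstrap confidence intervals, and
  generation-time conversion of divergence times.
* **Synthetic data** — seeded generators for coalescent genotypes in
  RAD-style loci (with missingness), ring site geographies with a
  barrier gap, and clinal traits, so every stage is testable end to end.

## Worked example: straight-line vs ring isolation by distance

```bash
python examples/03_isolation_by_distance.py
```

```text
straight-line distances: Mantel r = 0.075 (p = 0.283)
ring distances:          Mantel r = 0.501 (p = 0.001)
```

Linearised genetic distance is uncorrelated with straight-line geography
(r ≈ 0.08, not significant) but strongly correlated with distance along
the habitat ring through the reference point R1 (r ≈ 0.50, p ≈ 0.001):
gene flow has followed the ring of suitable habitat around the basin
rather than crossing it.  The other scripts in `examples/` walk the
remaining capabilities — simulation + filtering, diversity and AMOVA,
cline fitting on a synthetic ring, and SFS-based model selection — each
printing the quantities it computes with a note on what they mean.

A 30-second demographic illustration:

```python
import ringdiv as rd

matrix, popmap = rd.simulate_genotypes(
    rd.model1_scenario(),                       # published point estimates
    rd.SimulationConfig(n_loci=600, mu=2e-9, seed=42))
filtered, report = rd.apply_filter_chain(matrix, popmap)
print(report.to_rows())

ma = rd.years_to_ma(rd.generations_to_years(1_005_501, 15))
print(ma)  # 15.08 — the deep East/West divergence in Ma
```

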