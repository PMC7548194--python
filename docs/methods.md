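# Methods

`ringdiv` implements a population-genomic pipeline for species sampled on
a ring of habitat around a dispersal barrier — the motivating system is
*Phoebe zhennan* (golden-thread nanmu), whose populations encircle the
Sichuan Basin.  The pipeline runs from called diploid genotypes (RAD-style
multi-SNP loci in VCF) through SNP filtering, diversity and
differentiation statistics, ring-distance isolation by distance,
geographic cline fitting, and SFS-based coalescent demographic model
selection.  A synthetic-data layer generates genotypes, ring geography and
clinal traits with the statistical structure each stage assumes, so every
method is testable end to end without access to any particular empirical
dataset.

## Data model and conventions

A `GenotypeMatrix` holds per-sample, per-SNP allele pairs in {0, 1} with
`(-1, -1)` for a missing genotype; a partially missing call is normalised
to wholly missing, matching diploid call semantics.  SNPs carry a locus
identifier and a position within the locus; in VCF, `CHROM` is the locus
and `POS` the 1-based offset within the short (default 85 bp) locus, the
natural convention for reference-free RAD output.  Coordinates are parsed
from D°M′S″ or decimal text and held as decimal degrees; all distances are
kilometres.

## Filtering

The retention chain mirrors standard RAD practice and is applied in a
fixed order, with a report recording locus/SNP counts after each rule
(counts can only fall):

1. **Presence** — a sample counts as having a locus only when none of the
   locus's SNP calls are missing; a population has the locus when at most
   25% (default) of its samples lack it; the locus is kept when at least
   `min_pops` populations (default: all) have it.
2. **One SNP per locus** — `first` (smallest position) for summary
   statistics, `lowest_maf` (minimum pooled minor-allele frequency, ties
   to the smaller position) for SFS construction.
3. **MAF** — pooled over non-missing calls across all samples, inclusive
   threshold (a SNP at exactly 0.05 is kept).  Pooling is deliberate: the
   frequency filter runs before any population-level analysis.
4. **HWE** — the exact test conditional on allele counts (no mid-p
   correction), the method family behind the common VCF filtering tools.
   The default scope is per population, removing a SNP if *any*
   population rejects at α = 0.05: pooled-sample testing would confound
   population structure (the Wahlund effect) with genotyping artefacts.
   A `pooled` scope is available; populations with fewer than two
   genotyped samples are skipped with a warning.

## Diversity and differentiation

Observed heterozygosity is the fraction of heterozygous calls; expected
heterozygosity uses the unbiased small-sample correction
H_E = 2n/(2n−1) · 2p(1−p).  For a biallelic site this estimator coincides
with per-site nucleotide diversity (the average pairwise difference among
gene copies), which is why the SNP-panel `HE` and `pi` columns agree;
pipelines that report them separately use the uncorrected 1−Σp² for H_E.
Two panels are reported: *all-nucleotide*, dividing SNP sums by
`locus_length × n_loci` so invariant sites contribute zeros, and
*variant-only*, averaging over SNPs.  F_IS = 1 − H_O/H_E (defined as 0
when H_E = 0).  A private allele is one observed in exactly one
population.

F_ST and the hierarchical AMOVA use variance components of allele
indicators over gene copies — the frequency-based AMOVA estimator in the
Excoffier–Smouse–Quattro family.  Per SNP, sums of squares among and
within units are converted to components with the standard
unequal-sample-size coefficients; components are summed over SNPs before
taking ratios ("ratio of sums", as in Weir–Cockerham practice).  The
three-level design partitions variance among groups (F_CT), among
populations within groups (F_SC) and within populations (F_ST), with
permutation tests that shuffle the matching unit for each index:
individuals across all populations (F_ST), individuals within their group
(F_SC), whole populations across groups (F_CT).  When every group holds a
single population, F_SC is undefined (NaN, with a warning) and the design
reduces exactly to the pairwise two-level machinery — a property the test
suite checks.

Negative component estimates are retained; a zero-clamped view of the
pairwise matrix is also provided, since slightly negative pairwise values
are conventionally printed as zero.  The island-model conversion
Nm = (1 − F_ST)/(4 F_ST) and the isolation-by-distance linearisation
F_ST/(1 − F_ST) (with an optional clamp) are provided as closed forms.

PCA operates on mean-imputed, centred genotype dosages via SVD, with
deterministic component signs (largest-magnitude loading positive).

## Geography: ring distances, Mantel, clines

Great-circle distances use the haversine formula on a sphere of radius
6371.0088 km (IUGG mean); at the precision of site coordinates an
ellipsoid would change nothing.  *Ring* distances respect the habitat
ring: within-arc pairs keep their great-circle distance, while a
cross-arc pair is routed through the single reference point on the far
side of the ring, `d(w, ref) + d(ref, e)`.

For the bundled published sites, two west/east arc assignments ship:
*geographic* (side of the QCS–QL barrier) and *cluster* (the two genetic
clusters, under which QCS and TL are "eastern" and YC and CN2 "western"
despite their map positions).  The cluster assignment, with negative
F_ST clamped to zero, is the default because it is the construction under
which the package reproduces the published isolation-by-distance
correlations; the acceptance script prints the sensitivity of the ring
correlation to both choices (it ranges from ~0.17 under geographic arcs
to ~0.50 under cluster arcs).

The Mantel statistic is the Pearson correlation over lower-triangle
entries; the p-value co-permutes rows and columns of the genetic matrix,
with the conventional (count + 1)/(n_perm + 1) estimator.  Permutation
p-values are verified to be uniform under the null.

1-D ring positions order sites by angle around their centroid, cut the
circle at the gap, and accumulate great-circle legs between consecutive
sites.  The gap is located from the reference point when one is present
(its antipode lies inside the gap by construction), can be named
explicitly (`gap_between=("QCS", "QL")` for the published sites, whose
largest *angular* gap is the unsampled northern arc rather than the
barrier), and falls back to the largest angular gap.  An origin interior
to the resulting chain is rejected as ambiguous.

The cline model is the standard sigmoid Φ(x) = (1 + tanh(2(x−c)/w))/2
with centre `c` (position of steepest change) and width `w` (inverse of
the maximum slope, so the central slope of the scaled cline is
(pMax−pMin)/w).  Optional exponential tails replace the sigmoid beyond a
distance δ from the centre; the tail's log-slope at the joint is τ times
the sigmoid's, so τ = 1 keeps the profile C¹-smooth and smaller τ
flattens the approach to the asymptote.  Variants: none, left, right,
mirror (shared δ, τ), both (separate pairs).  Fitting maximises a
homoscedastic Gaussian likelihood over site trait values (a deliberate
simplification of per-site variance modelling), from multiple random
starts in both ascending and descending orientation, with pMin/pMax fixed
to observed trait extremes.  AIC parameter counts include the error
variance: null 2, none 3, left/right/mirror 5, both 7.  2-lnL support
ranges for centre and width are profiled along one axis with the other
parameters held at their estimates (a slice, not a full profile) using
bisection to locate the crossings.

Raw observed extremes are inflated by site noise (the expected extreme of
n noisy flat-region sites lies ~2 SD beyond the asymptote), which biases
the fitted width upward — about +20% at noise SD 0.02 on a 60-site
transect.  `fit_cline(extreme_quantile=0.1)` instead fixes pMin/pMax to
the means of the lower/upper decile of trait values, a noise-robust
version of "fixed to observed" that removes most of the bias; the
recovery analyses use it.

## Synthetic data

Genotypes are simulated with the msprime coalescent: each locus is an
independent non-recombining 85 bp segment; mutations follow an
infinite-sites model within the locus (continuous positions under a
binary model, so multi-hit sites cannot arise) at a per-site rate μ.
The default μ = 1e−8/site/generation is a synthetic-data choice in the
range typical for woody plants, used only to exercise the pipeline —
nothing downstream depends on it unless absolute-mode fitting is
requested, where μ is an explicit argument.  Diploids pair gene copies at
random within a population (random mating); missing calls are injected
independently per call at a configurable rate.  The default sampling
configuration is 30/24/24 gene copies for East/West1/West2.  Everything
is deterministic given the configuration seed.

Ring sites are placed on an annulus of configurable radius with an
angular gap (the barrier) at a configurable bearing; the chain's first
half is labelled west, the second east, and a reference point sits
opposite the gap.  Clinal traits evaluate the no-tail sigmoid at ring
positions plus Gaussian noise.

What the generators do *not* emulate: sequencing error and allele
dropout, depth-dependent missingness, paralog collapse, selection,
linkage between loci, recombination within loci.  Tests passing on
synthetic data therefore demonstrate the estimators' correctness under
the neutral model they assume, not robustness to RAD-specific artefacts.

## Demographic inference

The model space holds 20 three-population scenarios: nine two-divergence
models (each extant cluster in turn splitting first × gene flow none /
recent / recent+historical), nine admixture-origin models (each cluster
created by admixture of the other two × the same flow variants), and two
trifurcations (without and with recent flow).  Model 1 — East diverging
first, then West1/West2, with recent migration among all pairs and
historical migration between East and the western ancestor — ships
pre-parameterised with the published point estimates.  Sizes are diploid
Ne, times generations; migration parameters are backward per-generation
lineage-movement probabilities (the coalescent-simulator convention,
whose printed magnitudes are rate-like even where tables label them 2Nm);
`rate_to_2nm`/`two_nm_to_rate` convert.  Parameter search bounds default
to sizes and times in [1e3, 5e6] and rates in [1e−9, 1e−3], drawn
log-uniform.

The observed spectrum is the joint folded SFS over the group gene
copies, built from fully genotyped SNPs (sites with a missing call among
the grouped samples are dropped rather than projected) with one SNP per
locus.  Folding pools each cell with its complement, keeping the
representative with the smaller total minor-allele count; exact ties
(total equal to half the pooled copies) break lexicographically.  The
monomorphic corners are masked.

The expected SFS under a scenario is estimated by simulating independent
genealogies and averaging *branch-mode* frequency spectra — the expected
branch length subtending each configuration — which is the
mutation-rate-scaled expected SFS with far smaller Monte-Carlo variance
than counting simulated mutations.  Two likelihood modes:

* **relative** (default): cell probabilities renormalised over unmasked
  cells; multinomial composite likelihood conditioned on sites being
  SNPs.  No mutation rate enters, and only the shape of the history
  (relative sizes and times) is identified — scaling all sizes and times
  by a constant leaves the likelihood unchanged.
* **absolute**: cell counts treated as independent Poissons with mean
  μ × locus length × n_loci × (branch SFS), identifying absolute sizes
  and times.  Used by the parameter-recovery analyses.

Expected-cell probabilities below 1/(10 · sims · S) are floored before
the log (standard composite-likelihood stabilisation).  Fitting runs many
independent searches from log-uniform draws; each run cycles conditional
one-parameter maximisations (bounded scalar search on log10 scale, ~8
evaluations per parameter) with one simulation seed shared by all
evaluations of a cycle (common random numbers, suppressing Monte-Carlo
jitter in the 1-D searches) and dynamic bounds that keep divergence times
ordered.  Runs are compared on a final evaluation under a single scoring
seed; a fit that never improves on its initialisations raises a
diagnostic failure.  AIC = 2k − 2 lnL with k the number of free
parameters; goodness of fit is the distance of lnL to the self-likelihood
bound (the observed SFS scored against its own relative frequencies).
Parametric bootstrap draws synthetic spectra at the point estimates
(multinomial or Poisson by mode), refits each with reduced runs/cycles,
and reports order-statistic 2.5/97.5 percentiles; failed refits are
excluded and fewer than half succeeding flags the CIs unreliable.
Generations convert to years linearly with a default generation time of
15 years.

## Problem sizes in the test and acceptance suites

The verification analyses run at reduced scale, chosen as the smallest
sizes at which each check is statistically informative: neutral-SFS
goodness of fit on >= 10,000 one-SNP loci (16,000 simulated loci, the
polymorphic majority retained); two-population split-time
recovery on ~1,200 loci; model-family recovery on 2,500 loci (~5,000
SNPs) at 16/12/12 gene copies with 2 runs × 3 cycles per candidate;
scaled three-lineage recovery (published values ÷100 in sizes and times,
migration ×100 to preserve Nm) on 3,000 loci at μ = 2e−7 and 30/24/24
copies, with 16 bootstrap replicates; cline recovery on a 60-site
transect, whose spacing (~15 km) resolves the 50 km target width —
width is unidentifiable when site spacing exceeds it.

## Known limitations

* The composite likelihood treats SNPs as independent; linkage within a
  locus is handled only by the one-SNP-per-locus rule, and linkage-aware
  likelihoods are out of scope.
* The AMOVA is frequency-based (allele indicators), not
  haplotype-distance-based; with unphased biallelic SNPs the two agree up
  to the within-individual level, which is not modelled (no F_IS level in
  the AMOVA).
* Cline support ranges are likelihood slices, not full profiles, and the
  Gaussian trait model is homoscedastic across sites.
* `expected_sfs` assumes every sampled population persists to time 0 and
  three-population scenarios; arbitrary deme numbers, recombination and
  serial sampling are not supported.
* The search bounds and run/cycle defaults are pragmatic; for real
  inference the full 50 runs × 40 cycles regime is the intended setting,
  and the reduced regimes used in tests trade precision for runtime.
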