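"""Locus- and SNP-level retention rules for RAD genotype matrices.

The chain mirrors the order the rules are applied in RAD pipelines:

1. presence — keep loci genotyped in enough populations, with bounded
   within-population missingness;
2. one SNP per locus — ``first`` (smallest position) or ``lowest_maf``;
3. minor-allele-frequency threshold (inclusive);
4. Hardy–Weinberg exact-test removal.

A sample counts as genotyped at a locus only if none of the locus's SNP
calls are missing for it.  MAF is computed on non-missing calls pooled
across all samples, since the frequency filter is applied before any
population-level analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .core import GenotypeMatrix, PopulationMap


@dataclass
class FilterReport:
    """Locus/SNP counts after each rule; counts never increase."""

    stages: list = field(default_factory=list)

    def record(self, rule: str, matrix: GenotypeMatrix) -> None:
        if self.stages:
            _, loci, snps = self.stages[-1]
            if matrix.n_loci > loci or matrix.n_snps > snps:
                raise ValueError("filter increased locus/SNP counts")
        self.stages.append((rule, matrix.n_loci, matrix.n_snps))

    def to_rows(self) -> list:
        return [
            {"rule": r, "loci": l, "snps": s} for r, l, s in self.stages
        ]


def pooled_maf(matrix: GenotypeMatrix) -> np.ndarray:
    """Per-SNP minor-allele frequency over non-missing calls (NaN if none)."""
    dosage = matrix.dosage()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nanmean(dosage, axis=0) / 2.0
    return np.minimum(p, 1.0 - p)


def filter_presence(matrix: GenotypeMatrix, popmap: PopulationMap,
                    min_pops: int | None = None,
                    max_missing_within: float = 0.25) -> GenotypeMatrix:
    """Keep loci present in at least ``min_pops`` populations.

    A population counts as having the locus when the fraction of its
    samples missing the locus (any missing call across the locus's SNPs)
    is at most ``max_missing_within``.  ``min_pops`` defaults to all
    populations (100% presence).
    """
    if matrix.n_snps == 0:
        raise ValueError("empty genotype matrix")
    by_pop = popmap.sample_indices(matrix)
    if min_pops is None:
        min_pops = len(by_pop)
    if min_pops > len(by_pop):
        raise ValueError("min_pops exceeds the number of populations")
    if not 0 <= max_missing_within <= 1:
        raise ValueError("max_missing_within must be in [0, 1]")
    missing = matrix.missing_mask()
    keep = []
    for locus, snp_idx in matrix.locus_snp_indices().items():
        n_ok = 0
        for idx in by_pop.values():
            miss_frac = missing[np.ix_(idx, snp_idx)].any(axis=1).mean()
            if miss_frac <= max_missing_within:
                n_ok += 1
        if n_ok >= min_pops:
            keep.extend(snp_idx.tolist())
    return matrix.take_snps(sorted(keep))


def select_snp_per_locus(matrix: GenotypeMatrix,
                         strategy: str = "first") -> GenotypeMatrix:
    """Retain exactly one SNP per locus.

    ``first`` keeps the smallest position; ``lowest_maf`` keeps the SNP
    with minimal pooled minor-allele frequency, ties broken by smallest
    position.
    """
    if strategy not in ("first", "lowest_maf"):
        raise ValueError(f"unknown strategy {strategy!r}")
    maf = pooled_maf(matrix) if strategy == "lowest_maf" else None
    keep = []
    pos = matrix.snps["pos"].to_numpy()
    for locus, snp_idx in matrix.locus_snp_indices().items():
        if strategy == "first":
            keep.append(snp_idx[np.argmin(pos[snp_idx])])
        else:
            m = maf[snp_idx]
            best = np.nanmin(m)
            tied = snp_idx[m == best]
            keep.append(tied[np.argmin(pos[tied])])
    return matrix.take_snps(sorted(keep))


def filter_maf(matrix: GenotypeMatrix, min_maf: float = 0.05) -> GenotypeMatrix:
    """Keep SNPs with pooled minor-allele frequency >= ``min_maf``."""
    if not 0 <= min_maf <= 0.5:
        raise ValueError("min_maf must be in [0, 0.5]")
    maf = pooled_maf(matrix)
    keep = np.flatnonzero(maf >= min_maf)
    return matrix.take_snps(keep)


# ---------------------------------------------------------------------------
# Hardy–Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_pvalue(n_het: int, n_hom_minor: int, n_hom_major: int) -> float:
    """Exact Hardy–Weinberg test conditional on allele counts (no mid-p).

    The probability of each heterozygote count compatible with the
    observed allele counts is

        P(n_AB) = n! / (n_AA! n_AB! n_BB!) * 2^n_AB * n_A! n_B! / (2n)!

    and the p-value sums the probabilities of all configurations no more
    probable than the observed one.
    """
    n = n_het + n_hom_minor + n_hom_major
    n_minor = n_het + 2 * n_hom_minor
    n_major = 2 * n - n_minor
    if n == 0:
        return 1.0

    def log_prob(nab: int) -> float:
        naa = (n_minor - nab) // 2
        nbb = n - nab - naa
        return (
            gammaln(n + 1) - gammaln(naa + 1) - gammaln(nab + 1)
            - gammaln(nbb + 1) + nab * np.log(2.0)
            + gammaln(n_minor + 1) + gammaln(n_major + 1) - gammaln(2 * n + 1)
        )

    # heterozygote counts share the parity of the minor-allele count
    hets = range(n_minor % 2, min(n_minor, n_major) + 1, 2)
    logs = np.array([log_prob(h) for h in hets])
    probs = np.exp(logs - logs.max())
    probs /= probs.sum()
    p_obs = probs[list(hets).index(n_het)]
    return float(probs[probs <= p_obs * (1 + 1e-12)].sum())


def _genotype_counts(matrix: GenotypeMatrix, snp: int, idx) -> tuple:
    calls = matrix.calls[idx, snp, :]
    ok = calls[:, 0] >= 0
    calls = calls[ok]
    dos = calls.sum(axis=1)
    n_het = int((dos == 1).sum())
    n_alt = int((dos == 2).sum())
    n_ref = int((dos == 0).sum())
    # orient on the minor allele
    if 2 * n_alt + n_het <= 2 * n_ref + n_het:
        return n_het, n_alt, n_ref
    return n_het, n_ref, n_alt


def filter_hwe(matrix: GenotypeMatrix, popmap: PopulationMap | None = None,
               alpha: float = 0.05, scope: str = "per_population"
               ) -> GenotypeMatrix:
    """Remove SNPs whose HWE exact-test p-value is below ``alpha``.

    ``scope="per_population"`` (default) tests within each population and
    removes the SNP if any population fails — pooled-sample testing would
    confound structure (the Wahlund effect) with true disequilibrium.
    ``scope="pooled"`` tests all samples together.  Populations with fewer
    than two genotyped samples at a SNP are skipped with a warning.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if scope not in ("per_population", "pooled"):
        raise ValueError(f"unknown scope {scope!r}")
    if scope == "per_population":
        if popmap is None:
            raise ValueError("per-population scope requires a population map")
        groups = list(popmap.sample_indices(matrix).values())
    else:
        groups = [np.arange(matrix.n_samples)]
    keep = []
    warned = False
    for j in range(matrix.n_snps):
        failed = False
        for idx in groups:
            n_het, n_hom_minor, n_hom_major = _genotype_counts(matrix, j, idx)
            if n_het + n_hom_minor + n_hom_major < 2:
                if not warned:
                    warnings.warn(
                        "population with < 2 genotyped samples skipped in "
                        "HWE testing", stacklevel=2)
                    warned = True
                continue
            if hwe_exact_pvalue(n_het, n_hom_minor, n_hom_major) < alpha:
                failed = True
                break
        if not failed:
            keep.append(j)
    return matrix.take_snps(keep)


def count_ratio(n_snps: int, n_polymorphic_loci: int) -> float:
    """SNPs per polymorphic locus, rounded to 2 decimals for reporting."""
    if n_polymorphic_loci <= 0:
        raise ValueError("polymorphic locus count must be positive")
    return round(n_snps / n_polymorphic_loci, 2)


def apply_filter_chain(matrix: GenotypeMatrix, popmap: PopulationMap,
                       min_pops: int | None = None,
                       max_missing_within: float = 0.25,
                       snp_per_locus: str = "first",
                       min_maf: float = 0.05,
                       hwe_alpha: float = 0.05,
                       hwe_scope: str = "per_population"
                       ) -> tuple[GenotypeMatrix, FilterReport]:
    """Run the full retention chain, recording counts after each rule."""
    report = FilterReport()
    report.record("input", matrix)
    m = filter_presence(matrix, popmap, min_pops, max_missing_within)
    report.record("presence", m)
    m = select_snp_per_locus(m, snp_per_locus)
    report.record("one_snp_per_locus", m)
    m = filter_maf(m, min_maf)
    report.record("maf", m)
    m = filter_hwe(m, popmap, hwe_alpha, hwe_scope)
    report.record("hwe", m)
    return m, report
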