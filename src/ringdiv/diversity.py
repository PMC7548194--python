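"""Per-population diversity, differentiation, AMOVA and the PCA axis.

F_ST and the hierarchical AMOVA use variance components of allele
indicators over gene copies (the frequency-based AMOVA estimator, in the
Excoffier–Smouse–Quattro family): sums of squares are computed per SNP
from population allele frequencies, converted to variance components with
unequal-sample-size coefficients, and summed over SNPs before taking
ratios.  Negative component estimates are retained; a zero-clamped view
is also reported because slightly negative pairwise estimates are
conventionally printed as zero.

Expected heterozygosity uses the unbiased 2n/(2n-1) correction, under
which per-site H_E coincides with per-site nucleotide diversity for a
biallelic SNP.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, PopulationMap


# ---------------------------------------------------------------------------
# per-population summaries
# ---------------------------------------------------------------------------

def _pop_site_arrays(matrix: GenotypeMatrix, idx) -> dict:
    """Per-SNP gene-copy counts, alt frequencies and het fractions for one
    population (NaN where no genotyped sample)."""
    calls = matrix.calls[idx, :, :]
    ok = calls[:, :, 0] >= 0
    n_geno = ok.sum(axis=0).astype(float)
    dos = np.where(ok, calls.sum(axis=2), 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = dos.sum(axis=0) / (2.0 * n_geno)
        het = np.where(ok, calls[:, :, 0] != calls[:, :, 1], False)
        h_obs = het.sum(axis=0) / n_geno
    return {"n": n_geno, "p": p, "h_obs": h_obs}


def per_population_stats(matrix: GenotypeMatrix, popmap: PopulationMap,
                         locus_length: int = 85) -> pd.DataFrame:
    """Diversity summaries per population, in two panels.

    The all-nucleotide panel (``*_rad``) divides SNP sums by the total
    number of sites, ``locus_length * n_loci`` — i.e. invariant positions
    contribute zeros.  The variant-only panel (``*_snp``) averages over
    the SNPs of the matrix.  Columns: ``pct_polymorphic`` (percent of all
    nucleotide sites polymorphic within the population),
    ``HO/HE/pi/FIS`` per panel.
    """
    by_pop = popmap.sample_indices(matrix)
    total_sites = float(locus_length * matrix.n_loci)
    rows = []
    for pop, idx in by_pop.items():
        if len(idx) == 0:
            raise ValueError(f"population {pop!r} has no samples")
        arr = _pop_site_arrays(matrix, idx)
        n, p, h_obs = arr["n"], arr["p"], arr["h_obs"]
        usable = n >= 1
        two_n = 2.0 * n
        with np.errstate(invalid="ignore", divide="ignore"):
            h_exp = two_n / (two_n - 1.0) * 2.0 * p * (1.0 - p)
        h_exp = np.where(two_n > 1, h_exp, np.nan)
        poly = usable & (p > 0) & (p < 1)

        def _panel(values):
            v = np.where(usable, np.nan_to_num(values, nan=0.0), 0.0)
            snp_mean = float(np.nanmean(np.where(usable, values, np.nan)))
            rad_mean = float(v.sum() / total_sites)
            return rad_mean, snp_mean

        ho_rad, ho_snp = _panel(h_obs)
        he_rad, he_snp = _panel(h_exp)
        pi_rad, pi_snp = _panel(h_exp)  # per-site pi == unbiased H_E
        fis_rad = 1.0 - ho_rad / he_rad if he_rad > 0 else 0.0
        fis_snp = 1.0 - ho_snp / he_snp if he_snp > 0 else 0.0
        rows.append({
            "population": pop,
            "pct_polymorphic": 100.0 * poly.sum() / total_sites,
            "HO_rad": ho_rad, "HE_rad": he_rad, "pi_rad": pi_rad,
            "FIS_rad": fis_rad,
            "HO_snp": ho_snp, "HE_snp": he_snp, "pi_snp": pi_snp,
            "FIS_snp": fis_snp,
        })
    return pd.DataFrame(rows).set_index("population")


def nucleotide_diversity(matrix: GenotypeMatrix, idx=None,
                         per_site_total: float | None = None) -> float:
    """Average pairwise difference, summed over SNPs.

    With ``per_site_total`` the sum is divided by that many sites (the
    all-nucleotide convention); otherwise by the number of SNPs.
    """
    if idx is None:
        idx = np.arange(matrix.n_samples)
    arr = _pop_site_arrays(matrix, idx)
    n, p = arr["n"], arr["p"]
    two_n = 2.0 * n
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = two_n / (two_n - 1.0) * 2.0 * p * (1.0 - p)
    pi = np.nan_to_num(pi, nan=0.0)
    denom = per_site_total if per_site_total is not None else matrix.n_snps
    return float(pi.sum() / denom)


def private_alleles(matrix: GenotypeMatrix, popmap: PopulationMap) -> dict:
    """Count alleles observed in exactly one population, per population."""
    by_pop = popmap.sample_indices(matrix)
    if len(by_pop) < 2:
        raise ValueError("private alleles need at least two populations")
    pops = list(by_pop)
    # presence[pop, snp, allele]
    presence = np.zeros((len(pops), matrix.n_snps, 2), dtype=bool)
    for k, pop in enumerate(pops):
        calls = matrix.calls[by_pop[pop], :, :]
        ok = calls[:, :, 0] >= 0
        for allele in (0, 1):
            presence[k, :, allele] = ((calls == allele).any(axis=2) & ok).any(axis=0)
    n_pops_with = presence.sum(axis=0)
    counts = {}
    for k, pop in enumerate(pops):
        counts[pop] = int((presence[k] & (n_pops_with == 1)).sum())
    return counts


# ---------------------------------------------------------------------------
# F_ST and AMOVA variance components
# ---------------------------------------------------------------------------

def _two_level_components(matrix: GenotypeMatrix, groups: list) -> tuple:
    """Summed (sigma2_among, sigma2_within) over SNPs for >= 2 populations."""
    stats = [_pop_site_arrays(matrix, idx) for idx in groups]
    ns = np.stack([2.0 * s["n"] for s in stats])       # gene copies per pop
    ps = np.stack([s["p"] for s in stats])
    with np.errstate(invalid="ignore", divide="ignore"):
        N = ns.sum(axis=0)
        valid = (ns >= 1).all(axis=0) & (N > len(groups))
        pbar = np.where(valid, np.nansum(ns * ps, axis=0) / N, np.nan)
        ss_among = np.nansum(ns * (ps - pbar) ** 2, axis=0)
        ss_within = np.nansum(ns * ps * (1.0 - ps), axis=0)
        d = float(len(groups))
        ms_among = ss_among / (d - 1.0)
        ms_within = ss_within / (N - d)
        n_prime = (N - (ns ** 2).sum(axis=0) / N) / (d - 1.0)
        sig_a = (ms_among - ms_within) / n_prime
        sig_w = ms_within
    sig_a = np.where(valid, sig_a, 0.0)
    sig_w = np.where(valid, sig_w, 0.0)
    return float(np.nansum(sig_a)), float(np.nansum(sig_w))


@dataclass
class FstMatrix:
    """Pairwise F_ST with permutation p-values."""

    values: pd.DataFrame
    pvalues: pd.DataFrame

    def clamped(self) -> pd.DataFrame:
        """Negative estimates reported as zero."""
        return self.values.clip(lower=0.0)


def pairwise_fst(matrix: GenotypeMatrix, popmap: PopulationMap,
                 n_permutations: int = 0, seed: int | None = None
                 ) -> FstMatrix:
    """Pairwise F_ST from two-level variance components.

    For each population pair, F_ST = sigma2_a / (sigma2_a + sigma2_w)
    summed over SNPs.  The permutation p-value is the fraction of
    individual relabelings between the two populations with F_ST at least
    the observed value.  Populations of a single sample are excluded with
    a warning.
    """
    by_pop = popmap.sample_indices(matrix)
    pops = [p for p, idx in by_pop.items() if len(idx) >= 2]
    dropped = set(by_pop) - set(pops)
    if dropped:
        warnings.warn(f"populations of one sample excluded: {sorted(dropped)}",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    vals = pd.DataFrame(0.0, index=pops, columns=pops)
    pvals = pd.DataFrame(np.nan, index=pops, columns=pops)
    for a in range(len(pops)):
        for b in range(a + 1, len(pops)):
            ia, ib = by_pop[pops[a]], by_pop[pops[b]]
            sig_a, sig_w = _two_level_components(matrix, [ia, ib])
            denom = sig_a + sig_w
            fst = sig_a / denom if denom > 0 else 0.0
            vals.iloc[a, b] = vals.iloc[b, a] = fst
            if n_permutations:
                pool = np.concatenate([ia, ib])
                count = 0
                for _ in range(n_permutations):
                    perm = rng.permutation(pool)
                    pa, pb = perm[: len(ia)], perm[len(ia):]
                    sa, sw = _two_level_components(matrix, [pa, pb])
                    d = sa + sw
                    f = sa / d if d > 0 else 0.0
                    if f >= fst:
                        count += 1
                p = count / n_permutations
                pvals.iloc[a, b] = pvals.iloc[b, a] = p
    return FstMatrix(values=vals, pvalues=pvals)


def fst_to_nm(fst: float) -> float:
    """Island-model migrant number, Nm = (1 - F_ST) / (4 F_ST)."""
    if not 0 < fst <= 1:
        raise ValueError("Nm is defined for F_ST in (0, 1]")
    return (1.0 - fst) / (4.0 * fst)


def nm_to_fst(nm: float) -> float:
    """Inverse of :func:`fst_to_nm`."""
    if nm < 0:
        raise ValueError("Nm must be non-negative")
    return 1.0 / (1.0 + 4.0 * nm)


def linearize_fst(fst, clamp_negative: bool = False):
    """Genetic distance F_ST / (1 - F_ST); optionally clamp negatives to 0.

    Accepts scalars or arrays; F_ST = 1 maps to infinity and raises.
    """
    arr = np.asarray(fst, dtype=float)
    if np.any(arr >= 1.0):
        raise ValueError("linearised F_ST undefined at F_ST = 1")
    if clamp_negative:
        arr = np.clip(arr, 0.0, None)
    out = arr / (1.0 - arr)
    return float(out) if np.isscalar(fst) else out


# ---------------------------------------------------------------------------
# hierarchical AMOVA
# ---------------------------------------------------------------------------

@dataclass
class AmovaResult:
    sigma_a: float          # among groups
    sigma_b: float          # among populations within groups
    sigma_c: float          # within populations
    f_ct: float
    f_sc: float
    f_st: float
    percent: dict
    pvalues: dict

    def total(self) -> float:
        return self.sigma_a + self.sigma_b + self.sigma_c


def _nested_components(matrix: GenotypeMatrix, group_pop_idx: list) -> tuple:
    """Summed three-level components over SNPs.

    ``group_pop_idx``: list of groups, each a list of per-population
    sample-index arrays.
    """
    n_groups = len(group_pop_idx)
    n_pops = sum(len(g) for g in group_pop_idx)
    pop_stats = [[_pop_site_arrays(matrix, idx) for idx in g]
                 for g in group_pop_idx]
    S = matrix.n_snps
    sig_a = sig_b = sig_c = 0.0
    for j in range(S):
        nij, pij = [], []
        for g in pop_stats:
            nij.append(np.array([2.0 * s["n"][j] for s in g]))
            pij.append(np.array([s["p"][j] for s in g]))
        if any((n < 1).any() for n in nij):
            continue
        Ni = np.array([n.sum() for n in nij])
        N = Ni.sum()
        if N <= n_pops:
            continue
        pi_bar = np.array([(n * p).sum() / n.sum()
                           for n, p in zip(nij, pij)])
        pbar = (Ni * pi_bar).sum() / N
        ss_wp = sum((n * p * (1.0 - p)).sum() for n, p in zip(nij, pij))
        ss_ap = sum((n * (p - pb) ** 2).sum()
                    for n, p, pb in zip(nij, pij, pi_bar))
        ss_ag = (Ni * (pi_bar - pbar) ** 2).sum()
        ms_wp = ss_wp / (N - n_pops)
        ms_ap = ss_ap / (n_pops - n_groups) if n_pops > n_groups else np.nan
        ms_ag = ss_ag / (n_groups - 1)
        sum_nij2_over_Ni = sum((n ** 2).sum() / n.sum() for n in nij)
        sum_nij2_over_N = sum((n ** 2).sum() for n in nij) / N
        n1 = ((N - sum_nij2_over_Ni) / (n_pops - n_groups)
              if n_pops > n_groups else np.nan)
        n2 = (sum_nij2_over_Ni - sum_nij2_over_N) / (n_groups - 1)
        n3 = (N - (Ni ** 2).sum() / N) / (n_groups - 1)
        c = ms_wp
        b = (ms_ap - ms_wp) / n1 if n_pops > n_groups else 0.0
        a = (ms_ag - c - n2 * b) / n3
        sig_a += a
        sig_b += b
        sig_c += c
    return sig_a, sig_b, sig_c


def amova(matrix: GenotypeMatrix, popmap: PopulationMap, grouping: dict,
          n_permutations: int = 0, seed: int | None = None) -> AmovaResult:
    """Hierarchical AMOVA: groups / populations within groups / within.

    ``grouping`` maps population code -> group label and must cover every
    population, with at least two groups.  Permutation tests (when
    ``n_permutations`` > 0): F_ST permutes individuals among populations,
    F_SC permutes individuals among populations within their group, and
    F_CT permutes whole populations among groups.
    """
    by_pop = popmap.sample_indices(matrix)
    groups: dict = {}
    for pop in by_pop:
        if pop not in grouping:
            raise ValueError(f"population {pop!r} missing from grouping")
        groups.setdefault(grouping[pop], []).append(pop)
    if len(groups) < 2:
        raise ValueError("AMOVA needs at least two groups")
    all_singleton = all(len(pops) == 1 for pops in groups.values())
    if all_singleton:
        warnings.warn(
            "every group holds a single population: F_SC is undefined and "
            "the design reduces to a two-level AMOVA", stacklevel=2)

    def components(assign_groups: dict, pop_indices: dict) -> tuple:
        gpi = [[pop_indices[p] for p in pops]
               for pops in assign_groups.values()]
        return _nested_components(matrix, gpi)

    sa, sb, sc = components(groups, by_pop)
    total = sa + sb + sc
    f_ct = sa / total
    f_sc = sb / (sb + sc) if not all_singleton else float("nan")
    f_st = (sa + sb) / total
    percent = {"among_groups": 100.0 * sa / total,
               "among_pops_within_groups": 100.0 * sb / total,
               "within_pops": 100.0 * sc / total}
    pvalues: dict = {}
    if n_permutations:
        rng = np.random.default_rng(seed)
        pops = list(by_pop)
        sizes = {p: len(by_pop[p]) for p in pops}
        obs = {"f_st": f_st, "f_sc": f_sc, "f_ct": f_ct}
        count = {k: 0 for k in obs}
        all_idx = np.concatenate([by_pop[p] for p in pops])
        for _ in range(n_permutations):
            # F_ST: individuals shuffled among all populations
            perm = rng.permutation(all_idx)
            out = {}
            start = 0
            for p in pops:
                out[p] = perm[start:start + sizes[p]]
                start += sizes[p]
            a, b, c = components(groups, out)
            if (a + b) / (a + b + c) >= obs["f_st"]:
                count["f_st"] += 1
            # F_SC: individuals shuffled within their group
            out2 = {}
            for pops_in_g in groups.values():
                pool = np.concatenate([by_pop[p] for p in pops_in_g])
                perm_g = rng.permutation(pool)
                start = 0
                for p in pops_in_g:
                    out2[p] = perm_g[start:start + sizes[p]]
                    start += sizes[p]
            a, b, c = components(groups, out2)
            if not all_singleton and b / (b + c) >= obs["f_sc"]:
                count["f_sc"] += 1
            # F_CT: whole populations shuffled among groups
            shuffled = rng.permutation(pops)
            start = 0
            galt: dict = {}
            for g, pops_in_g in groups.items():
                galt[g] = list(shuffled[start:start + len(pops_in_g)])
                start += len(pops_in_g)
            a, b, c = components(galt, by_pop)
            if a / (a + b + c) >= obs["f_ct"]:
                count["f_ct"] += 1
        pvalues = {k: (count[k] + 1) / (n_permutations + 1) for k in count}
    return AmovaResult(sa, sb, sc, f_ct, f_sc, f_st, percent, pvalues)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca_genotypes(matrix: GenotypeMatrix, n_components: int | None = None,
                  scale: bool = False) -> tuple:
    """Principal components of centered genotype dosage.

    Missing dosages are mean-imputed per SNP; SNPs with no genotyped
    sample are dropped with a warning.  Returns ``(scores, fractions)``:
    per-sample component scores and the explained-variance fractions in
    descending order.  Component signs are fixed so the largest-magnitude
    loading of each axis is positive.
    """
    d = matrix.dosage()
    all_missing = np.isnan(d).all(axis=0)
    if all_missing.any():
        warnings.warn(f"{int(all_missing.sum())} all-missing SNPs dropped",
                      stacklevel=2)
        d = d[:, ~all_missing]
    if d.shape[0] < 2 or d.shape[1] < 1:
        raise ValueError("PCA needs >= 2 samples and >= 1 SNP")
    mean = np.nanmean(d, axis=0)
    d = np.where(np.isnan(d), mean, d) - mean
    if scale:
        sd = d.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        d = d / sd
    u, s, vt = np.linalg.svd(d, full_matrices=False)
    # deterministic sign: largest-|.| loading positive
    for k in range(len(s)):
        pivot = np.argmax(np.abs(vt[k]))
        if vt[k, pivot] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    scores = u * s
    total_var = (d ** 2).sum()
    fractions = s ** 2 / total_var if total_var > 0 else np.zeros_like(s)
    if n_components is not None:
        scores = scores[:, :n_components]
        fractions = fractions[:n_components]
    return scores, fractions
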