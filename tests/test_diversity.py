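import itertools

import numpy as np
import pytest
from scipy import stats

from ringdiv.core import PopulationMap
from ringdiv.diversity import (_two_level_components, amova, fst_to_nm,
                               linearize_fst, nm_to_fst, nucleotide_diversity,
                               pairwise_fst, pca_genotypes,
                               per_population_stats, private_alleles)

from .conftest import make_matrix, random_matrix


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def naive_pi(matrix, idx, per_site_total):
    """Average pairwise difference over all gene-copy pairs, per site."""
    total = 0.0
    for j in range(matrix.n_snps):
        copies = []
        for i in idx:
            a, b = matrix.calls[i, j]
            if a >= 0:
                copies.extend([a, b])
        diffs = sum(x != y for x, y in itertools.combinations(copies, 2))
        n_pairs = len(copies) * (len(copies) - 1) / 2
        if n_pairs:
            total += diffs / n_pairs
    return total / per_site_total


def naive_two_level(matrix, idx1, idx2):
    """One-way ANOVA on allele indicators over gene copies, per SNP,
    with unequal-size coefficient; components summed over SNPs."""
    sig_a_sum = sig_w_sum = 0.0
    for j in range(matrix.n_snps):
        groups = []
        for idx in (idx1, idx2):
            copies = []
            for i in idx:
                a, b = matrix.calls[i, j]
                if a >= 0:
                    copies.extend([a, b])
            groups.append(np.array(copies, dtype=float))
        if any(len(g) < 1 for g in groups):
            continue
        N = sum(len(g) for g in groups)
        if N <= 2:
            continue
        grand = np.concatenate(groups).mean()
        ss_among = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
        ms_a = ss_among / 1.0
        ms_w = ss_within / (N - 2)
        n_prime = (N - sum(len(g) ** 2 for g in groups) / N) / 1.0
        sig_a_sum += (ms_a - ms_w) / n_prime
        sig_w_sum += ms_w
    return sig_a_sum, sig_w_sum


def naive_nested(matrix, group_pop_idx):
    """Spreadsheet-style nested ANOVA executed with explicit loops."""
    sig = np.zeros(3)
    n_groups = len(group_pop_idx)
    n_pops = sum(len(g) for g in group_pop_idx)
    for j in range(matrix.n_snps):
        data = []  # list of groups; each group list of pop copy-arrays
        for g in group_pop_idx:
            pops = []
            for idx in g:
                copies = []
                for i in idx:
                    a, b = matrix.calls[i, j]
                    if a >= 0:
                        copies.extend([a, b])
                pops.append(np.array(copies, dtype=float))
            data.append(pops)
        if any(len(p) < 1 for g in data for p in g):
            continue
        N = sum(len(p) for g in data for p in g)
        Ni = [sum(len(p) for p in g) for g in data]
        grand = np.concatenate([p for g in data for p in g]).mean()
        gmeans = [np.concatenate(g).mean() for g in data]
        ss_wp = sum(((p - p.mean()) ** 2).sum() for g in data for p in g)
        ss_ap = sum(len(p) * (p.mean() - gm) ** 2
                    for g, gm in zip(data, gmeans) for p in g)
        ss_ag = sum(n * (gm - grand) ** 2 for n, gm in zip(Ni, gmeans))
        ms_wp = ss_wp / (N - n_pops)
        ms_ap = ss_ap / (n_pops - n_groups)
        ms_ag = ss_ag / (n_groups - 1)
        sum_nij2_over_Ni = sum(sum(len(p) ** 2 for p in g) / n
                               for g, n in zip(data, Ni))
        sum_nij2_over_N = sum(len(p) ** 2 for g in data for p in g) / N
        n1 = (N - sum_nij2_over_Ni) / (n_pops - n_groups)
        n2 = (sum_nij2_over_Ni - sum_nij2_over_N) / (n_groups - 1)
        n3 = (N - sum(n ** 2 for n in Ni) / N) / (n_groups - 1)
        c = ms_wp
        b = (ms_ap - ms_wp) / n1
        a = (ms_ag - c - n2 * b) / n3
        sig += [a, b, c]
    return tuple(sig)


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

class TestPerPopulationStats:
    def test_pi_equals_naive_pairwise_average(self, rng, two_pop_map):
        m = random_matrix(rng, n_samples=6, n_loci=5, snps_per_locus=4,
                          missing_rate=0.15)
        total_sites = 85 * m.n_loci
        idx = np.arange(6)
        assert nucleotide_diversity(m, idx, total_sites) == pytest.approx(
            naive_pi(m, idx, total_sites), rel=1e-12)

    def test_monomorphic_population(self):
        m = make_matrix([[(0, 0), (0, 0)]] * 4 + [[(0, 1), (1, 1)]] * 4)
        pm = PopulationMap({f"s{i}": ("P1" if i <= 4 else "P2")
                            for i in range(1, 9)})
        t = per_population_stats(m, pm, locus_length=85)
        assert t.loc["P1", "pct_polymorphic"] == 0.0
        assert t.loc["P1", "pi_rad"] == 0.0
        assert t.loc["P1", "HO_snp"] == 0.0

    def test_all_heterozygous_extreme(self):
        m = make_matrix([[(0, 1)]] * 6)
        pm = PopulationMap({f"s{i}": "P1" for i in range(1, 7)})
        t = per_population_stats(m, pm)
        assert t.loc["P1", "HO_snp"] == 1.0
        assert t.loc["P1", "FIS_snp"] < 0

    def test_stat_ranges(self, rng, two_pop_map):
        t = per_population_stats(random_matrix(rng), two_pop_map)
        for col in ("HO_snp", "HE_snp", "pi_snp"):
            assert ((t[col] >= 0) & (t[col] <= 1)).all()
        assert ((t["FIS_snp"] >= -1) & (t["FIS_snp"] <= 1)).all()


class TestPrivateAlleles:
    def test_definition(self):
        # alt allele present only in P2; ref allele shared
        m = make_matrix([[(0, 0)]] * 4 + [[(0, 1)]] * 4)
        pm = PopulationMap({f"s{i}": ("P1" if i <= 4 else "P2")
                            for i in range(1, 9)})
        counts = private_alleles(m, pm)
        assert counts == {"P1": 0, "P2": 1}

    def test_shared_allele_counts_for_neither(self):
        m = make_matrix([[(0, 1)]] * 8)
        pm = PopulationMap({f"s{i}": ("P1" if i <= 4 else "P2")
                            for i in range(1, 9)})
        assert private_alleles(m, pm) == {"P1": 0, "P2": 0}

    def test_matches_exhaustive_scan(self, rng, two_pop_map):
        m = random_matrix(rng, n_samples=8, n_loci=10, snps_per_locus=2,
                          missing_rate=0.2)
        counts = private_alleles(m, two_pop_map)
        pops = {"P1": range(0, 4), "P2": range(4, 8)}
        expected = {p: 0 for p in pops}
        for j in range(m.n_snps):
            for allele in (0, 1):
                holders = [p for p, idx in pops.items()
                           if any(allele in m.calls[i, j] and
                                  m.calls[i, j][0] >= 0 for i in idx)]
                if len(holders) == 1:
                    expected[holders[0]] += 1
        assert counts == expected


class TestPairwiseFst:
    def test_fixed_difference_gives_one(self):
        m = make_matrix([[(0, 0)] * 3] * 4 + [[(1, 1)] * 3] * 4)
        pm = PopulationMap({f"s{i}": ("P1" if i <= 4 else "P2")
                            for i in range(1, 9)})
        fst = pairwise_fst(m, pm)
        assert fst.values.loc["P1", "P2"] == pytest.approx(1.0)

    def test_matches_naive_components(self, rng, two_pop_map):
        m = random_matrix(rng, n_samples=8, n_loci=6, snps_per_locus=2,
                          missing_rate=0.1)
        fst = pairwise_fst(m, two_pop_map)
        sa, sw = naive_two_level(m, np.arange(0, 4), np.arange(4, 8))
        assert fst.values.loc["P1", "P2"] == pytest.approx(
            sa / (sa + sw), rel=1e-10)

    def test_null_panmictic_fst_near_zero(self, rng):
        arr = (rng.random((20, 80, 2)) < 0.3).astype(int)
        m = make_matrix([[tuple(arr[i, j]) for j in range(80)]
                         for i in range(20)])
        pm = PopulationMap({f"s{i}": ("P1" if i <= 10 else "P2")
                            for i in range(1, 21)})
        fst = pairwise_fst(m, pm, n_permutations=99, seed=1)
        assert abs(fst.values.loc["P1", "P2"]) < 0.05
        assert fst.pvalues.loc["P1", "P2"] > 0.05

    def test_permutation_p_uniform_under_null(self, rng):
        """Null-calibration: permutation p-values are uniform when both
        populations are drawn from one panmictic pool."""
        pvals = []
        for rep in range(120):
            arr = (rng.random((12, 30, 2)) < 0.4).astype(int)
            m = make_matrix([[tuple(arr[i, j]) for j in range(30)]
                             for i in range(12)])
            pm = PopulationMap({f"s{i}": ("P1" if i <= 6 else "P2")
                                for i in range(1, 13)})
            fst = pairwise_fst(m, pm, n_permutations=49, seed=rep)
            pvals.append(fst.pvalues.loc["P1", "P2"])
        # discrete grid {0, 1/49, ...}: compare against uniform
        stat = stats.kstest(pvals, "uniform").pvalue
        assert stat > 0.01

    def test_singleton_population_excluded(self, rng):
        m = random_matrix(rng, n_samples=5, n_loci=4, snps_per_locus=1,
                          missing_rate=0)
        pm = PopulationMap({"s1": "P1", "s2": "P1", "s3": "P2", "s4": "P2",
                            "s5": "P3"})
        with pytest.warns(UserWarning, match="excluded"):
            fst = pairwise_fst(m, pm)
        assert "P3" not in fst.values.index


class TestNmAndLinearisation:
    def test_published_mean_fst_to_nm(self):
        assert fst_to_nm(0.258) == pytest.approx(0.719, abs=5e-4)

    def test_closed_form_points(self):
        assert fst_to_nm(1.0) == 0.0
        assert fst_to_nm(0.2) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            fst_to_nm(0.0)

    def test_inverse_identity(self):
        for f in np.linspace(0.01, 1.0, 25):
            assert nm_to_fst(fst_to_nm(f)) == pytest.approx(f, rel=1e-12)

    def test_linearize(self):
        assert linearize_fst(0.0) == 0.0
        assert linearize_fst(0.5) == pytest.approx(1.0)
        assert linearize_fst(-0.05) == pytest.approx(-0.0476, abs=1e-4)
        assert linearize_fst(-0.05, clamp_negative=True) == 0.0
        with pytest.raises(ValueError):
            linearize_fst(1.0)


class TestAmova:
    def _matrix_and_map(self, rng):
        m = random_matrix(rng, n_samples=12, n_loci=4, snps_per_locus=1,
                          missing_rate=0.1)
        pm = PopulationMap({f"s{i}": f"P{(i - 1) // 4 + 1}"
                            for i in range(1, 13)})
        grouping = {"P1": "G1", "P2": "G1", "P3": "G2"}
        return m, pm, grouping

    def test_identical_frequencies_leave_only_within(self, rng):
        arr = (rng.random((12, 40, 2)) < 0.5).astype(int)
        m = make_matrix([[tuple(arr[i, j]) for j in range(40)]
                         for i in range(12)])
        pm = PopulationMap({f"s{i}": f"P{(i - 1) // 4 + 1}"
                            for i in range(1, 13)})
        res = amova(m, pm, {"P1": "G1", "P2": "G1", "P3": "G2"})
        assert res.percent["within_pops"] > 90

    def test_matches_hand_computation(self, rng):
        m, pm, grouping = self._matrix_and_map(rng)
        res = amova(m, pm, grouping)
        idx = [np.arange(0, 4), np.arange(4, 8), np.arange(8, 12)]
        sa, sb, sc = naive_nested(m, [[idx[0], idx[1]], [idx[2]]])
        assert res.sigma_a == pytest.approx(sa, rel=1e-10)
        assert res.sigma_b == pytest.approx(sb, rel=1e-10)
        assert res.sigma_c == pytest.approx(sc, rel=1e-10)

    def test_percent_sums_to_100_and_indices(self, rng):
        m, pm, grouping = self._matrix_and_map(rng)
        res = amova(m, pm, grouping, n_permutations=49, seed=2)
        assert sum(res.percent.values()) == pytest.approx(100.0)
        assert res.f_ct == pytest.approx(res.sigma_a / res.total())
        assert res.f_st == pytest.approx(
            (res.sigma_a + res.sigma_b) / res.total())
        assert all(0 < p <= 1 for p in res.pvalues.values())

    def test_singleton_groups_reduce_to_pairwise_fst(self, rng):
        m = random_matrix(rng, n_samples=8, n_loci=5, snps_per_locus=2,
                          missing_rate=0)
        pm = PopulationMap({f"s{i}": ("P1" if i <= 4 else "P2")
                            for i in range(1, 9)})
        with pytest.warns(UserWarning, match="single population"):
            res = amova(m, pm, {"P1": "G1", "P2": "G2"})
        fst = pairwise_fst(m, pm)
        assert np.isnan(res.f_sc)
        assert res.f_ct == pytest.approx(fst.values.loc["P1", "P2"],
                                         rel=1e-10)

    def test_grouping_must_cover(self, rng):
        m, pm, _ = self._matrix_and_map(rng)
        with pytest.raises(ValueError, match="missing from grouping"):
            amova(m, pm, {"P1": "G1"})


class TestPCA:
    def test_two_clusters_on_pc1(self):
        m = make_matrix([[(0, 0)] * 5] * 4 + [[(1, 1)] * 5] * 4)
        scores, frac = pca_genotypes(m)
        assert frac[0] == pytest.approx(1.0)
        side = np.sign(scores[:, 0])
        assert set(side[:4]) != set(side[4:])

    def test_fraction_sum_bounded(self, rng):
        m = random_matrix(rng, n_samples=10, n_loci=8, snps_per_locus=2)
        _, frac = pca_genotypes(m)
        assert frac.sum() <= 1.0 + 1e-9
        assert np.all(np.diff(frac) <= 1e-12)

    def test_three_population_clusters_separate(self):
        """Synthetic three-lineage data forms distinct PCA clusters."""
        import ringdiv as rd
        m, pm = rd.simulate_genotypes(
            rd.model1_scenario(),
            rd.SimulationConfig(n_loci=300, mu=5e-8, seed=42))
        scores, _ = pca_genotypes(m, n_components=2)
        from sklearn.metrics import silhouette_score
        labels = [pm.population_of(s) for s in m.samples]
        assert silhouette_score(scores, labels) > 0.5
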