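import itertools

import numpy as np
import pytest

from ringdiv.core import PopulationMap
from ringdiv.demography import (FitResult, composite_log_likelihood,
                                expected_max_log_likelihood, expected_sfs,
                                fit_scenario, generations_to_years,
                                model_select, parametric_bootstrap,
                                poisson_log_likelihood, years_to_ma)
from ringdiv.scenarios import (ScenarioError, island_scenario, model1_scenario,
                               panmictic_scenario, scenario_catalog,
                               split_scenario)
from ringdiv.sfs import (JointSFS, fold_counts, fold_joint_sfs,
                         neutral_folded_weights)

from .conftest import make_matrix


# ---------------------------------------------------------------------------
# folding
# ---------------------------------------------------------------------------

class TestFolding:
    def test_single_low_count_snp(self):
        counts = np.zeros((31, 25, 25))
        counts[1, 0, 0] = 1
        folded, mask = fold_counts(counts, (30, 24, 24))
        assert folded[1, 0, 0] == 1
        assert not mask[1, 0, 0]

    def test_complement_folds_down(self):
        counts = np.zeros((31, 25, 25))
        counts[29, 24, 24] = 1  # complement of (1, 0, 0)
        folded, _ = fold_counts(counts, (30, 24, 24))
        assert folded[1, 0, 0] == 1
        assert folded[29, 24, 24] == 0

    def test_monomorphic_corners_masked(self):
        counts = np.ones((5, 5))
        folded, mask = fold_counts(counts, (4, 4))
        assert mask[0, 0] and mask[4, 4]
        assert folded[0, 0] == 0

    def test_total_preserved_outside_corners(self, rng):
        counts = rng.integers(0, 10, size=(7, 9)).astype(float)
        counts[0, 0] = counts[6, 8] = 0
        folded, mask = fold_counts(counts, (6, 8))
        assert folded[~mask].sum() == pytest.approx(counts.sum())

    def test_matches_brute_force_tally(self, rng):
        """Observed SFS equals an exhaustive per-SNP tally."""
        arr = (rng.random((6, 40, 2)) < 0.35).astype(np.int8)
        m = make_matrix([[tuple(arr[i, j]) for j in range(40)]
                         for i in range(6)])
        pm = PopulationMap({f"s{i}": ("A" if i <= 3 else "B")
                            for i in range(1, 7)})
        sfs = fold_joint_sfs(m, pm, {"A": ["A"], "B": ["B"]})
        assert sfs.copies == (6, 6)
        # brute force: count minor-allele configurations SNP by SNP
        expected = np.zeros((7, 7))
        for j in range(40):
            i_a = arr[:3, j].sum()
            i_b = arr[3:, j].sum()
            if (i_a, i_b) in ((0, 0), (6, 6)):
                continue
            if i_a + i_b > 6 or (i_a + i_b == 6 and (6 - i_a, 6 - i_b)
                                 < (i_a, i_b)):
                i_a, i_b = 6 - i_a, 6 - i_b
            expected[i_a, i_b] += 1
        assert np.array_equal(sfs.counts, expected)

    def test_missing_snps_dropped(self):
        m = make_matrix([[(0, 1), None], [(0, 0), (0, 1)]])
        pm = PopulationMap({"s1": "A", "s2": "A"})
        sfs = fold_joint_sfs(m, pm, {"A": ["A"]})
        assert sfs.n_snps == 1

    def test_shape_validation(self):
        with pytest.raises(ValueError, match="shape"):
            JointSFS(["a"], (4,), np.zeros(4))


# ---------------------------------------------------------------------------
# likelihoods
# ---------------------------------------------------------------------------

def _toy_observed():
    counts = np.zeros((5, 5))
    counts[1, 0] = 30
    counts[0, 1] = 20
    counts[1, 1] = 25
    counts[2, 1] = 10
    counts[2, 2] = 15
    return JointSFS(["a", "b"], (4, 4), counts)


class TestCompositeLikelihood:
    def test_uniform_expected_closed_form(self):
        obs = _toy_observed()
        unmasked = ~obs.mask
        uniform = JointSFS(obs.pops, obs.copies,
                           np.where(unmasked, 1.0, 0.0), mask=obs.mask)
        C = int(unmasked.sum())
        S = obs.n_snps
        assert composite_log_likelihood(obs, uniform) == pytest.approx(
            S * np.log(1.0 / C))

    def test_self_likelihood_attains_bound(self):
        obs = _toy_observed()
        self_exp = JointSFS(obs.pops, obs.copies, obs.counts.copy(),
                            mask=obs.mask)
        lnl = composite_log_likelihood(obs, self_exp)
        assert lnl == pytest.approx(expected_max_log_likelihood(obs))

    def test_bound_holds_for_random_expectations(self, rng):
        obs = _toy_observed()
        bound = expected_max_log_likelihood(obs)
        for _ in range(20):
            e = np.where(~obs.mask, rng.random(obs.counts.shape), 0.0)
            exp = JointSFS(obs.pops, obs.copies, e, mask=obs.mask)
            assert composite_log_likelihood(obs, exp) <= bound + 1e-9

    def test_hand_summed_multinomial(self):
        obs = _toy_observed()
        e = np.zeros((5, 5))
        cells = {(1, 0): 0.4, (0, 1): 0.2, (1, 1): 0.2, (2, 1): 0.1,
                 (2, 2): 0.1}
        for c, p in cells.items():
            e[c] = p
        exp = JointSFS(obs.pops, obs.copies, e, mask=obs.mask)
        by_hand = sum(obs.counts[c] * np.log(p) for c, p in cells.items())
        assert composite_log_likelihood(obs, exp) == pytest.approx(by_hand)

    def test_zero_cells_floored(self):
        obs = _toy_observed()
        e = np.zeros((5, 5))
        e[1, 0] = 1.0  # all other observed cells have zero expectation
        exp = JointSFS(obs.pops, obs.copies, e, mask=obs.mask)
        lnl = composite_log_likelihood(obs, exp, zero_floor=1e-10)
        assert np.isfinite(lnl)

    def test_poisson_likelihood_peaks_at_observed(self):
        obs = _toy_observed()
        at_obs = poisson_log_likelihood(obs, JointSFS(
            obs.pops, obs.copies, obs.counts.copy(), mask=obs.mask))
        off = poisson_log_likelihood(obs, JointSFS(
            obs.pops, obs.copies, obs.counts * 2.0, mask=obs.mask))
        assert at_obs > off


# ---------------------------------------------------------------------------
# expected SFS
# ---------------------------------------------------------------------------

class TestExpectedSFS:
    def test_single_population_neutral_shape(self):
        sc = panmictic_scenario(1e4)
        e = expected_sfs(sc, copies={"pop": 10}, n_sim_loci=3000, seed=21)
        marginal = e.counts[1:6, ]
        got = marginal / marginal.sum()
        want = neutral_folded_weights(10)
        assert np.allclose(got, want, rtol=0.05)

    def test_island_symmetry(self):
        sc = island_scenario(5e3, 1e-4)
        e = expected_sfs(sc, copies={"d1": 8, "d2": 8}, n_sim_loci=3000,
                         seed=22)
        # folded spectrum symmetric under deme exchange within MC error;
        # cells on the fold tie-line keep a single representative, so
        # compare only where both a cell and its transpose are unmasked
        a, b = e.counts, e.counts.T
        both = ~e.mask & ~e.mask.T & ((a + b) > 0.05 * a.max())
        rel = np.abs(a - b) / np.maximum(a + b, 1e-12)
        assert np.nanmax(rel[both]) < 0.2

    def test_recent_split_approaches_panmixia(self):
        pan = expected_sfs(panmictic_scenario(1e4), copies={"pop": 8},
                           n_sim_loci=4000, seed=23)
        sc = split_scenario(1e4, 1e4, 1e4, 10.0)  # T -> 0
        near = expected_sfs(sc, copies={"a": 4, "b": 4}, n_sim_loci=4000,
                            seed=24)
        # pool the two demes of the split into one marginal spectrum
        pooled = np.zeros(9)
        for i in range(5):
            for j in range(5):
                if near.mask[i, j]:
                    continue
                pooled[i + j] += near.counts[i, j]
        folded = np.zeros(5)
        for k in range(1, 8):
            folded[min(k, 8 - k)] += pooled[k]
        got = folded[1:5] / folded[1:5].sum()
        want_raw = pan.counts[1:5]
        want = want_raw / want_raw.sum()
        assert np.allclose(got, want, rtol=0.1)

    def test_deterministic_given_seed(self):
        sc = panmictic_scenario(1e4)
        a = expected_sfs(sc, copies={"pop": 6}, n_sim_loci=200, seed=5)
        b = expected_sfs(sc, copies={"pop": 6}, n_sim_loci=200, seed=5)
        assert np.array_equal(a.counts, b.counts)

    def test_validation_errors(self):
        sc = split_scenario(1e4, 1e4, 1e4, -5.0)
        with pytest.raises(ScenarioError):
            expected_sfs(sc, copies={"a": 4, "b": 4}, n_sim_loci=10, seed=1)
        with pytest.raises(ValueError, match="odd"):
            expected_sfs(panmictic_scenario(1e3), copies={"pop": 5},
                         n_sim_loci=10, seed=1)


# ---------------------------------------------------------------------------
# time conversion
# ---------------------------------------------------------------------------

class TestGenerationsToYears:
    @pytest.mark.parametrize("generations,ma", [
        (1_005_501, 15.08), (474_808, 7.12), (0, 0.0),
    ])
    def test_reported_divergence_times(self, generations, ma):
        assert years_to_ma(generations_to_years(generations, 15)) == ma

    def test_linear_and_invertible(self):
        g = 123_456.0
        y = generations_to_years(g, 15)
        assert y == 15 * g
        assert y / 15 == g

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            generations_to_years(-1.0)


# ---------------------------------------------------------------------------
# catalog
# ---------------------------------------------------------------------------

class TestCatalog:
    def test_twenty_models(self):
        assert len(scenario_catalog()) == 20

    def test_model1_topology_and_estimates(self):
        m1 = model1_scenario()
        splits = [e for e in m1.events if e["type"] == "split"]
        recent = next(e for e in splits if e["time"] == "T_2")
        old = next(e for e in splits if e["time"] == "T_1")
        assert set(recent["derived"]) == {"West1", "West2"}
        assert "East" in old["derived"]
        v = m1.values()
        assert v["T_1"] == 1_005_501
        assert v["T_2"] == 474_808
        assert v["N_cur_West1"] == 78_864
        m1.validate()

    def test_every_template_builds_a_demography(self):
        for sc in scenario_catalog():
            values = {}
            for name, p in sc.params.items():
                if p.value is not None:
                    continue
                lo, hi = p.bounds
                values[name] = float(np.sqrt(lo * hi)) if p.log else 0.5
            # keep divergence/admixture times ordered
            for earlier, later in sc.time_orderings:
                if earlier in values:
                    values[earlier] = values.get(later,
                                                 sc.values()[later] or 1e5) / 3
            dem = sc.to_demography(values)
            assert dem.num_populations >= 4

    def test_family_composition(self):
        cat = scenario_catalog()
        n_admix = sum(any(e["type"] == "admixture" for e in sc.events)
                      for sc in cat)
        n_trifurcation = sum(
            any(e["type"] == "split" and len(e["derived"]) == 3
                for e in sc.events) for sc in cat)
        assert n_admix == 9
        assert n_trifurcation == 2


# ---------------------------------------------------------------------------
# fitting, selection, bootstrap
# ---------------------------------------------------------------------------

def _make_fit(name, lnl, k, n_snps=100.0, copies=(4, 4)):
    return FitResult(name, {}, lnl, lnl + 5.0, k, 2 * k - 2 * lnl,
                     "relative", n_snps, copies)


class TestModelSelect:
    def test_aic_penalty_breaks_ties(self):
        table = model_select([_make_fit("big", -50.0, 7),
                              _make_fit("small", -50.0, 5)])
        assert table["scenario"].iloc[0] == "small"

    def test_single_fit(self):
        table = model_select([_make_fit("only", -10.0, 3)])
        assert len(table) == 1
        assert table["delta_AIC"].iloc[0] == 0.0

    def test_mismatched_observed_rejected(self):
        with pytest.raises(ValueError, match="different observed"):
            model_select([_make_fit("a", -10, 3, n_snps=100),
                          _make_fit("b", -10, 3, n_snps=200)])


@pytest.fixture(scope="module")
def observed():
    import ringdiv as rd
    sc = split_scenario(1e4, 1e4, 8e3, 2.5e4)
    cfg = rd.SimulationConfig(gene_copies={"a": 12, "b": 12},
                              n_loci=1200, mu=1e-7, seed=31)
    m, pm = rd.simulate_genotypes(sc, cfg)
    return fold_joint_sfs(m, pm, {"a": ["a"], "b": ["b"]})


class TestFitScenario:

    def test_all_fixed_returns_single_evaluation(self, observed):
        sc = split_scenario(1e4, 1e4, 8e3, 2.5e4)
        fit = fit_scenario(observed, sc, n_runs=1, n_cycles=1,
                           sims_per_eval=100, seed=1)
        assert fit.k == 0
        assert fit.aic == pytest.approx(-2 * fit.log_likelihood)
        assert fit.log_likelihood <= fit.expected_max

    def test_split_time_recovery(self, observed):
        sc = split_scenario(1e4, 1e4, 8e3, None, free=("T",),
                            bounds={"T": (2e3, 5e5)})
        fit = fit_scenario(observed, sc, n_runs=3, n_cycles=6,
                           sims_per_eval=300, seed=17)
        assert fit.params["T"] == pytest.approx(2.5e4, rel=0.25)
        assert fit.log_likelihood <= fit.expected_max

    def test_population_mismatch_rejected(self, observed):
        sc = panmictic_scenario(1e4)
        with pytest.raises(ValueError, match="do not match"):
            fit_scenario(observed, sc, n_runs=1, n_cycles=1,
                         sims_per_eval=50, seed=1)


class TestParametricBootstrap:
    def test_two_replicates_bracket_min_max(self):
        import ringdiv as rd
        sc_true = split_scenario(1e4, 1e4, 8e3, 2.5e4)
        cfg = rd.SimulationConfig(gene_copies={"a": 8, "b": 8}, n_loci=400,
                                  mu=1e-7, seed=41)
        m, pm = rd.simulate_genotypes(sc_true, cfg)
        obs = fold_joint_sfs(m, pm, {"a": ["a"], "b": ["b"]})
        sc = split_scenario(1e4, 1e4, 8e3, None, free=("T",),
                            bounds={"T": (5e3, 2e5)})
        fit = fit_scenario(obs, sc, n_runs=2, n_cycles=3, sims_per_eval=120,
                           seed=5)
        res = parametric_bootstrap(fit, sc, n_boot=2, seed=6, n_runs=1,
                                   n_cycles=2, sims_per_eval=120)
        ests = res["estimates"]["T"].to_numpy()
        lo, hi = res["ci"]["T"]
        assert lo == pytest.approx(ests.min())
        assert hi == pytest.approx(ests.max())
        assert res["reliable"]

    def test_no_free_parameters_zero_width(self):
        sc = split_scenario(1e4, 1e4, 8e3, 2.5e4)
        fit = FitResult(sc.name, sc.values(), -10.0, -9.0, 0, 20.0,
                        "relative", 100.0, (8, 8))
        res = parametric_bootstrap(fit, sc, n_boot=5, seed=1)
        assert res["ci"] == {}
        assert res["reliable"]
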