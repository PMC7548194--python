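"""SFS-based coalescent demographic inference.

The expected joint SFS under a scenario is estimated by coalescent
simulation of independent non-recombining loci, using *branch-mode*
frequency spectra: the expected total branch length subtending each
allele-count configuration, averaged over simulated genealogies.  This is
an unbiased Monte-Carlo estimate of the mutation-rate-scaled expected
SFS with far lower variance than counting simulated mutations.

Two likelihood modes are offered.  ``relative`` conditions on a site
being a SNP: cell probabilities are renormalised over polymorphic cells
and the likelihood is multinomial, so no mutation rate is needed and only
the *shape* of the history (relative sizes and times) is identified.
``absolute`` treats cell counts as independent Poissons with expectation
``mu * locus_length * n_loci * (branch SFS)``, which identifies absolute
sizes and times.

Fitting mirrors the standard composite-likelihood recipe: many
independent runs start from log-uniform draws within bounds and each run
performs cycles of conditional one-parameter maximisation (bounded
scalar search on log scale), with common random numbers across the
evaluations of a cycle to suppress Monte-Carlo jitter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .datasets import GROUP_GENE_COPIES
from .scenarios import DemographicScenario
from .sfs import JointSFS, fold_counts

DEFAULT_GENERATION_TIME = 15.0


def generations_to_years(generations: float,
                         generation_time: float = DEFAULT_GENERATION_TIME
                         ) -> float:
    """Convert generations to years (exactly linear)."""
    if generations < 0 or generation_time < 0:
        raise ValueError("inputs must be non-negative")
    return generations * generation_time


def years_to_ma(years: float) -> float:
    """Years to million-years, rounded to 2 decimals for reporting."""
    return round(years / 1e6, 2)


# ---------------------------------------------------------------------------
# expected SFS by simulation
# ---------------------------------------------------------------------------

def expected_sfs(scenario: DemographicScenario, overrides: dict | None = None,
                 copies: dict | None = None, n_sim_loci: int = 1000,
                 seed: int | None = None) -> JointSFS:
    """Monte-Carlo expected folded joint SFS (branch-length units/site).

    ``copies`` maps each sampled population to its gene-copy count
    (default: the study configuration 30/24/24).  Cell values are mean
    branch lengths per site; multiply by the per-site mutation rate for
    expected SNP densities, or renormalise for cell probabilities.
    """
    import msprime

    if n_sim_loci < 1:
        raise ValueError("n_sim_loci must be >= 1")
    if copies is None:
        copies = {p: GROUP_GENE_COPIES[p] for p in scenario.populations}
    for pop, c in copies.items():
        if c % 2:
            raise ValueError(f"odd gene-copy count for {pop} (diploids)")
    dem = scenario.to_demography(overrides)
    samples = {p: copies[p] // 2 for p in scenario.populations}
    reps = msprime.sim_ancestry(
        samples=samples, demography=dem, sequence_length=1, ploidy=2,
        num_replicates=n_sim_loci, random_seed=_msprime_seed(seed))
    total = None
    sample_sets = None
    for ts in reps:
        if sample_sets is None:
            name_to_id = {p.metadata.get("name", str(p.id)): p.id
                          for p in ts.populations()}
            sample_sets = [ts.samples(population=name_to_id[p])
                           for p in scenario.populations]
        afs = ts.allele_frequency_spectrum(
            sample_sets=sample_sets, mode="branch", polarised=True,
            span_normalise=True)
        total = afs if total is None else total + afs
    mean_afs = total / n_sim_loci
    cps = tuple(copies[p] for p in scenario.populations)
    folded, mask = fold_counts(mean_afs, cps)
    return JointSFS(list(scenario.populations), cps, folded, folded=True,
                    mask=mask)


def _msprime_seed(seed: int | None) -> int | None:
    if seed is None:
        return None
    return int(np.random.default_rng(seed).integers(1, 2**31 - 1))


# ---------------------------------------------------------------------------
# composite likelihoods
# ---------------------------------------------------------------------------

def _check_compatible(observed: JointSFS, expected: JointSFS) -> None:
    if observed.copies != expected.copies:
        raise ValueError("observed/expected sample sizes differ")
    if observed.folded != expected.folded:
        raise ValueError("observed/expected folding differs")
    if not np.array_equal(observed.mask, expected.mask):
        raise ValueError("observed/expected masks differ")


def composite_log_likelihood(observed: JointSFS, expected: JointSFS,
                             zero_floor: float = 1e-10) -> float:
    """SNP-conditioned multinomial log-likelihood.

    ``expected`` cell values are renormalised over unmasked cells; cells
    with probability below ``zero_floor`` are floored there (and the
    distribution renormalised) so observed counts in empty simulated
    cells stay finite.
    """
    _check_compatible(observed, expected)
    m = observed.counts[~observed.mask]
    e = expected.counts[~expected.mask].astype(float)
    total = e.sum()
    if total <= 0:
        raise ValueError("expected SFS is empty")
    p = e / total
    floored = np.maximum(p, zero_floor)
    p = floored / floored.sum()
    return float((m * np.log(p)).sum())


def expected_max_log_likelihood(observed: JointSFS) -> float:
    """Self-likelihood bound: lnL of the observed SFS against its own
    relative frequencies (the maximum any expected SFS can reach)."""
    m = observed.counts[~observed.mask]
    total = m.sum()
    nz = m > 0
    return float((m[nz] * np.log(m[nz] / total)).sum())


def poisson_log_likelihood(observed: JointSFS, expected_counts: JointSFS,
                           zero_floor: float = 1e-30) -> float:
    """Poisson composite log-likelihood for absolute-mode fitting."""
    _check_compatible(observed, expected_counts)
    m = observed.counts[~observed.mask]
    e = np.maximum(expected_counts.counts[~expected_counts.mask], zero_floor)
    return float((m * np.log(e) - e).sum())


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    scenario: str
    params: dict
    log_likelihood: float
    expected_max: float
    k: int
    aic: float
    mode: str
    n_snps: float
    copies: tuple
    run_maxima: list = field(default_factory=list)
    ci: dict | None = None

    @property
    def gof_distance(self) -> float:
        """Likelihood distance to the self-likelihood bound (>= 0)."""
        return self.expected_max - self.log_likelihood


class FitFailure(RuntimeError):
    pass


def _make_objective(observed: JointSFS, scenario: DemographicScenario,
                    copies: dict, sims_per_eval: int, mode: str,
                    mu: float | None, locus_length: int,
                    n_loci: int | None, zero_floor: float):
    if mode == "absolute":
        if mu is None or n_loci is None:
            raise ValueError("absolute mode needs mu and n_loci")
        scale = mu * locus_length * n_loci
    elif mode != "relative":
        raise ValueError(f"unknown mode {mode!r}")

    def objective(values: dict, sim_seed: int) -> float:
        exp = expected_sfs(scenario, values, copies, sims_per_eval, sim_seed)
        if mode == "relative":
            return composite_log_likelihood(observed, exp, zero_floor)
        scaled = JointSFS(exp.pops, exp.copies, exp.counts * scale,
                          folded=True, mask=exp.mask)
        return poisson_log_likelihood(observed, scaled)

    return objective


def _bounds_for(scenario: DemographicScenario, name: str,
                values: dict) -> tuple:
    p = scenario.params[name]
    lo, hi = p.bounds
    for earlier, later in scenario.time_orderings:
        if name == earlier and values.get(later) is not None:
            hi = min(hi, 0.999 * values[later])
        if name == later and values.get(earlier) is not None:
            lo = max(lo, 1.001 * values[earlier])
    if lo >= hi:
        lo = hi / 2.0
    return lo, hi


def fit_scenario(observed: JointSFS, scenario: DemographicScenario,
                 n_runs: int = 50, n_cycles: int = 40,
                 sims_per_eval: int = 1000, seed: int | None = None,
                 mode: str = "relative", mu: float | None = None,
                 locus_length: int = 85, n_loci: int | None = None,
                 maxiter_1d: int = 8) -> FitResult:
    """Maximise the composite likelihood of ``observed`` under ``scenario``.

    Each of ``n_runs`` runs draws free parameters log-uniform within
    their bounds, then alternates ``n_cycles`` of conditional
    one-parameter bounded maximisations.  Within a cycle every evaluation
    reuses one simulation seed (common random numbers); runs are compared
    on a final evaluation under one shared scoring seed.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    copies = dict(zip(observed.pops, observed.copies))
    if list(observed.pops) != list(scenario.populations):
        raise ValueError(
            f"observed SFS populations {observed.pops} do not match "
            f"scenario populations {list(scenario.populations)}")
    zero_floor = 1.0 / (10.0 * sims_per_eval * max(observed.n_snps, 1.0))
    objective = _make_objective(observed, scenario, copies, sims_per_eval,
                                mode, mu, locus_length, n_loci, zero_floor)
    rng = np.random.default_rng(seed)
    scoring_seed = int(rng.integers(1, 2**31 - 1))
    free = scenario.free_params()
    fixed_values = scenario.values()

    if not free:
        lnl = objective(fixed_values, scoring_seed)
        return FitResult(scenario.name, dict(fixed_values), lnl,
                         expected_max_log_likelihood(observed), 0,
                         -2.0 * lnl, mode, observed.n_snps, observed.copies,
                         run_maxima=[lnl])

    best = None
    run_maxima = []
    init_lnls = []
    for _ in range(n_runs):
        values = dict(fixed_values)
        for name in free:
            p = scenario.params[name]
            lo, hi = _bounds_for(scenario, name, values)
            if p.log:
                values[name] = 10 ** rng.uniform(np.log10(lo), np.log10(hi))
            else:
                values[name] = rng.uniform(lo, hi)
        try:
            scenario.validate(values)
        except Exception:
            # redraw times in order if the draw violated orderings
            for earlier, later in scenario.time_orderings:
                if values[earlier] >= values[later]:
                    values[earlier], values[later] = (
                        min(values[earlier], values[later]) * 0.5,
                        max(values[earlier], values[later]))
        init_lnls.append(objective(values, scoring_seed))
        for cycle in range(n_cycles):
            cycle_seed = int(rng.integers(1, 2**31 - 1))
            for name in free:
                p = scenario.params[name]
                lo, hi = _bounds_for(scenario, name, values)

                def neg(z):
                    v = dict(values)
                    v[name] = 10 ** z if p.log else z
                    return -objective(v, cycle_seed)

                blo, bhi = (np.log10([lo, hi]) if p.log else (lo, hi))
                res = optimize.minimize_scalar(
                    neg, bounds=(blo, bhi), method="bounded",
                    options={"maxiter": maxiter_1d, "xatol": 0.01})
                values[name] = 10 ** res.x if p.log else float(res.x)
        lnl = objective(values, scoring_seed)
        run_maxima.append(lnl)
        if best is None or lnl > best[0]:
            best = (lnl, dict(values))
    if best[0] < max(init_lnls) - 1e-9:
        raise FitFailure("no run improved over its initialisation")
    lnl, values = best
    k = len(free)
    return FitResult(scenario.name, values, lnl,
                     expected_max_log_likelihood(observed), k,
                     2.0 * k - 2.0 * lnl, mode, observed.n_snps,
                     observed.copies, run_maxima=run_maxima)


# ---------------------------------------------------------------------------
# model selection and bootstrap
# ---------------------------------------------------------------------------

def model_select(fits: list) -> pd.DataFrame:
    """Rank fitted scenarios by AIC (ascending).

    All fits must target the same observed SFS (same sample sizes and SNP
    total).  The table reports AIC, the AIC difference to the best model,
    and the likelihood distance to the self-likelihood bound as a
    goodness-of-fit measure.
    """
    if not fits:
        raise ValueError("no fits to rank")
    ref = (fits[0].copies, round(fits[0].n_snps, 6))
    for f in fits[1:]:
        if (f.copies, round(f.n_snps, 6)) != ref:
            raise ValueError("fits target different observed SFS")
    rows = [{"scenario": f.scenario, "k": f.k, "lnL": f.log_likelihood,
             "AIC": f.aic, "gof_distance": f.gof_distance} for f in fits]
    df = pd.DataFrame(rows).sort_values("AIC").reset_index(drop=True)
    df["delta_AIC"] = df["AIC"] - df["AIC"].iloc[0]
    return df


def simulate_observed_from_expected(expected: JointSFS, n_snps: float,
                                    seed: int | None, mode: str = "relative",
                                    scale: float | None = None) -> JointSFS:
    """Draw a synthetic observed SFS from an expected one.

    ``relative``: multinomial with ``n_snps`` trials over unmasked cell
    probabilities.  ``absolute``: independent Poissons with mean
    ``scale * expected``.
    """
    rng = np.random.default_rng(seed)
    counts = np.zeros_like(expected.counts)
    un = ~expected.mask
    if mode == "relative":
        p = expected.counts[un] / expected.counts[un].sum()
        counts[un] = rng.multinomial(int(round(n_snps)), p)
    else:
        counts[un] = rng.poisson(scale * expected.counts[un])
    return JointSFS(expected.pops, expected.copies, counts, folded=True,
                    mask=expected.mask)


def parametric_bootstrap(best: FitResult, scenario: DemographicScenario,
                         n_boot: int = 100, seed: int | None = None,
                         n_runs: int = 2, n_cycles: int = 5,
                         sims_per_eval: int = 300,
                         truth_sims: int | None = None,
                         mu: float | None = None, locus_length: int = 85,
                         n_loci: int | None = None) -> dict:
    """Percentile 95% confidence intervals by parametric bootstrap.

    ``n_boot`` synthetic spectra are drawn at the point estimates and
    each is refit (with reduced runs/cycles); per-parameter 2.5/97.5
    percentiles form the CIs.  Refit failures are logged and excluded;
    if fewer than half succeed the CIs are flagged unreliable.
    """
    rng = np.random.default_rng(seed)
    copies = {p: c for p, c in zip(scenario.populations, best.copies)}
    point = best.params
    free = scenario.free_params()
    if not free:
        return {"ci": {}, "estimates": pd.DataFrame(), "n_success": n_boot,
                "reliable": True}
    hi_sims = truth_sims if truth_sims is not None else 4 * sims_per_eval
    exp = expected_sfs(scenario, point, copies, hi_sims,
                       int(rng.integers(1, 2**31 - 1)))
    scale = None
    if best.mode == "absolute":
        scale = mu * locus_length * n_loci
    estimates = []
    failures = 0
    for b in range(n_boot):
        boot_obs = simulate_observed_from_expected(
            exp, best.n_snps, int(rng.integers(1, 2**31 - 1)), best.mode,
            scale)
        try:
            fit = fit_scenario(
                boot_obs, scenario, n_runs=n_runs, n_cycles=n_cycles,
                sims_per_eval=sims_per_eval,
                seed=int(rng.integers(1, 2**31 - 1)), mode=best.mode,
                mu=mu, locus_length=locus_length, n_loci=n_loci)
            estimates.append({name: fit.params[name] for name in free})
        except Exception as exc:  # refit failures excluded, counted
            failures += 1
            warnings.warn(f"bootstrap replicate {b} failed: {exc}",
                          stacklevel=2)
    est_df = pd.DataFrame(estimates)
    ci = {}
    for name in free:
        if est_df.empty:
            ci[name] = (np.nan, np.nan)
            continue
        # order-statistic percentiles so tiny n_boot brackets min/max
        lo = np.percentile(est_df[name], 2.5, method="inverted_cdf")
        hi = np.percentile(est_df[name], 97.5, method="higher")
        ci[name] = (float(lo), float(hi))
    n_success = len(estimates)
    return {"ci": ci, "estimates": est_df, "n_success": n_success,
            "reliable": n_success >= n_boot / 2.0}
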