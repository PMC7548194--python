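"""Synthetic genotype, geography and cline data generators.

These emulate the statistical structure the analysis assumes so every
downstream stage can be exercised end to end: coalescent
divergence-with-migration genotypes in RAD-style multi-SNP loci (with
missing calls), sites on a ring around an inaccessible interior with a
barrier gap, and clinal trait variation along the ring.

Loci are independent non-recombining segments; mutations follow an
infinite-sites model within the locus (continuous positions, so no
multi-hit sites) and diploid genotypes pair gene copies at random within
a population.  Everything is deterministic given the configuration seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (ARC_EAST, ARC_REFERENCE, ARC_WEST, MISSING,
                   GenotypeMatrix, PopulationMap, SiteTable)
from .geography import EARTH_RADIUS_KM, cline_value, ring_positions
from .scenarios import DemographicScenario

#: default per-site per-generation mutation rate for synthetic data only
DEFAULT_MU = 1e-8


@dataclass
class SimulationConfig:
    """Settings for genotype simulation.

    ``gene_copies`` maps population label -> sampled gene copies (must be
    even; the defaults are the study sampling configuration).  ``mu`` is
    the per-site mutation rate per generation — a synthetic-data choice,
    not an inferred quantity.  ``snps_per_locus`` is an optional
    bookkeeping target; a warning is raised when the realised mean is far
    from it.
    """

    gene_copies: dict = field(
        default_factory=lambda: {"East": 30, "West1": 24, "West2": 24})
    n_loci: int = 2000
    locus_length: int = 85
    mu: float = DEFAULT_MU
    missing_rate: float = 0.0
    snps_per_locus: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        for pop, c in self.gene_copies.items():
            if c <= 0 or c % 2:
                raise ValueError(
                    f"gene copies for {pop} must be positive and even")
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing rate must be in [0, 1)")
        if self.n_loci < 1 or self.locus_length < 1:
            raise ValueError("n_loci and locus_length must be positive")


def simulate_genotypes(scenario: DemographicScenario,
                       config: SimulationConfig) -> tuple:
    """Simulate a genotype matrix and its population map under a scenario.

    Each locus is an independent coalescent genealogy; biallelic SNPs are
    placed by infinite-sites mutation within the locus.  Sample names are
    ``<pop>_<index>``; SNP positions are 1-based offsets within the
    locus.  Returns ``(GenotypeMatrix, PopulationMap)``.
    """
    import msprime

    pops = [p for p in scenario.populations if p in config.gene_copies]
    if set(config.gene_copies) - set(pops):
        raise ValueError("gene copies given for unknown populations")
    dem = scenario.to_demography()
    samples = {p: config.gene_copies[p] // 2 for p in pops}
    rng = np.random.default_rng(config.seed)
    anc_seed = int(rng.integers(1, 2**31 - 1))
    mut_seeds = rng.integers(1, 2**31 - 1, size=config.n_loci)

    sample_names: list = []
    popmap: dict = {}
    reps = msprime.sim_ancestry(
        samples=samples, demography=dem,
        sequence_length=config.locus_length, ploidy=2,
        num_replicates=config.n_loci, random_seed=anc_seed)
    loci, poss, blocks = [], [], []
    n_ind = sum(samples.values())
    node_order = None
    for locus_i, ts in enumerate(reps):
        if not sample_names:
            name_to_id = {p.metadata.get("name", str(p.id)): p.id
                          for p in ts.populations()}
            id_to_name = {i: n for n, i in name_to_id.items()}
            counters: dict = {}
            node_order = np.empty(2 * n_ind, dtype=int)
            sample_nodes = list(ts.samples())
            node_index = {n: i for i, n in enumerate(sample_nodes)}
            for ind in ts.individuals():
                pname = id_to_name[ts.node(ind.nodes[0]).population]
                counters[pname] = counters.get(pname, 0) + 1
                sname = f"{pname}_{counters[pname]:02d}"
                sample_names.append(sname)
                popmap[sname] = pname
                node_order[2 * ind.id] = node_index[ind.nodes[0]]
                node_order[2 * ind.id + 1] = node_index[ind.nodes[1]]
        mts = msprime.sim_mutations(
            ts, rate=config.mu, model=msprime.BinaryMutationModel(),
            discrete_genome=False, random_seed=int(mut_seeds[locus_i]))
        if mts.num_sites == 0:
            continue
        # infinite sites: every site is biallelic with genotypes in {0,1}
        g = mts.genotype_matrix()[:, node_order]  # (sites, 2*n_ind)
        blocks.append(g.astype(np.int8).reshape(mts.num_sites, n_ind, 2))
        used_pos: set = set()
        for p in mts.sites_position:
            pos = int(p) + 1
            while pos in used_pos:
                pos += 1
            used_pos.add(pos)
            poss.append(pos)
            loci.append(f"locus_{locus_i + 1:06d}")
    snps = pd.DataFrame({"locus": loci, "pos": poss,
                         "ref": "A", "alt": "T"})
    calls = (np.concatenate(blocks, axis=0).transpose(1, 0, 2)
             if blocks else np.zeros((n_ind, 0, 2), dtype=np.int8))
    matrix = GenotypeMatrix(samples=sample_names, snps=snps, calls=calls)
    if config.missing_rate > 0:
        matrix = inject_missingness(matrix, config.missing_rate,
                                    int(rng.integers(1, 2**31 - 1)))
    if config.snps_per_locus is not None and matrix.n_loci:
        realised = matrix.n_snps / matrix.n_loci
        if not 0.5 * config.snps_per_locus <= realised <= 2.0 * config.snps_per_locus:
            warnings.warn(
                f"realised SNPs/locus {realised:.2f} far from target "
                f"{config.snps_per_locus:.2f}; adjust mu", stacklevel=2)
    return matrix, PopulationMap(popmap)


def inject_missingness(matrix: GenotypeMatrix, rate: float,
                       seed: int | None = None) -> GenotypeMatrix:
    """Set calls missing independently at the given rate (reproducible)."""
    if not 0 <= rate < 1:
        raise ValueError("rate must be in [0, 1)")
    if rate == 0:
        return matrix.copy()
    rng = np.random.default_rng(seed)
    out = matrix.copy()
    drop = rng.random((out.n_samples, out.n_snps)) < rate
    out.calls[drop] = MISSING
    return out


# ---------------------------------------------------------------------------
# geography
# ---------------------------------------------------------------------------

def generate_ring_sites(n_sites: int, center=(104.5, 29.5),
                        radius_km: float = 250.0, gap_arc: float = 30.0,
                        gap_bearing: float = 315.0,
                        samples_per_site: int = 6) -> SiteTable:
    """Sites on an annulus with a gap (the dispersal barrier).

    ``gap_arc`` degrees of the ring centred on compass bearing
    ``gap_bearing`` are left empty; ``n_sites`` sites spread evenly over
    the remaining arc (codes ``S01``... starting at the gap's
    counter-clockwise edge).  The first half of the chain is labelled
    ``west``, the second ``east``, and a reference point sits on the ring
    opposite the gap.
    """
    if n_sites < 3:
        raise ValueError("need at least 3 sites")
    if radius_km <= 0:
        raise ValueError("radius must be positive")
    if not 0 < gap_arc < 180:
        raise ValueError("gap arc must be in (0, 180) degrees")
    lon_c, lat_c = center
    ang_span = 360.0 - gap_arc
    bearings = gap_bearing + gap_arc / 2.0 + ang_span * np.arange(n_sites) / (
        n_sites - 1)

    def place(bearing_deg: float) -> tuple:
        b = np.radians(bearing_deg)
        dlat = (radius_km / EARTH_RADIUS_KM) * np.cos(b)
        dlon = (radius_km / (EARTH_RADIUS_KM
                             * np.cos(np.radians(lat_c)))) * np.sin(b)
        return lon_c + np.degrees(dlon), lat_c + np.degrees(dlat)

    rows = []
    for i, bearing in enumerate(bearings):
        lon, lat = place(bearing)
        arc = ARC_WEST if i < n_sites / 2 else ARC_EAST
        rows.append({"code": f"S{i + 1:02d}", "lon": lon, "lat": lat,
                     "arc": arc, "n": samples_per_site})
    lon, lat = place(gap_bearing + 180.0)
    rows.append({"code": "REF", "lon": lon, "lat": lat,
                 "arc": ARC_REFERENCE, "n": 0})
    return SiteTable(pd.DataFrame(rows))


def generate_clinal_trait(sites: SiteTable, center_km: float,
                          width_km: float, p_min: float, p_max: float,
                          noise_sd: float = 0.0, seed: int | None = None,
                          origin: str | None = None) -> pd.Series:
    """Sigmoid clinal trait values at the sites' ring positions.

    The trait is the no-tail cline evaluated at each site's 1-D ring
    position (from ``origin``; default the first site code) plus
    independent Gaussian noise.  Returns a Series indexed by site code in
    ring order.
    """
    if width_km <= 0:
        raise ValueError("width must be positive")
    if p_min >= p_max:
        raise ValueError("p_min must be below p_max")
    codes = sites.sampled().codes
    origin = origin if origin is not None else codes[0]
    pos = ring_positions(sites, origin=origin)
    values = cline_value(pos.to_numpy(), center_km, width_km, p_min, p_max,
                         tails="none")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sd, size=len(pos))
    return pd.Series(values, index=pos.index, name="trait")
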