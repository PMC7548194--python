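import numpy as np
import pandas as pd
import pytest

from ringdiv.core import GenotypeMatrix, PopulationMap


def make_matrix(calls, loci=None, positions=None, samples=None):
    """Build a GenotypeMatrix from a nested list of allele pairs.

    ``calls[sample][snp]`` is a pair of alleles or None (missing).
    """
    n_samples = len(calls)
    n_snps = len(calls[0])
    arr = np.full((n_samples, n_snps, 2), -1, dtype=np.int8)
    for i, row in enumerate(calls):
        for j, c in enumerate(row):
            if c is not None:
                arr[i, j] = c
    if loci is None:
        loci = [f"L{j + 1}" for j in range(n_snps)]
    if positions is None:
        positions = [1] * n_snps
    snps = pd.DataFrame({
        "locus": loci, "pos": positions,
        "ref": ["A"] * n_snps, "alt": ["T"] * n_snps,
    })
    if samples is None:
        samples = [f"s{i + 1}" for i in range(n_samples)]
    return GenotypeMatrix(samples=samples, snps=snps, calls=arr)


def random_matrix(rng, n_samples=8, n_loci=5, snps_per_locus=2,
                  missing_rate=0.1):
    """Random biallelic matrix with per-locus SNP grouping and missingness."""
    n_snps = n_loci * snps_per_locus
    freqs = rng.uniform(0.05, 0.95, size=n_snps)
    arr = (rng.random((n_samples, n_snps, 2)) < freqs[None, :, None]
           ).astype(np.int8)
    miss = rng.random((n_samples, n_snps)) < missing_rate
    arr[miss] = -1
    loci = [f"L{k + 1}" for k in range(n_loci) for _ in range(snps_per_locus)]
    positions = list(range(1, snps_per_locus + 1)) * n_loci
    return make_matrix(
        [[tuple(arr[i, j]) if arr[i, j, 0] >= 0 else None
          for j in range(n_snps)] for i in range(n_samples)],
        loci=loci, positions=positions)


@pytest.fixture
def two_pop_map():
    return PopulationMap({f"s{i}": ("P1" if i <= 4 else "P2")
                          for i in range(1, 9)})


@pytest.fixture
def rng():
    return np.random.default_rng(20230915)
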