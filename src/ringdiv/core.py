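"""Core in-memory containers shared by every pipeline stage.

The pipeline starts from called genotypes: diploid, biallelic SNPs grouped
into short RAD-style loci.  Three containers circulate between stages:

* :class:`GenotypeMatrix` — samples x SNPs allele-pair calls, SNPs tagged by
  locus;
* :class:`PopulationMap` — sample -> population assignment;
* :class:`SiteTable` — population coordinates and ring-arc membership.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

SNP_COLUMNS = ("locus", "pos", "ref", "alt")


@dataclass
class GenotypeMatrix:
    """Diploid biallelic genotype calls for samples x SNPs.

    Parameters
    ----------
    samples:
        Ordered sample identifiers.
    snps:
        One row per SNP with columns ``locus`` (locus identifier), ``pos``
        (position within the locus), ``ref`` and ``alt`` (allele codes).
    calls:
        ``(n_samples, n_snps, 2)`` int8 array of allele indices in
        ``{0, 1}``; a missing genotype is ``(-1, -1)``.  A partially missing
        call (one known allele) is normalised to wholly missing, matching
        diploid call semantics.
    """

    samples: list[str]
    snps: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.snps = self.snps.reset_index(drop=True)
        missing_cols = [c for c in SNP_COLUMNS if c not in self.snps.columns]
        if missing_cols:
            raise ValueError(f"snps table lacks columns {missing_cols}")
        calls = np.asarray(self.calls, dtype=np.int8)
        if calls.shape != (len(self.samples), len(self.snps), 2):
            raise ValueError(
                f"calls shape {calls.shape} does not match "
                f"({len(self.samples)}, {len(self.snps)}, 2)"
            )
        partial = (calls < 0).any(axis=2)
        calls[partial] = MISSING
        self.calls = calls

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def loci(self) -> list:
        """Locus identifiers in first-appearance order."""
        return list(pd.unique(self.snps["locus"]))

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def missing_mask(self) -> np.ndarray:
        """Boolean ``(n_samples, n_snps)``; True where the call is missing."""
        return self.calls[:, :, 0] == MISSING

    def dosage(self) -> np.ndarray:
        """Alt-allele dosage in {0,1,2}, NaN where missing."""
        d = self.calls.sum(axis=2).astype(float)
        d[self.missing_mask()] = np.nan
        return d

    # -- subsetting ------------------------------------------------------
    def take_snps(self, index) -> "GenotypeMatrix":
        index = np.asarray(index, dtype=int)
        return GenotypeMatrix(
            samples=list(self.samples),
            snps=self.snps.iloc[index].reset_index(drop=True),
            calls=self.calls[:, index, :].copy(),
        )

    def take_samples(self, names) -> "GenotypeMatrix":
        pos = [self.samples.index(s) for s in names]
        return GenotypeMatrix(
            samples=list(names),
            snps=self.snps.copy(),
            calls=self.calls[pos, :, :].copy(),
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.samples), self.snps.copy(), self.calls.copy())

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.samples == other.samples
            and self.snps[list(SNP_COLUMNS)].equals(other.snps[list(SNP_COLUMNS)])
            and np.array_equal(self.calls, other.calls)
        )

    def locus_snp_indices(self) -> dict:
        """Map locus id -> array of SNP column indices, in position order."""
        out: dict = {}
        order = np.lexsort((self.snps["pos"].to_numpy(),))
        for idx in order:
            out.setdefault(self.snps["locus"].iloc[idx], []).append(idx)
        return {k: np.asarray(v) for k, v in out.items()}


@dataclass
class PopulationMap:
    """Assignment of every sample to exactly one population."""

    assignment: dict

    def __post_init__(self) -> None:
        self.assignment = dict(self.assignment)
        if not self.assignment:
            raise ValueError("population map is empty")

    @property
    def populations(self) -> list:
        """Population codes in first-appearance order."""
        return list(dict.fromkeys(self.assignment.values()))

    def samples_of(self, pop) -> list:
        return [s for s, p in self.assignment.items() if p == pop]

    def population_of(self, sample):
        return self.assignment[sample]

    def sample_indices(self, matrix: GenotypeMatrix) -> dict:
        """Map population -> integer indices into ``matrix.samples``.

        Samples absent from the map are ignored; a population with no
        sample in the matrix is dropped.
        """
        out: dict = {p: [] for p in self.populations}
        for i, s in enumerate(matrix.samples):
            if s in self.assignment:
                out[self.assignment[s]].append(i)
        return {p: np.asarray(ix, dtype=int) for p, ix in out.items() if ix}


ARC_WEST = "west"
ARC_EAST = "east"
ARC_REFERENCE = "reference"


@dataclass
class SiteTable:
    """Population sites on (or near) the habitat ring.

    ``table`` columns: ``code``, ``lon`` (decimal degrees E), ``lat``
    (decimal degrees N), ``arc`` in {west, east, reference}, ``n`` sample
    count (0 for the reference point).
    """

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        t = self.table.reset_index(drop=True)
        for col in ("code", "lon", "lat", "arc"):
            if col not in t.columns:
                raise ValueError(f"site table lacks column {col!r}")
        if "n" not in t.columns:
            t = t.assign(n=0)
        if (t["lon"].abs() > 180).any() or (t["lat"].abs() > 90).any():
            raise ValueError("coordinates out of range")
        bad = set(t["arc"]) - {ARC_WEST, ARC_EAST, ARC_REFERENCE}
        if bad:
            raise ValueError(f"unknown arc labels {sorted(bad)}")
        self.table = t

    @property
    def codes(self) -> list:
        return list(self.table["code"])

    def coords(self, code) -> tuple:
        row = self.table.loc[self.table["code"] == code]
        if row.empty:
            raise KeyError(code)
        return float(row["lon"].iloc[0]), float(row["lat"].iloc[0])

    def arc_of(self, code) -> str:
        row = self.table.loc[self.table["code"] == code]
        if row.empty:
            raise KeyError(code)
        return str(row["arc"].iloc[0])

    def reference_code(self):
        ref = self.table.loc[self.table["arc"] == ARC_REFERENCE, "code"]
        if len(ref) != 1:
            raise ValueError(
                f"expected exactly one reference site, found {len(ref)}"
            )
        return ref.iloc[0]

    def sampled(self) -> "SiteTable":
        """Sites that carry samples (everything except the reference point)."""
        return SiteTable(
            self.table.loc[self.table["arc"] != ARC_REFERENCE].reset_index(drop=True)
        )

    def with_arcs(self, west, east) -> "SiteTable":
        """Return a copy with arc membership reassigned from two code lists."""
        t = self.table.copy()
        for code in t["code"]:
            if t.loc[t["code"] == code, "arc"].iloc[0] == ARC_REFERENCE:
                continue
            if code in west:
                t.loc[t["code"] == code, "arc"] = ARC_WEST
            elif code in east:
                t.loc[t["code"] == code, "arc"] = ARC_EAST
            else:
                raise ValueError(f"site {code!r} assigned to neither arc")
        return SiteTable(t)
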