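"""Joint folded site-frequency spectra.

A :class:`JointSFS` tabulates, over one to three population groups, how
many SNPs show each configuration of allele counts.  Because RAD data
carry no ancestral-state information the spectrum is *folded*: a cell is
indexed by minor-allele counts, i.e. cell ``c`` is pooled with its
complement ``n - c`` and only the representative with the smaller total
count is kept.  The monomorphic corners carry no information about
polymorphism and are masked.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .core import GenotypeMatrix, PopulationMap


def _canonical_cell(cell: tuple, copies: tuple) -> tuple:
    """Folded representative of ``cell``: the smaller of cell/complement.

    Smaller means smaller total allele count; an exact tie (total equal to
    half the pooled sample size) is broken lexicographically so that every
    pair folds deterministically onto one member.
    """
    comp = tuple(n - c for n, c in zip(copies, cell))
    t, tc = sum(cell), sum(comp)
    if t < tc:
        return cell
    if tc < t:
        return comp
    return min(cell, comp)


@lru_cache(maxsize=None)
def _fold_map(copies: tuple) -> tuple:
    """Flat canonical-cell index per cell, plus the folded mask."""
    shape = tuple(n + 1 for n in copies)
    idx = np.indices(shape).reshape(len(copies), -1)
    comp = np.asarray(copies)[:, None] - idx
    t, tc = idx.sum(axis=0), comp.sum(axis=0)
    use_comp = tc < t
    tie = tc == t
    for d in range(len(copies)):  # lexicographic tie-break
        use_comp |= tie & (comp[d] < idx[d])
        tie &= comp[d] == idx[d]
    canon_cells = np.where(use_comp, comp, idx)
    canon_flat = np.ravel_multi_index(tuple(canon_cells), shape)
    mask = np.ones(int(np.prod(shape)), dtype=bool)
    mask[canon_flat] = False  # representatives unmasked ...
    mask[np.ravel_multi_index(tuple(0 for _ in copies), shape)] = True
    mask[np.ravel_multi_index(copies, shape)] = True  # ... corners masked
    return canon_flat, mask.reshape(shape)


def fold_counts(counts: np.ndarray, copies) -> tuple:
    """Fold an unfolded count array; return (folded counts, mask).

    The mask is True on cells that are not folded representatives and on
    the monomorphic corners.
    """
    copies = tuple(int(n) for n in copies)
    counts = np.asarray(counts, dtype=float)
    canon_flat, mask = _fold_map(copies)
    folded = np.zeros(counts.size, dtype=float)
    np.add.at(folded, canon_flat, counts.ravel())
    folded = folded.reshape(counts.shape)
    folded[mask] = 0.0
    return folded, mask.copy()


@dataclass
class JointSFS:
    """Multidimensional folded SFS over ordered population groups."""

    pops: list
    copies: tuple
    counts: np.ndarray
    folded: bool = True
    mask: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.pops = list(self.pops)
        self.copies = tuple(int(n) for n in self.copies)
        counts = np.asarray(self.counts, dtype=float)
        expected_shape = tuple(n + 1 for n in self.copies)
        if counts.shape != expected_shape:
            raise ValueError(
                f"counts shape {counts.shape} does not match sample sizes "
                f"{self.copies} (expected {expected_shape})"
            )
        if (counts < 0).any():
            raise ValueError("negative SFS cell")
        self.counts = counts
        if self.mask is None:
            if self.folded:
                _, self.mask = fold_counts(np.zeros_like(counts), self.copies)
            else:
                self.mask = np.zeros(counts.shape, dtype=bool)
                self.mask[tuple(0 for _ in self.copies)] = True
                self.mask[self.copies] = True
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def n_snps(self) -> float:
        return float(self.counts[~self.mask].sum())

    def probabilities(self) -> np.ndarray:
        """Cell probabilities renormalised over unmasked cells."""
        total = self.counts[~self.mask].sum()
        if total <= 0:
            raise ValueError("empty SFS")
        p = np.zeros_like(self.counts)
        p[~self.mask] = self.counts[~self.mask] / total
        return p

    def fold(self) -> "JointSFS":
        if self.folded:
            return self
        folded, mask = fold_counts(self.counts, self.copies)
        return JointSFS(self.pops, self.copies, folded, folded=True, mask=mask)


def fold_joint_sfs(matrix: GenotypeMatrix, popmap: PopulationMap,
                   groups: dict) -> JointSFS:
    """Observed joint folded SFS over population groups.

    ``groups`` maps a group label to the population codes pooled into it,
    in the group order the spectrum should use.  SNPs with any missing
    call among the grouped samples are dropped (no projection), so every
    SNP contributes full gene-copy counts.
    """
    by_pop = popmap.sample_indices(matrix)
    group_idx = {}
    for g, pops in groups.items():
        idx = np.concatenate([by_pop[p] for p in pops])
        group_idx[g] = idx
    labels = list(groups)
    copies = tuple(2 * len(group_idx[g]) for g in labels)
    counts = np.zeros(tuple(n + 1 for n in copies), dtype=float)
    dosage = matrix.calls.sum(axis=2)  # alt dosage; -2 when missing
    missing = matrix.missing_mask()
    for j in range(matrix.n_snps):
        cell = []
        ok = True
        for g in labels:
            idx = group_idx[g]
            if missing[idx, j].any():
                ok = False
                break
            cell.append(int(dosage[idx, j].sum()))
        if ok:
            counts[tuple(cell)] += 1
    folded, mask = fold_counts(counts, copies)
    return JointSFS(labels, copies, folded, folded=True, mask=mask)


def neutral_folded_weights(n: int) -> np.ndarray:
    """Expected folded single-population SFS shape under neutrality.

    For sample size ``n`` gene copies the expected count at minor-allele
    frequency ``i`` is proportional to ``1/i + 1/(n-i)``, halved at
    ``i = n/2`` where a class is its own complement.  Returns the
    normalised weights for i = 1 .. floor(n/2).
    """
    if n < 2:
        raise ValueError("need n >= 2 gene copies")
    ks = np.arange(1, n // 2 + 1)
    w = 1.0 / ks + 1.0 / (n - ks)
    w[ks == n - ks] /= 2.0
    return w / w.sum()


# ---------------------------------------------------------------------------
# text serialisation
# ---------------------------------------------------------------------------

def write_sfs(sfs: JointSFS, path) -> None:
    """Write the SFS as text with an explicit dimension header."""
    with open(path, "w") as fh:
        fh.write("pops:\t" + "\t".join(str(p) for p in sfs.pops) + "\n")
        fh.write("copies:\t" + "\t".join(str(n) for n in sfs.copies) + "\n")
        fh.write(f"folded:\t{int(sfs.folded)}\n")
        flat = sfs.counts.ravel(order="C")
        fh.write("\t".join(repr(float(v)) for v in flat) + "\n")


def read_sfs(path) -> JointSFS:
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    header = {}
    data_lines = []
    for ln in lines:
        key = ln.split("\t", 1)[0]
        if key in ("pops:", "copies:", "folded:"):
            header[key[:-1]] = ln.split("\t")[1:]
        else:
            data_lines.append(ln)
    for req in ("pops", "copies", "folded"):
        if req not in header:
            raise ValueError(f"SFS file lacks {req!r} header")
    pops = header["pops"]
    copies = tuple(int(v) for v in header["copies"])
    folded = bool(int(header["folded"][0]))
    values = [float(v) for ln in data_lines for v in ln.split("\t")]
    shape = tuple(n + 1 for n in copies)
    if len(values) != int(np.prod(shape)):
        raise ValueError(
            f"cell count {len(values)} does not match declared dimensions "
            f"{shape} ({int(np.prod(shape))} cells)"
        )
    counts = np.asarray(values, dtype=float).reshape(shape, order="C")
    return JointSFS(pops, copies, counts, folded=folded)
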