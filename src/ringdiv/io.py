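"""Readers and writers for the formats the pipeline touches.

Genotypes travel as VCF.  The locus-membership convention mirrors
reference-free RAD output: ``CHROM`` is the locus identifier and ``POS``
is the (1-based) offset of the SNP within the short locus.  Population
maps and site tables are plain TSV; the joint SFS uses a small text format
with an explicit dimension header (see :mod:`ringdiv.sfs`).

Coordinates are normalised internally to decimal degrees and all
distances to kilometres.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd

from .core import MISSING, GenotypeMatrix, PopulationMap, SiteTable


class VCFParseError(ValueError):
    """The file is not well-formed VCF."""


class VCFFormatError(ValueError):
    """The VCF is readable but violates the pipeline's genotype contract."""


# ---------------------------------------------------------------------------
# coordinates
# ---------------------------------------------------------------------------

_DMS_RE = re.compile(
    r"""^\s*([+-]?)(\d+)\s*[°d]\s*          # degrees
         (\d+)\s*[′'m]\s*                   # minutes
         (\d+(?:\.\d+)?)\s*[″"s]?\s*        # seconds
         ([NSEWnsew]?)\s*$""",
    re.VERBOSE,
)


def parse_dms(text) -> float:
    """Parse a D°M′S″ or plain decimal coordinate to decimal degrees.

    The sign (or a trailing hemisphere letter S/W) is preserved.  Minutes
    and seconds must be < 60.
    """
    if isinstance(text, (int, float)):
        return float(text)
    text = str(text).strip()
    m = _DMS_RE.match(text)
    if m is None:
        try:
            return float(text)
        except ValueError:
            raise ValueError(f"unparseable coordinate {text!r}") from None
    sign_s, d, mi, s, hemi = m.groups()
    minutes, seconds = float(mi), float(s)
    if minutes >= 60 or seconds >= 60:
        raise ValueError(f"minutes/seconds out of range in {text!r}")
    value = float(d) + minutes / 60.0 + seconds / 3600.0
    sign = -1.0 if sign_s == "-" or hemi.upper() in ("S", "W") else 1.0
    return sign * value


def format_dms(value: float, seconds_decimals: int = 4) -> str:
    """Format decimal degrees as D°M′S″ (sign as a leading minus)."""
    sign = "-" if value < 0 else ""
    v = abs(value)
    d = int(v)
    rem = (v - d) * 60.0
    mi = int(rem)
    s = (rem - mi) * 60.0
    s = round(s, seconds_decimals)
    if s >= 60.0:  # carry after rounding
        s -= 60.0
        mi += 1
    if mi >= 60:
        mi -= 60
        d += 1
    return f"{sign}{d}°{mi}′{s:.{seconds_decimals}f}″"


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf(path, on_multiallelic: str = "error") -> GenotypeMatrix:
    """Read diploid biallelic genotypes from a VCF file.

    ``CHROM`` is taken as the locus id and ``POS`` as the offset within
    the locus.  ``on_multiallelic`` is one of ``"error"`` (reject the
    record) or ``"split"`` (emit one biallelic SNP per alternate allele).
    """
    from cyvcf2 import VCF

    if on_multiallelic not in ("error", "split"):
        raise ValueError(f"unknown multiallelic policy {on_multiallelic!r}")
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError on bad headers
        raise VCFParseError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    loci, poss, refs, alts, rows = [], [], [], [], []
    for rec_no, var in enumerate(vcf, start=1):
        gts = var.genotypes
        alleles_list = []
        for si, g in enumerate(gts):
            # cyvcf2 genotype: [allele_0, ..., allele_{ploidy-1}, phased]
            alleles = g[:-1]
            if len(alleles) != 2:
                raise VCFFormatError(
                    f"non-diploid genotype for sample {samples[si]!r} at "
                    f"record {rec_no} ({var.CHROM}:{var.POS})"
                )
            alleles_list.append(alleles)
        var_alts = list(var.ALT)
        if len(var_alts) > 1 and on_multiallelic == "error":
            raise VCFFormatError(
                f"multiallelic record {rec_no} ({var.CHROM}:{var.POS}); "
                "use on_multiallelic='split' to split it"
            )
        for alt_idx, alt in enumerate(var_alts, start=1):
            row = np.full((len(samples), 2), MISSING, dtype=np.int8)
            for si, alleles in enumerate(alleles_list):
                if alleles[0] < 0 or alleles[1] < 0:
                    continue
                row[si] = [1 if a == alt_idx else 0 for a in alleles]
            loci.append(var.CHROM)
            poss.append(var.POS)
            refs.append(var.REF)
            alts.append(alt)
            rows.append(row)
    snps = pd.DataFrame({"locus": loci, "pos": poss, "ref": refs, "alt": alts})
    calls = (
        np.stack(rows, axis=1)
        if rows
        else np.zeros((len(samples), 0, 2), dtype=np.int8)
    )
    return GenotypeMatrix(samples=samples, snps=snps, calls=calls)


def write_vcf(matrix: GenotypeMatrix, path) -> None:
    """Write a genotype matrix as minimal VCF v4.2 text."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for locus in matrix.loci:
            fh.write(f"##contig=<ID={locus}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        for j in range(matrix.n_snps):
            rec = matrix.snps.iloc[j]
            fields = [
                str(rec["locus"]),
                str(int(rec["pos"])),
                f"{rec['locus']}_{int(rec['pos'])}",
                str(rec["ref"]),
                str(rec["alt"]),
                ".",
                "PASS",
                ".",
                "GT",
            ]
            for i in range(matrix.n_samples):
                a, b = matrix.calls[i, j]
                fields.append("./." if a == MISSING else f"{a}/{b}")
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# population map and site table TSV
# ---------------------------------------------------------------------------

def read_population_map(path) -> PopulationMap:
    df = pd.read_csv(path, sep="\t", header=None, names=["sample", "population"],
                     dtype=str, comment="#")
    return PopulationMap(dict(zip(df["sample"], df["population"])))


def write_population_map(popmap: PopulationMap, path) -> None:
    with open(path, "w") as fh:
        for s, p in popmap.assignment.items():
            fh.write(f"{s}\t{p}\n")


def read_site_table(path) -> SiteTable:
    """Read a site table TSV (code, lon, lat, arc, n); lon/lat may be DMS."""
    df = pd.read_csv(path, sep="\t", dtype={"code": str, "arc": str})
    df["lon"] = [parse_dms(v) for v in df["lon"]]
    df["lat"] = [parse_dms(v) for v in df["lat"]]
    if "n" in df.columns:
        df["n"] = df["n"].fillna(0).astype(int)
    return SiteTable(df)


def write_site_table(sites: SiteTable, path) -> None:
    sites.table.to_csv(path, sep="\t", index=False)
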