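"""Published reference values for the nanmu ring-diversification system.

*Phoebe zhennan* (golden-thread nanmu) was sampled at 12 sites around the
Sichuan Basin, whose interior is unsuitable habitat — the populations form
a ring with a gene-flow barrier between the QCS and QL sites.  This module
bundles the published field values used as worked-example inputs and
cross-checks: site coordinates (with the ring reference point R1 used for
ring distances), the pairwise F_ST matrix among the 12 sites, per-population
diversity summaries, and the point estimates of the best-fit three-lineage
demographic model.

Two arc assignments for ring distances are provided.  ``ARCS_GEOGRAPHIC``
splits sites by which side of the QCS–QL barrier they lie on.
``ARCS_CLUSTER`` follows the two genetic clusters instead (QCS and TL are
genetically eastern despite their map position, YC and CN2 western); the
published isolation-by-distance result uses this assignment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import ARC_EAST, ARC_REFERENCE, ARC_WEST, SiteTable
from .io import parse_dms

#: site code -> (longitude E, latitude N) in D°M′S″, sample count n
_SITES = {
    "QCS": ("103°34′17.11″", "30°53′57.66″", 6),
    "QL": ("103°11′56.24″", "30°20′46.43″", 6),
    "MS": ("103°12′13.74″", "30°14′19.11″", 6),
    "EMS": ("103°26′5.58″", "29°33′50.42″", 12),
    "SF": ("104°19′9.94″", "28°34′4.52″", 6),
    "YJ": ("104°22′20.85″", "28°13′59.72″", 6),
    "CN1": ("105°0′42.27″", "28°40′42.51″", 3),
    "CN2": ("104°58′45.57″", "28°27′46.13″", 3),
    "JY": ("105°19′0.01″", "28°49′31.26″", 6),
    "XY": ("105°31′24.46″", "28°19′7.19″", 6),
    "YC": ("105°53′14.80″", "29°33′47.98″", 6),
    "TL": ("106°5′48.29″", "29°35′17.00″", 6),
    "R1": ("103°44′47.67″", "29°06′10.79″", 0),
}

SITE_CODES = [c for c in _SITES if c != "R1"]

#: arc split by geographic side of the QCS–QL barrier
ARCS_GEOGRAPHIC = {
    "west": ["QCS", "QL", "MS", "EMS", "SF", "YJ"],
    "east": ["CN1", "CN2", "JY", "XY", "YC", "TL"],
}

#: arc split by genetic cluster membership (K = 2)
ARCS_CLUSTER = {
    "west": ["QL", "MS", "EMS", "SF", "YJ", "CN2", "YC"],
    "east": ["QCS", "CN1", "JY", "XY", "TL"],
}


def site_table(arcs: str = "cluster") -> SiteTable:
    """The 12 sites plus the ring reference point R1.

    ``arcs`` selects the west/east split used for ring distances:
    ``"cluster"`` (genetic clusters; the published construction) or
    ``"geographic"`` (side of the QCS–QL barrier).
    """
    assignment = {"cluster": ARCS_CLUSTER, "geographic": ARCS_GEOGRAPHIC}[arcs]
    rows = []
    for code, (lon, lat, n) in _SITES.items():
        if code == "R1":
            arc = ARC_REFERENCE
        elif code in assignment["west"]:
            arc = ARC_WEST
        else:
            arc = ARC_EAST
        rows.append(
            {"code": code, "lon": parse_dms(lon), "lat": parse_dms(lat),
             "arc": arc, "n": n}
        )
    return SiteTable(pd.DataFrame(rows))


# lower triangle of the published pairwise F_ST among the 12 sites
# (16,210 SNPs; slightly negative estimates retained as printed)
_FST_LOWER = {
    "QL": [0.377],
    "MS": [0.291, 0.265],
    "EMS": [0.220, 0.259, 0.193],
    "SF": [0.278, 0.317, 0.248, 0.185],
    "YJ": [0.389, 0.421, 0.362, 0.297, 0.034],
    "CN1": [-0.131, 0.415, 0.321, 0.250, 0.299, 0.418],
    "CN2": [0.351, 0.385, 0.305, 0.049, 0.277, 0.400, 0.400],
    "JY": [-0.076, 0.375, 0.293, 0.225, 0.279, 0.387, -0.133, 0.345],
    "XY": [-0.038, 0.321, 0.239, 0.170, 0.226, 0.337, -0.068, 0.278, -0.036],
    "YC": [0.325, 0.403, 0.329, 0.257, 0.315, 0.419, 0.413, 0.379, 0.372,
           0.320],
    "TL": [-0.068, 0.446, 0.366, 0.295, 0.351, 0.454, -0.157, 0.433, -0.069,
           -0.004, 0.444],
}


def pairwise_fst() -> pd.DataFrame:
    """Published 12x12 pairwise F_ST matrix (zeros on the diagonal)."""
    n = len(SITE_CODES)
    m = np.zeros((n, n))
    for i, code in enumerate(SITE_CODES):
        for j, v in enumerate(_FST_LOWER.get(code, [])):
            m[i, j] = m[j, i] = v
    return pd.DataFrame(m, index=SITE_CODES, columns=SITE_CODES)


# per-population diversity summaries computed from the full dataset
# (31,834 polymorphic loci).  Columns: %P, private alleles, then
# (H_O, H_E, pi, F_IS) for the all-nucleotide panel and the SNP-only panel.
_DIVERSITY_ROWS = [
    # code   %P    PA    HO_rad  HE_rad  pi_rad  FIS_rad  HO_snp HE_snp pi_snp FIS_snp
    ("QCS", 1.16, 49, 0.0071, 0.0043, 0.0048, -0.0042, 0.227, 0.138, 0.152, -0.135),
    ("QL", 0.81, 114, 0.0079, 0.0040, 0.0044, -0.0064, 0.252, 0.128, 0.141, -0.203),
    ("MS", 1.28, 1068, 0.0076, 0.0046, 0.0051, -0.0045, 0.247, 0.151, 0.165, -0.146),
    ("EMS", 1.95, 3435, 0.0076, 0.0058, 0.0061, -0.0033, 0.243, 0.186, 0.196, -0.107),
    ("SF", 1.19, 821, 0.0075, 0.0049, 0.0053, -0.0042, 0.250, 0.163, 0.179, -0.142),
    ("YJ", 0.80, 33, 0.0078, 0.0039, 0.0044, -0.0062, 0.260, 0.132, 0.145, -0.208),
    ("JY", 1.20, 922, 0.0070, 0.0043, 0.0047, -0.0041, 0.233, 0.143, 0.157, -0.136),
    ("XY", 1.26, 1076, 0.0070, 0.0048, 0.0053, -0.0036, 0.234, 0.160, 0.176, -0.119),
    ("YC", 0.76, 327, 0.0075, 0.0038, 0.0041, -0.0061, 0.249, 0.126, 0.139, -0.202),
    ("TL", 0.72, 19, 0.0071, 0.0036, 0.0039, -0.0058, 0.234, 0.118, 0.130, -0.190),
]


def diversity_table() -> pd.DataFrame:
    """Published per-population diversity summaries (10 populations)."""
    return pd.DataFrame(
        _DIVERSITY_ROWS,
        columns=["code", "pct_polymorphic", "private_alleles",
                 "HO_rad", "HE_rad", "pi_rad", "FIS_rad",
                 "HO_snp", "HE_snp", "pi_snp", "FIS_snp"],
    ).set_index("code")


# dataset bookkeeping from the locus/SNP calling stage
N_PRELIMINARY_LOCI = 43906
N_POLYMORPHIC_LOCI = 31834
N_SNPS_FULL = 59288
N_SNPS_FILTERED = 16210

# best-fit three-lineage demographic model: point estimates
# sizes are diploid Ne, times in generations, migration is the backward
# per-generation migration probability
MODEL1_ESTIMATES = {
    "N_cur_W1": 78_864.0,
    "N_cur_W2": 722_318.0,
    "N_cur_East": 757_511.0,
    "N_Anc_all": 850_047.0,
    "N_Anc_w12": 34_972.0,
    "T_1": 1_005_501.0,
    "T_2": 474_808.0,
    "M12": 1.00e-05,
    "M21": 2.63e-08,
    "M01": 3.70e-06,
    "M10": 2.02e-06,
    "M20": 3.13e-09,
    "M02": 5.06e-08,
    "M0_w12": 1.89e-07,
    "Mw12_0": 4.16e-07,
}

GENERATION_TIME_YEARS = 15.0

# gene copies sampled per group in the demographic analysis
GROUP_GENE_COPIES = {"East": 30, "West1": 24, "West2": 24}
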