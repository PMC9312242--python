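"""Published reference values for a 29-locus Eurasian perch marker panel.

Printed tables from a four-population wild *Perca fluviatilis* survey in
Xinjiang (Kalaeerqisi River KR n=34, Wulungu River WR n=77, Jili Lake JL
n=68, Wulungu Lake WL n=89; 268 diploid individuals genotyped at 29
tetranucleotide microsatellite loci). These serve as fixed re-analysis
inputs and cross-checks; the underlying genotypes are not public, so
anything requiring them is exercised on synthetic data instead.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "POPULATION_SIZES",
    "N_SAMPLES",
    "marker_panel",
    "tetranucleotide_motif_counts",
    "genome_ssr_period_counts",
    "locus_diversity_table",
    "amova_components",
    "distance_fst_table",
    "PRIMERS_TESTED",
    "PRIMERS_POLYMORPHIC",
    "PRIMERS_CLEAR_BANDS",
]

POPULATION_SIZES = {"KR": 34, "WR": 77, "JL": 68, "WL": 89}
N_SAMPLES = 268

PRIMERS_TESTED = 200
PRIMERS_CLEAR_BANDS = 191
PRIMERS_POLYMORPHIC = 152

# genome-wide perfect-SSR counts per motif period
_PERIOD_COUNTS = {2: 76943, 3: 10494, 4: 8751, 5: 2237}

_MARKERS = [
    # locus, forward, reverse, motif, n_repeats, size_min, size_max
    ("HLJHL007", "GCTAATGCCTGACCACCACT", "CAGGTCCCTGGAGAAGAGAGA", "ACAG", 10, 109, 130),
    ("HLJHL022", "CCCTGAGTGGAGCACATACC", "GGCCGAATTTTGCCTTTGTA", "ACAG", 12, 100, 131),
    ("HLJHL045", "GATGGTCTCACGAGGCTAGC", "TCGGTTTGGATGGTCGGTTT", "ACAG", 14, 86, 114),
    ("HLJHL052", "ACCTGAAGGCAAGTGGATGG", "CCTGGCCCTGAATGTACCAA", "ACAG", 15, 92, 120),
    ("HLJHL056", "CAGCAGCCTGATCAGCATCA", "TGCTTTACTTCCTCATCACAGC", "ACAG", 15, 120, 148),
    ("HLJHL059", "GGTTTCAAGGGAGAGGGAGG", "GCAGCTCATGAACAACTCTGC", "ACAG", 15, 92, 145),
    ("HLJHL084", "AGCTCGACTAGGGTGACTGT", "CCGAGCACTGCTACGAAACT", "ACAG", 18, 143, 174),
    ("HLJHL089", "ATTCACACAAACAAGCAGGC", "GCTATGTGGCTCTTTGTATGCC", "ACAG", 19, 100, 160),
    ("HLJHL090", "GGCGCTGTCCATGGTACTAA", "ACCACGAAAAGCAAGAAGGC", "ACAG", 19, 117, 162),
    ("HLJHL094", "ACTCACCATACGCATGTGCT", "CTCCTCAAAGTCGCCTTCCA", "ACAG", 19, 114, 186),
    ("HLJHL104", "CCCAAATTTCCTGACAACCCA", "GGACTGTCCCGTGTTTCTCA", "AGAT", 10, 132, 223),
    ("HLJHL105", "GCGCGATAAAATAATTGTCGGC", "TCAGGCTCAGGAATTTCTTTCA", "AGAT", 10, 107, 148),
    ("HLJHL107", "AGACAGGGTGATAGTTACATCCA", "TGTGCAAAATTTACATGGGATGA", "AGAT", 10, 118, 188),
    ("HLJHL121", "ATTGGCATCAGAGCAAGCTG", "ATGGGGCTTTGACGTGAGAG", "AGAT", 11, 184, 265),
    ("HLJHL152", "GCCAACACCCTATAACTGAAGC", "CGTTGTTGCCAATGGAATGC", "AGAT", 14, 140, 185),
    ("HLJHL153", "GGCTGATAAACATAGGCCTATGC", "AGCTACTGGGATCTTGAAGGT", "AGAT", 14, 123, 151),
    ("HLJHL164", "CCACCTCTGCCACCTCATAC", "CGAAGGGATCTCCATCTGCT", "AGAT", 15, 104, 175),
    ("HLJHL165", "TCCAGTTGTCACTTCAGCGT", "AGGACACATTTCCTTCGGGA", "AGAT", 15, 88, 194),
    ("HLJHL167", "CGTTTTGGATATGTGCCATGT", "TGGCACATATCTAAAACGTGGT", "AGAT", 15, 140, 188),
    ("HLJHL169", "GCAGGGGCAAACAGTCATCA", "TCTGTGAGCTACTGGGACCT", "AGAT", 16, 100, 152),
    ("HLJHL172", "ACAGCCCATAACACAGCAGT", "TCTGCATGAACTAAAGTGTGACA", "AGAT", 16, 126, 187),
    ("HLJHL174", "TCAGCTGCGGATTATTACACA", "GCAGTGATATTGCAACAGGAAA", "AGAT", 16, 131, 162),
    ("HLJHL179", "GGTGATACATAGATAGGTAGGTCGG", "TCTGGTAGTCTCAGCTCGCT", "AGAT", 16, 96, 153),
    ("HLJHL183", "TGTTGTCAGTGTGTTCATCCA", "TGCATGGTGTTTTAAGTCAGGG", "AGAT", 17, 125, 168),
    ("HLJHL186", "CAACCAGCTTCAACCCGTTG", "TCCACCTCTCCCTTTCCCTT", "AGAT", 17, 123, 237),
    ("HLJHL189", "CCTCCTGTGTTTTGTGTCTTGG", "TCTCCAGTACTCACAATGGCT", "AGAT", 18, 124, 175),
    ("HLJHL192", "TGGTTCTACAAGCTGCCTAAA", "AACCAGGCGTTGAGTTTCAA", "AGAT", 18, 102, 168),
    ("HLJHL196", "TCTGAGACAAAGGGACATGAAT", "CAGGAATTTCCCCAGTGTGG", "AGAT", 19, 111, 183),
    ("HLJHL199", "TGGACTAAGACTGCCTACTGC", "CCTTGAGTTCACTTGCGTGT", "AGAT", 20, 134, 190),
]

_TETRA_COUNTS = {
    "AGAT": 1556, "ACAG": 1339, "ATCC": 752, "AAAT": 645, "AAAG": 610,
    "ACAT": 560, "AATC": 485, "ACGC": 442, "AGGG": 430, "AATG": 302,
    "AAGG": 234, "AAAC": 221, "AAGT": 201, "ACTC": 173, "ACTG": 135,
    "AACT": 127, "AGGC": 107, "AGCT": 101, "AGCC": 75, "AATT": 69,
    "AACC": 52, "ACCT": 40, "ACCC": 37, "ATGC": 22, "ACCG": 9,
    "AAGC": 8, "AGCG": 7, "ATCG": 4, "ACGG": 3, "CCCG": 2,
    "ACGT": 2, "CCGG": 1,
}

_DIVERSITY_ROWS = [
    # locus, Na, Ne, Ho, He, PIC (pooled over the 268 samples)
    ("HLJHL007", 4, 2.201, 0.403, 0.547, 0.489),
    ("HLJHL022", 6, 2.169, 0.496, 0.540, 0.450),
    ("HLJHL045", 8, 2.133, 0.485, 0.532, 0.496),
    ("HLJHL052", 4, 1.784, 0.425, 0.440, 0.364),
    ("HLJHL056", 5, 2.827, 0.623, 0.647, 0.578),
    ("HLJHL059", 10, 4.444, 0.675, 0.776, 0.741),
    ("HLJHL084", 9, 1.310, 0.239, 0.237, 0.225),
    ("HLJHL089", 11, 2.264, 0.489, 0.559, 0.528),
    ("HLJHL090", 11, 1.671, 0.373, 0.402, 0.389),
    ("HLJHL094", 18, 3.057, 0.623, 0.674, 0.661),
    ("HLJHL104", 17, 7.506, 0.869, 0.868, 0.853),
    ("HLJHL105", 11, 7.389, 0.847, 0.866, 0.850),
    ("HLJHL107", 18, 9.968, 0.896, 0.901, 0.892),
    ("HLJHL121", 19, 10.077, 0.877, 0.902, 0.893),
    ("HLJHL152", 13, 5.949, 0.791, 0.833, 0.811),
    ("HLJHL153", 8, 4.181, 0.716, 0.762, 0.725),
    ("HLJHL164", 14, 5.863, 0.776, 0.831, 0.809),
    ("HLJHL165", 20, 3.269, 0.608, 0.695, 0.650),
    ("HLJHL167", 13, 6.486, 0.519, 0.847, 0.827),
    ("HLJHL169", 9, 3.256, 0.690, 0.694, 0.641),
    ("HLJHL172", 15, 4.677, 0.750, 0.788, 0.765),
    ("HLJHL174", 9, 4.714, 0.731, 0.789, 0.760),
    ("HLJHL179", 11, 3.273, 0.612, 0.696, 0.658),
    ("HLJHL183", 12, 3.973, 0.698, 0.750, 0.720),
    ("HLJHL186", 29, 10.914, 0.694, 0.910, 0.901),
    ("HLJHL192", 14, 5.783, 0.694, 0.829, 0.808),
    ("HLJHL196", 15, 2.389, 0.526, 0.583, 0.512),
    ("HLJHL199", 16, 9.361, 0.843, 0.895, 0.884),
    ("HLJHL200", 15, 6.564, 0.813, 0.849, 0.833),
]

# two-level AMOVA over the 268 samples (gene-copy level)
_AMOVA = {
    "df_among": 3, "df_within": 532, "df_total": 535,
    "ss_among": 334.462, "ss_within": 5188.229, "ss_total": 5522.690,
    "var_among": 0.784, "var_within": 9.752, "var_total": 10.536,
}

_POP_ORDER = ["WR", "JL", "WL", "KR"]
# Nei's standard genetic distance D (below diagonal) / pairwise Fst (above)
_FST_ABOVE = {
    ("WR", "JL"): 0.087, ("WR", "WL"): 0.071, ("WR", "KR"): 0.158,
    ("JL", "WL"): 0.003, ("JL", "KR"): 0.116, ("WL", "KR"): 0.100,
}
_D_BELOW = {
    ("JL", "WR"): 0.205, ("WL", "WR"): 0.157, ("KR", "WR"): 0.288,
    ("WL", "JL"): 0.027, ("KR", "JL"): 0.244, ("KR", "WL"): 0.1987,
}


def marker_panel() -> pd.DataFrame:
    """The 29 published primer pairs with motif and fragment-size range."""
    return pd.DataFrame(
        _MARKERS,
        columns=["locus", "forward", "reverse", "motif", "n_repeats",
                 "size_min", "size_max"],
    )


def tetranucleotide_motif_counts() -> dict[str, int]:
    """Genome-wide tetranucleotide SSR counts per canonical motif class."""
    return dict(_TETRA_COUNTS)


def genome_ssr_period_counts() -> dict[int, int]:
    """Genome-wide perfect-SSR counts by motif period (2-5 bp)."""
    return dict(_PERIOD_COUNTS)


def locus_diversity_table() -> pd.DataFrame:
    """Published per-locus diversity panel (pooled sample, n = 268)."""
    return pd.DataFrame(
        _DIVERSITY_ROWS, columns=["locus", "Na", "Ne", "Ho", "He", "PIC"]
    )


def amova_components() -> dict[str, float]:
    """Published AMOVA decomposition (df, SS, variance components)."""
    return dict(_AMOVA)


def distance_fst_table():
    """(labels, D matrix, Fst matrix) for the four populations.

    D is Nei's standard distance (symmetric full matrix built from the
    published below-diagonal entries), Fst the pairwise differentiation.
    """
    labels = list(_POP_ORDER)
    n = len(labels)
    d = np.zeros((n, n))
    fst = np.zeros((n, n))
    for (a, b), v in _D_BELOW.items():
        i, j = labels.index(a), labels.index(b)
        d[i, j] = d[j, i] = v
    for (a, b), v in _FST_ABOVE.items():
        i, j = labels.index(a), labels.index(b)
        fst[i, j] = fst[j, i] = v
    return labels, d, fst
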