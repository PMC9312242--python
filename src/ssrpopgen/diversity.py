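"""Per-locus diversity statistics for codominant microsatellite data.

Implements the classic marker-characterisation panel: observed allele number
Na, effective allele number Ne = 1/sum(p_i^2), observed heterozygosity Ho,
Nei's unbiased expected heterozygosity He = (2n/(2n-1))(1 - sum p_i^2),
Botstein's polymorphic information content

    PIC = 1 - sum_i p_i^2 - sum_{i<j} 2 p_i^2 p_j^2,

a Monte-Carlo exact Hardy-Weinberg test conditioning on allele counts, and
Nei's (1972) standard genetic distance between populations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from ._util import MISSING, round_half_up
from .genotypes import AlleleFrequencyTable, GenotypeMatrix, allele_freqs

__all__ = [
    "LocusStats",
    "PopulationStats",
    "locus_stats",
    "population_locus_stats",
    "pic",
    "classify_pic",
    "hwe_exact_test",
    "nei_distance",
    "nei_distance_matrix",
    "aggregate_population_stats",
]


@dataclass(frozen=True)
class LocusStats:
    """One locus's diversity panel (a row of a marker-characterisation table)."""

    locus: str
    na: int
    ne: float
    ho: float
    he: float
    pic: float
    n: int
    p_hwe: float | None = None


@dataclass(frozen=True)
class PopulationStats:
    """Across-locus means of the diversity panel for one population."""

    population: str
    n_loci: int
    total_alleles: int
    mean_na: float
    mean_ne: float
    mean_ho: float
    mean_he: float
    mean_pic: float
    n_high_pic: int
    n_moderate_pic: int
    n_low_pic: int
    n_hwe_departures: int | None = None


def pic(frequencies) -> float:
    """Botstein polymorphic information content of an allele-frequency vector."""
    p = np.asarray(list(frequencies), dtype=float)
    if (p < 0).any():
        raise ValueError("negative allele frequency")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"frequencies sum to {p.sum()}, not 1")
    s2 = float(np.sum(p**2))
    s4 = float(np.sum(p**4))
    # sum_{i<j} 2 p_i^2 p_j^2 == (sum p^2)^2 - sum p^4
    return 1.0 - s2 - (s2 * s2 - s4)


def classify_pic(value: float) -> str:
    """Polymorphism band: >=0.5 high, [0.25, 0.5) moderate, <0.25 low."""
    if value >= 0.5:
        return "high"
    if value >= 0.25:
        return "moderate"
    return "low"


def locus_stats(
    locus: str,
    freq_entry: dict[int, float],
    n: int,
    genotype_column: np.ndarray | None = None,
    unbiased_he: bool = True,
) -> LocusStats:
    """Diversity panel for one locus.

    *freq_entry* maps allele code -> relative frequency over the 2n copies;
    *genotype_column* is the (m, 2) array of calls used for Ho (rows with
    MISSING are skipped). With ``unbiased_he`` the Nei small-sample factor
    2n/(2n-1) is applied, which is what the standard marker-table software
    reports; the biased 1 - sum p^2 form is available for cross-checks.
    """
    if n < 1 or not freq_entry:
        raise ValueError(f"locus {locus!r} has no called genotypes")
    p = np.array(list(freq_entry.values()), dtype=float)
    s2 = float(np.sum(p**2))
    na = int(np.sum(p > 0))
    ne = 1.0 / s2
    he = 1.0 - s2
    if unbiased_he:
        he *= (2 * n) / (2 * n - 1)

    ho = float("nan")
    if genotype_column is not None:
        col = np.asarray(genotype_column)
        called = col[col[:, 0] != MISSING]
        if len(called):
            ho = float(np.mean(called[:, 0] != called[:, 1]))
    return LocusStats(locus=locus, na=na, ne=ne, ho=ho, he=he, pic=pic(p), n=n)


def population_locus_stats(
    g: GenotypeMatrix,
    pool: str = "ALL",
    unbiased_he: bool = True,
    hwe_mc: int | None = None,
    seed: int | None = None,
) -> list[LocusStats]:
    """Per-locus panels for one population (or the pooled sample)."""
    table = allele_freqs(g, pool)
    idx = g.pop_indices(pool)
    out: list[LocusStats] = []
    rngs = None
    if hwe_mc is not None:
        rngs = np.random.SeedSequence(seed).spawn(g.n_loci)
    for j, locus in enumerate(g.loci):
        if table.n[locus] == 0:
            continue  # flagged via AlleleFrequencyTable.empty_loci
        st = locus_stats(
            locus, table.freqs[locus], table.n[locus],
            genotype_column=g.calls[idx, j, :], unbiased_he=unbiased_he,
        )
        if hwe_mc is not None:
            p_hwe = hwe_exact_test(
                _genotype_counts(g.calls[idx, j, :]), n_mc=hwe_mc,
                seed=rngs[j],
            )
            st = LocusStats(**{**st.__dict__, "p_hwe": p_hwe})
        out.append(st)
    return out


def _genotype_counts(column: np.ndarray) -> dict[tuple[int, int], int]:
    col = np.asarray(column)
    called = col[col[:, 0] != MISSING]
    counts: dict[tuple[int, int], int] = {}
    for a, b in called:
        key = (int(min(a, b)), int(max(a, b)))
        counts[key] = counts.get(key, 0) + 1
    return counts


def hwe_exact_test(
    genotype_counts: dict[tuple[int, int], int],
    n_mc: int = 10_000,
    seed=None,
) -> float:
    """Monte-Carlo exact Hardy-Weinberg test (Guo-Thompson style).

    Tables are generated by randomly pairing the observed allele pool
    (i.e. sampled from the null conditional on allele counts); the p-value
    is the share of tables whose conditional probability is <= that of the
    observed table, with the observed table counted in both numerator and
    denominator. Monomorphic loci return p = 1 by convention.
    """
    if n_mc < 100:
        raise ValueError(f"n_mc must be >= 100, got {n_mc}")
    n = sum(genotype_counts.values())
    if n < 1:
        raise ValueError("no genotypes")
    pairs: list[tuple[int, int]] = []
    for (a, b), c in genotype_counts.items():
        pairs.extend([(a, b)] * c)
    alleles = sorted({a for ab in pairs for a in ab})
    if len(alleles) < 2:
        return 1.0
    code = {a: i for i, a in enumerate(alleles)}
    k = len(alleles)
    obs_pairs = np.array([(code[a], code[b]) for a, b in pairs], dtype=np.int64)
    pool_arr = obs_pairs.ravel().copy()

    logfact = gammaln(np.arange(2 * n + 1) + 1.0)

    def table_logprob(pair_codes: np.ndarray) -> float:
        # Levene's conditional probability of a genotype table given allele counts
        lo = pair_codes.min(axis=1)
        hi = pair_codes.max(axis=1)
        cell = lo * k + hi
        cnt = np.bincount(cell, minlength=k * k)
        n_het = int(np.sum(lo != hi))
        return n_het * math.log(2.0) - float(logfact[cnt].sum())

    # the constant log n! + sum_a log c_a! - log (2n)! cancels in the comparison
    obs_lp = table_logprob(obs_pairs)

    rng = np.random.default_rng(seed)
    hits = 0
    work = pool_arr.copy()
    for _ in range(n_mc):
        rng.shuffle(work)
        if table_logprob(work.reshape(-1, 2)) <= obs_lp + 1e-12:
            hits += 1
    return (hits + 1) / (n_mc + 1)


def nei_distance(fx: AlleleFrequencyTable, fy: AlleleFrequencyTable) -> float:
    """Nei's (1972) standard genetic distance between two populations.

    D = -ln( Jxy / sqrt(Jx * Jy) ) with Jxy, Jx, Jy the arithmetic means
    over shared loci of sum_i p_xi p_yi, sum_i p_xi^2 and sum_i p_yi^2.
    Returns ``inf`` when the populations share no alleles at any locus.
    """
    shared = [
        loc for loc in fx.freqs
        if loc in fy.freqs and fx.n.get(loc, 0) > 0 and fy.n.get(loc, 0) > 0
    ]
    if not shared:
        raise ValueError("no loci with data in both populations")
    jxy = np.mean([
        sum(p * fy.freqs[loc].get(a, 0.0) for a, p in fx.freqs[loc].items())
        for loc in shared
    ])
    jx = np.mean([sum(p * p for p in fx.freqs[loc].values()) for loc in shared])
    jy = np.mean([sum(p * p for p in fy.freqs[loc].values()) for loc in shared])
    if jxy == 0.0:
        return float("inf")
    return float(-math.log(jxy / math.sqrt(jx * jy)))


def nei_distance_matrix(g: GenotypeMatrix):
    """Pairwise Nei D over the populations of *g* (labelled DistanceMatrix)."""
    from .upgma import DistanceMatrix

    labels = g.population_labels
    tables = {p: allele_freqs(g, p) for p in labels}
    m = np.zeros((len(labels), len(labels)))
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            d = nei_distance(tables[labels[i]], tables[labels[j]])
            m[i, j] = m[j, i] = d
    return DistanceMatrix(labels=labels, values=m)


def aggregate_population_stats(
    stats: list[LocusStats],
    population: str = "ALL",
    alpha: float = 0.05,
    hwe_correction: str = "none",
) -> PopulationStats:
    """Across-locus arithmetic means plus PIC-band and HWE-departure counts.

    ``hwe_correction`` is ``"none"`` (per-locus alpha, the default the
    standard table software uses) or ``"holm"`` (sequential Bonferroni).
    """
    if not stats:
        raise ValueError("no per-locus stats to aggregate")
    bands = [classify_pic(s.pic) for s in stats]
    n_dep: int | None = None
    pvals = [s.p_hwe for s in stats if s.p_hwe is not None]
    if pvals:
        if hwe_correction == "holm":
            order = np.argsort(pvals)
            m = len(pvals)
            n_dep = 0
            for rank, ix in enumerate(order):
                if pvals[ix] <= alpha / (m - rank):
                    n_dep += 1
                else:
                    break
        elif hwe_correction == "none":
            n_dep = sum(p < alpha for p in pvals)
        else:
            raise ValueError(f"unknown hwe_correction {hwe_correction!r}")
    return PopulationStats(
        population=population,
        n_loci=len(stats),
        total_alleles=int(sum(s.na for s in stats)),
        mean_na=float(np.mean([s.na for s in stats])),
        mean_ne=float(np.mean([s.ne for s in stats])),
        mean_ho=float(np.mean([s.ho for s in stats])),
        mean_he=float(np.mean([s.he for s in stats])),
        mean_pic=float(np.mean([s.pic for s in stats])),
        n_high_pic=bands.count("high"),
        n_moderate_pic=bands.count("moderate"),
        n_low_pic=bands.count("low"),
        n_hwe_departures=n_dep,
    )


def stats_to_dataframe(stats: list[LocusStats], ndigits: int = 3):
    """Marker-table layout (Na, Ne, Ho, He, PIC per locus), values rounded
    half-up to *ndigits* as such tables conventionally print."""
    import pandas as pd

    return pd.DataFrame(
        {
            "locus": [s.locus for s in stats],
            "Na": [s.na for s in stats],
            "Ne": [round_half_up(s.ne, ndigits) for s in stats],
            "Ho": [round_half_up(s.ho, ndigits) for s in stats],
            "He": [round_half_up(s.he, ndigits) for s in stats],
            "PIC": [round_half_up(s.pic, ndigits) for s in stats],
            "P_HWE": [
                None if s.p_hwe is None else round_half_up(s.p_hwe, ndigits)
                for s in stats
            ],
            "n": [s.n for s in stats],
        }
    )
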