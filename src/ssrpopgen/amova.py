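"""Analysis of molecular variance (AMOVA) and Fst for codominant genotypes.

Two-level AMOVA partitioning the variance of allele-copy differences into
among- and within-population components. Each diploid individual contributes
two gene copies; the squared distance between two copies is the number of
loci at which their alleles differ (loci missing in either individual are
skipped pairwise). Sums of squares are computed from per-locus allele counts
(algebraically identical to partitioning the pairwise mismatch-distance
matrix) so permutation tests stay cheap:

    SS_within = sum_loci sum_k (m_kl - sum_a c_kla^2 / m_kl) / 2 / ...

with degrees of freedom (P-1, 2N-P, 2N-1) over gene copies. The among
component uses the standard unequal-sample-size coefficient
n' = (m - sum_k m_k^2 / m) / (P - 1) on copy counts. Fst is
sigma2_a / (sigma2_a + sigma2_w); its p-value comes from permuting whole
individuals among populations (sizes preserved) with the (b+1)/(m+1)
correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import MISSING, round_half_up
from .genotypes import GenotypeMatrix

__all__ = [
    "Amova",
    "AmovaResult",
    "PairwiseFstMatrix",
    "amova",
    "pct_from_components",
    "pairwise_fst",
    "classify_fst",
]


@dataclass
class AmovaResult:
    """Variance decomposition, Fst and permutation p for one AMOVA fit."""

    df_among: int
    df_within: int
    ss_among: float
    ss_within: float
    var_among: float
    var_within: float
    pct_among: float
    pct_within: float
    fst: float
    p_value: float | None
    n_permutations: int
    seed: int | None
    populations: list[str] = field(default_factory=list)

    @property
    def df_total(self) -> int:
        return self.df_among + self.df_within

    @property
    def ss_total(self) -> float:
        return self.ss_among + self.ss_within

    @property
    def var_total(self) -> float:
        return self.var_among + self.var_within

    def summary(self) -> str:
        rows = [
            ("Among populations", self.df_among, self.ss_among, self.var_among, self.pct_among),
            ("Within populations", self.df_within, self.ss_within, self.var_within, self.pct_within),
            ("Total", self.df_total, self.ss_total, self.var_total, None),
        ]
        lines = [
            f"{'Source of variation':<22}{'df':>6}{'SS':>12}{'Var comp':>10}{'% var':>8}",
        ]
        for name, df, ss, var, pct in rows:
            pct_s = "" if pct is None else f"{round_half_up(pct, 2):>8}"
            lines.append(
                f"{name:<22}{df:>6}{round_half_up(ss, 3):>12}{round_half_up(var, 3):>10}{pct_s}"
            )
        lines.append(
            f"Fst = {round_half_up(self.fst, 3)} ({classify_fst(max(self.fst, 0.0))} differentiation)"
        )
        if self.p_value is not None:
            lines.append(
                f"Permutation p = {self.p_value:.4g} ({self.n_permutations} permutations)"
            )
        return "\n".join(lines)


@dataclass
class PairwiseFstMatrix:
    """Symmetric pairwise Fst with permutation p-values per population pair."""

    labels: list[str]
    fst: np.ndarray
    p_values: np.ndarray
    alpha: float = 0.05
    unreliable: list[tuple[str, str]] = field(default_factory=list)

    def significant(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return self.p_values < self.alpha

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.fst, index=self.labels, columns=self.labels)


def classify_fst(fst: float) -> str:
    """Wright's differentiation bands, left-inclusive."""
    if fst < 0:
        raise ValueError("classification expects fst >= 0")
    if fst < 0.05:
        return "low"
    if fst < 0.15:
        return "moderate"
    if fst < 0.25:
        return "high"
    return "very high"


def pct_from_components(var_among: float, var_within: float):
    """Percent variation and Fst from printed variance components."""
    total = var_among + var_within
    if total == 0:
        raise ValueError("both variance components are zero; Fst undefined")
    fst = var_among / total
    return 100.0 * fst, 100.0 * var_within / total, fst


class Amova:
    """Two-level AMOVA model for a multi-population genotype matrix.

    Built from data; :meth:`fit` runs the decomposition and permutation
    test and returns an :class:`AmovaResult`.
    """

    def __init__(self, genotypes: GenotypeMatrix):
        if len(genotypes.population_labels) < 2:
            raise ValueError("AMOVA needs at least 2 populations")
        self.genotypes = genotypes
        self.labels = genotypes.population_labels
        self._prepare()

    def _prepare(self) -> None:
        g = self.genotypes
        self._pop_of_ind = np.array(
            [self.labels.index(p) for p in g.populations], dtype=np.int64
        )
        # per locus: copy-level arrays (individual index, allele code index)
        self._locus_copies: list[tuple[np.ndarray, np.ndarray, int]] = []
        for j in range(g.n_loci):
            col = g.calls[:, j, :]
            called = np.flatnonzero(col[:, 0] != MISSING)
            if called.size == 0:
                continue
            ind_idx = np.repeat(called, 2)
            alleles = col[called].ravel()
            codes = np.unique(alleles, return_inverse=True)[1]
            self._locus_copies.append((ind_idx, codes, int(codes.max()) + 1))

    def _ss(self, pop_of_ind: np.ndarray) -> tuple[float, float]:
        """(SS_among, SS_within) for a given individual->population mapping.

        Units are the 2N gene copies; distances skip loci missing in either
        individual, so the per-locus pair counts use called copies while the
        denominators stay the groups' full copy counts.
        """
        n_pops = len(self.labels)
        copies_per_pop = 2.0 * np.bincount(pop_of_ind, minlength=n_pops)
        m_total = copies_per_pop.sum()
        within_num = np.zeros(n_pops)  # sum over loci of pairwise mismatches x2
        total_num = 0.0
        for ind_idx, codes, n_alleles in self._locus_copies:
            grp = pop_of_ind[ind_idx]
            m_kl = np.bincount(grp, minlength=n_pops).astype(float)
            joint = np.bincount(grp * n_alleles + codes,
                                minlength=n_pops * n_alleles).astype(float)
            joint = joint.reshape(n_pops, n_alleles)
            within_num += (m_kl**2 - (joint**2).sum(axis=1)) / 2.0
            c_tot = joint.sum(axis=0)
            total_num += (m_kl.sum() ** 2 - float((c_tot**2).sum())) / 2.0
        ss_within = float((within_num / copies_per_pop).sum())
        ss_total = total_num / m_total
        return ss_total - ss_within, ss_within

    def _components(self, pop_of_ind: np.ndarray):
        g = self.genotypes
        n_pops = len(self.labels)
        copies_per_pop = 2.0 * np.bincount(pop_of_ind, minlength=n_pops)
        m = copies_per_pop.sum()
        df_among = n_pops - 1
        df_within = int(m) - n_pops
        n_prime = (m - (copies_per_pop**2).sum() / m) / df_among
        ss_among, ss_within = self._ss(pop_of_ind)
        var_within = ss_within / df_within
        var_among = (ss_among / df_among - var_within) / n_prime
        return ss_among, ss_within, var_among, var_within, df_among, df_within

    def fit(self, n_permutations: int = 1000, seed: int | None = None) -> AmovaResult:
        ss_a, ss_w, var_a, var_w, df_a, df_w = self._components(self._pop_of_ind)
        if var_a < 0:
            warnings.warn(
                "negative among-population variance component "
                f"({var_a:.4g}); reported as-is", stacklevel=2
            )
        total = var_a + var_w
        fst = var_a / total if total > 0 else float("nan")
        pct_among = 100.0 * fst
        pct_within = 100.0 - pct_among

        p_value = None
        if n_permutations > 0:
            rng = np.random.default_rng(seed)
            labels = self._pop_of_ind.copy()
            hits = 0
            for _ in range(n_permutations):
                rng.shuffle(labels)
                _, _, pa, pw, _, _ = self._components(labels)
                ptot = pa + pw
                perm_fst = pa / ptot if ptot > 0 else float("-inf")
                if perm_fst >= fst:
                    hits += 1
            p_value = (hits + 1) / (n_permutations + 1)

        return AmovaResult(
            df_among=df_a, df_within=df_w,
            ss_among=ss_a, ss_within=ss_w,
            var_among=var_a, var_within=var_w,
            pct_among=pct_among, pct_within=pct_within,
            fst=fst, p_value=p_value,
            n_permutations=n_permutations, seed=seed,
            populations=list(self.labels),
        )


def amova(g: GenotypeMatrix, n_permutations: int = 1000, seed: int | None = None) -> AmovaResult:
    """Functional wrapper: fit the two-level AMOVA on *g*."""
    return Amova(g).fit(n_permutations=n_permutations, seed=seed)


def pairwise_fst(
    g: GenotypeMatrix, n_permutations: int = 1000, seed: int | None = None,
    alpha: float = 0.05,
) -> PairwiseFstMatrix:
    """Each population pair analysed as a two-population AMOVA.

    Pairs involving a population with fewer than 2 individuals are flagged
    unreliable (Fst still reported, p-value NaN-safe)."""
    labels = g.population_labels
    sizes = g.population_sizes()
    k = len(labels)
    fst = np.zeros((k, k))
    pvals = np.full((k, k), np.nan)
    np.fill_diagonal(pvals, 1.0)
    unreliable = []
    ss = np.random.SeedSequence(seed).spawn(k * k)
    for i in range(k):
        for j in range(i + 1, k):
            sub = g.subset_populations([labels[i], labels[j]])
            res = Amova(sub).fit(
                n_permutations=n_permutations,
                seed=int(ss[i * k + j].generate_state(1)[0] % (2**31)),
            )
            fst[i, j] = fst[j, i] = res.fst
            pvals[i, j] = pvals[j, i] = res.p_value
            if sizes[labels[i]] < 2 or sizes[labels[j]] < 2:
                unreliable.append((labels[i], labels[j]))
    return PairwiseFstMatrix(labels=labels, fst=fst, p_values=pvals,
                             alpha=alpha, unreliable=unreliable)
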