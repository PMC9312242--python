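"""Lightweight admixture inference for multilocus codominant genotypes.

A Pritchard-style mixture model fitted by Gibbs sampling: each of an
individual's allele copies originates from one of K clusters; cluster k
carries its own allele-frequency vector per locus (independent across
clusters, uniform Dirichlet prior) and individual i has membership vector
q_i (Dirichlet prior with fixed admixture parameter alpha). The sampler
alternates

  1. z: origin of every allele copy given (Q, P),
  2. P: cluster allele frequencies given z (Dirichlet posterior),
  3. Q: memberships given z (Dirichlet posterior),

and reports posterior means of Q and P plus the per-sweep log-likelihood
log Pr(data | P, Q) with copy origins summed out, the quantity Evanno-style
model selection operates on. Deliberate simplifications relative to the
full admixture software: alpha is fixed (not sampled) and cluster allele
frequencies are uncorrelated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import MISSING, round_half_up
from .genotypes import GenotypeMatrix

__all__ = [
    "AdmixtureModel",
    "AdmixtureFit",
    "EvannoTable",
    "fit_admixture",
    "evanno_delta_k",
    "align_to_truth",
]


@dataclass
class AdmixtureFit:
    """Posterior-mean admixture estimates for one K."""

    K: int
    Q: np.ndarray  # (n_individuals, K) posterior-mean memberships
    P: list[np.ndarray]  # per locus: (K, n_alleles) posterior-mean frequencies
    mean_lnP: float
    lnP_trace: np.ndarray
    burnin: int
    n_iter: int
    seed: int | None
    individuals: list[str]
    populations: list[str]
    allele_codes: list[np.ndarray]

    def q_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.Q, columns=[f"q_{k + 1}" for k in range(self.K)])
        df.insert(0, "individual", self.individuals)
        df.insert(1, "population", self.populations)
        return df

    def summary(self) -> str:
        lines = [
            f"Admixture fit: K = {self.K}, {len(self.individuals)} individuals, "
            f"{len(self.P)} loci",
            f"burn-in {self.burnin}, {self.n_iter} sampling sweeps, seed {self.seed}",
            f"mean ln P(data | P, Q) = {round_half_up(self.mean_lnP, 2)}",
            "mean membership per predefined population:",
        ]
        df = self.q_dataframe()
        means = df.groupby("population", sort=False).mean(numeric_only=True)
        lines.append(means.round(3).to_string())
        return "\n".join(lines)


@dataclass
class EvannoTable:
    """Mean/SD of lnP per K with first/second differences and delta-K."""

    table: pd.DataFrame  # columns: K, mean_lnP, sd_lnP, n_runs, Lp, Lpp, delta_K
    best_K: int

    def summary(self) -> str:
        return (
            self.table.round(3).to_string(index=False)
            + f"\nbest K by delta-K: {self.best_K}"
        )


class AdmixtureModel:
    """Admixture mixture model over a genotype matrix for a fixed K.

    ``alpha`` is the symmetric Dirichlet admixture parameter. ``None``
    (default) samples it by a Metropolis step with a uniform prior on
    (0, 10], as the original software does — essential for crisp
    memberships when individuals are effectively unadmixed, since a fixed
    alpha = 1 bounds the posterior-mean self-membership well below 1.
    A fixed positive value is accepted for the simpler fixed-alpha variant.
    """

    def __init__(self, genotypes: GenotypeMatrix, K: int, alpha: float | None = None):
        if K < 1:
            raise ValueError("K must be >= 1")
        if K > genotypes.n_individuals:
            raise ValueError(
                f"K = {K} exceeds the number of individuals ({genotypes.n_individuals})"
            )
        if alpha is not None and alpha <= 0:
            raise ValueError("alpha must be positive (or None to sample it)")
        self.genotypes = genotypes
        self.K = K
        self.alpha = alpha
        self._prepare()

    def _prepare(self) -> None:
        g = self.genotypes
        ind_idx, slot_idx = [], []
        self._allele_codes: list[np.ndarray] = []
        self._locus_offsets = [0]
        offset = 0
        for j in range(g.n_loci):
            col = g.calls[:, j, :]
            called = np.flatnonzero(col[:, 0] != MISSING)
            alleles, inverse = np.unique(col[called].ravel(), return_inverse=True)
            self._allele_codes.append(alleles)
            ind_idx.append(np.repeat(called, 2))
            slot_idx.append(offset + inverse)
            offset += len(alleles)
            self._locus_offsets.append(offset)
        self._ind_idx = np.concatenate(ind_idx)
        self._slot_idx = np.concatenate(slot_idx)
        self._n_slots = offset

    def fit(
        self,
        burnin: int = 500,
        n_iter: int = 2000,
        seed: int | None = None,
        thin: int = 1,
    ) -> AdmixtureFit:
        """Run the Gibbs sampler; deterministic under a fixed seed.

        Defaults (burn-in 500, 2,000 sampling sweeps) are sized for
        datasets of a few hundred individuals and tens of loci, where the
        chain reaches its stationary regime within ~100 sweeps; pass larger
        values for weakly structured data.
        """
        if burnin < 1 or n_iter < 1:
            raise ValueError("burnin and n_iter must be >= 1")
        g, K = self.genotypes, self.K
        rng = np.random.default_rng(seed)
        N, C, S = g.n_individuals, len(self._ind_idx), self._n_slots
        ind_idx, slot_idx = self._ind_idx, self._slot_idx
        offsets = np.array(self._locus_offsets[:-1])
        seg_id = np.repeat(np.arange(g.n_loci), np.diff(self._locus_offsets))

        sample_alpha = self.alpha is None
        alpha = 1.0 if sample_alpha else float(self.alpha)
        Q = np.full((N, K), 1.0 / K)
        P = self._draw_p(rng, np.zeros((K, S)), seg_id)  # prior draw

        Q_sum = np.zeros_like(Q)
        P_sum = np.zeros((K, S))
        lnP_trace = []
        kept = 0

        for sweep in range(burnin + n_iter):
            # 1. copy-origin assignments
            probs = P[:, slot_idx].T * Q[ind_idx]  # (C, K)
            row_tot = probs.sum(axis=1)
            cs = np.cumsum(probs, axis=1)
            u = rng.random(C) * row_tot
            z = (cs < u[:, None]).sum(axis=1)
            # 2. cluster allele frequencies
            counts_p = np.bincount(z * S + slot_idx, minlength=K * S).reshape(K, S)
            P = self._draw_p(rng, counts_p, seg_id)
            # 3. memberships
            counts_q = np.bincount(ind_idx * K + z, minlength=N * K).reshape(N, K)
            # clip guards against gamma underflow to exact 0 at tiny alpha
            gam = np.clip(rng.gamma(counts_q + alpha), 1e-300, None)
            Q = gam / gam.sum(axis=1, keepdims=True)
            # 4. admixture parameter (Metropolis, uniform prior on (0, 10])
            if sample_alpha and K > 1:
                alpha = self._update_alpha(rng, alpha, Q)

            if sweep >= burnin and (sweep - burnin) % thin == 0:
                Q_sum += Q
                P_sum += P
                lnP_trace.append(float(np.log(row_tot).sum()))
                kept += 1

        P_mean = P_sum / kept
        P_per_locus = [
            P_mean[:, self._locus_offsets[j] : self._locus_offsets[j + 1]]
            for j in range(g.n_loci)
        ]
        P_per_locus = [p / p.sum(axis=1, keepdims=True) for p in P_per_locus]
        lnP_trace = np.array(lnP_trace)
        return AdmixtureFit(
            K=K,
            Q=Q_sum / kept,
            P=P_per_locus,
            mean_lnP=float(lnP_trace.mean()),
            lnP_trace=lnP_trace,
            burnin=burnin,
            n_iter=n_iter,
            seed=seed,
            individuals=list(g.individuals),
            populations=list(g.populations),
            allele_codes=self._allele_codes,
        )

    @staticmethod
    def _update_alpha(rng, alpha: float, Q: np.ndarray) -> float:
        from scipy.special import gammaln as _lg

        def logpost(a: float) -> float:
            n, k = Q.shape
            return n * (_lg(k * a) - k * _lg(a)) + (a - 1.0) * float(
                np.log(Q).sum()
            )

        prop = alpha + rng.normal(0.0, 0.1)
        if not (0.0 < prop <= 10.0):
            return alpha
        if np.log(rng.random()) < logpost(prop) - logpost(alpha):
            return prop
        return alpha

    def _draw_p(self, rng, counts: np.ndarray, seg_id: np.ndarray) -> np.ndarray:
        gam = rng.gamma(counts + 1.0)  # uniform Dirichlet prior
        seg_tot = np.zeros((counts.shape[0], self.genotypes.n_loci))
        np.add.at(seg_tot.T, seg_id, gam.T)
        return gam / seg_tot[:, seg_id]


def fit_admixture(
    g: GenotypeMatrix, K: int, burnin: int = 500, n_iter: int = 2000,
    seed: int | None = None, alpha: float | None = None,
) -> AdmixtureFit:
    """Functional wrapper around :class:`AdmixtureModel`."""
    return AdmixtureModel(g, K, alpha=alpha).fit(burnin=burnin, n_iter=n_iter, seed=seed)


def evanno_delta_k(runs: dict[int, list[float]]) -> EvannoTable:
    """Evanno-style model selection from per-run mean lnP values.

    delta-K(K) = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / SD(L(K)),
    defined for interior K with positive SD; best K is the argmax. Needs
    at least 3 consecutive K values with >= 2 runs each.
    """
    ks = sorted(runs)
    if len(ks) < 3 or ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("need >= 3 consecutive K values")
    for k in ks:
        if len(runs[k]) < 2:
            raise ValueError(f"K = {k} has fewer than 2 runs")
    means = {k: float(np.mean(runs[k])) for k in ks}
    sds = {k: float(np.std(runs[k], ddof=1)) for k in ks}
    rows = []
    for k in ks:
        lp = means[k] - means[k - 1] if k > ks[0] else np.nan
        lpp = (
            means[k + 1] - 2 * means[k] + means[k - 1]
            if ks[0] < k < ks[-1] else np.nan
        )
        if not np.isnan(lpp) and sds[k] > 0:
            dk = abs(lpp) / sds[k]
        else:
            dk = np.nan  # flagged undefined (zero SD or boundary K)
        rows.append((k, means[k], sds[k], len(runs[k]), lp, lpp, dk))
    table = pd.DataFrame(
        rows, columns=["K", "mean_lnP", "sd_lnP", "n_runs", "Lp", "Lpp", "delta_K"]
    )
    if table["delta_K"].notna().sum() == 0:
        raise ValueError("delta-K undefined at every interior K (zero SD?)")
    best_K = int(table.loc[table["delta_K"].idxmax(), "K"])
    return EvannoTable(table=table, best_K=best_K)


def align_to_truth(Q: np.ndarray, true_labels: np.ndarray) -> np.ndarray:
    """Permute Q's columns to best match integer truth labels (0..K-1).

    Resolves label switching before any accuracy statement: chooses the
    column permutation maximising total self-membership.
    """
    from itertools import permutations

    K = Q.shape[1]
    best, best_score = None, -np.inf
    for perm in permutations(range(K)):
        score = sum(
            Q[true_labels == k, perm[k]].sum() for k in range(min(K, true_labels.max() + 1))
        )
        if score > best_score:
            best, best_score = perm, score
    return Q[:, list(best)]
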