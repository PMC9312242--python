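"""Independent brute-force oracles used only by the test suite.

Each oracle recomputes a quantity by the most direct route available
(naive scans, full enumeration, explicit distance matrices) so it shares
no code path with the implementation it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def primitive(motif: str) -> bool:
    p = len(motif)
    return not any(
        p % d == 0 and motif == motif[:d] * (p // d) for d in range(1, p)
    )


def brute_find_ssrs(seq: str, thresholds: dict[int, int]) -> set[tuple[int, int, str]]:
    """O(n * period * tract) scan over every start position and period."""
    seq = seq.upper()
    n = len(seq)
    ok = set("ACGT")
    out = set()
    for p, thr in thresholds.items():
        for s in range(n):
            # only maximal runs: position s-1 must not extend the match track
            if (
                s >= 1
                and s - 1 + p < n
                and seq[s - 1] in ok
                and seq[s - 1 + p] in ok
                and seq[s - 1] == seq[s - 1 + p]
            ):
                continue
            length = 0
            while (
                s + length + p < n
                and seq[s + length] in ok
                and seq[s + length + p] in ok
                and seq[s + length] == seq[s + length + p]
            ):
                length += 1
            if length == 0:
                continue
            reps = (length + p) // p
            motif = seq[s : s + p]
            if reps >= thr and primitive(motif):
                out.add((s, s + p * reps, motif))
    return out


def brute_canonical(motif: str) -> str:
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    rc = "".join(comp[b] for b in reversed(motif))
    rotations = [m[i:] + m[:i] for m in (motif, rc) for i in range(len(m))]
    return min(rotations)


# SantaLucia (1998) unified parameters, re-entered independently as
# (dH kcal/mol, dS cal/mol/K) per propagation step 5'-XY-3'.
_NN_TABLE = [
    ("AA", -7.9, -22.2), ("AT", -7.2, -20.4), ("TA", -7.2, -21.3),
    ("CA", -8.5, -22.7), ("GT", -8.4, -22.4), ("CT", -7.8, -21.0),
    ("GA", -8.2, -22.2), ("CG", -10.6, -27.2), ("GC", -9.8, -24.4),
    ("GG", -8.0, -19.9),
]


def nn_tm_oracle(seq: str, na_mM: float = 50.0, oligo_uM: float = 0.25) -> float:
    """Hand-summed NN Tm: look up each step (or its reverse complement)."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    table = {}
    for step, dh, ds in _NN_TABLE:
        table[step] = (dh, ds)
        rc = "".join(comp[b] for b in reversed(step))
        table.setdefault(rc, (dh, ds))
    dh_sum, ds_sum = 0.0, 0.0
    for i in range(len(seq) - 1):
        dh, ds = table[seq[i : i + 2]]
        dh_sum += dh
        ds_sum += ds
    for end in (seq[0], seq[-1]):
        if end in "GC":
            dh_sum += 0.1
            ds_sum += -2.8
        else:
            dh_sum += 2.3
            ds_sum += 4.1
    rc_full = "".join(comp[b] for b in reversed(seq))
    ct = oligo_uM * 1e-6
    if seq == rc_full:
        ds_sum += -1.4
    else:
        ct /= 4.0
    ds_sum += 0.368 * (len(seq) - 1) * math.log(na_mM / 1000.0)
    return 1000.0 * dh_sum / (ds_sum + 1.9872 * math.log(ct)) - 273.15


def pic_double_loop(p) -> float:
    p = list(p)
    total = 1.0 - sum(x * x for x in p)
    for i in range(len(p)):
        for j in range(i + 1, len(p)):
            total -= 2.0 * p[i] ** 2 * p[j] ** 2
    return total


def hwe_exact_enum_biallelic(n11: int, n12: int, n22: int) -> float:
    """Full-enumeration exact HWE p for a biallelic locus (Levene)."""
    n = n11 + n12 + n22
    n1 = 2 * n11 + n12

    def logprob(h: int) -> float:
        a = (n1 - h) // 2
        b = n - a - h
        return (
            math.lgamma(n + 1)
            - math.lgamma(a + 1) - math.lgamma(h + 1) - math.lgamma(b + 1)
            + h * math.log(2.0)
            + math.lgamma(n1 + 1) + math.lgamma(2 * n - n1 + 1)
            - math.lgamma(2 * n + 1)
        )

    hs = [h for h in range(n1 % 2, min(n1, 2 * n - n1) + 1, 2)]
    probs = {h: math.exp(logprob(h)) for h in hs}
    obs = probs[n12]
    return sum(p for p in probs.values() if p <= obs * (1 + 1e-12))


def amova_from_distances(calls: np.ndarray, pops: np.ndarray):
    """Copy-level AMOVA via the explicit pairwise mismatch-distance matrix.

    calls: (N, L, 2) with -1 missing; pops: integer labels per individual.
    Returns (ss_among, ss_within, var_among, var_within, fst).
    """
    n, L, _ = calls.shape
    copies = []  # (individual, allele-vector with None for missing)
    for i in range(n):
        for c in range(2):
            copies.append((i, [None if calls[i, j, 0] == -1 else calls[i, j, c] for j in range(L)]))
    m = len(copies)

    def dist(a, b) -> float:
        return sum(
            1.0
            for x, y in zip(a[1], b[1])
            if x is not None and y is not None and x != y
        )

    d = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            d[i, j] = d[j, i] = dist(copies[i], copies[j])

    grp = np.array([pops[ind] for ind, _ in copies])
    labels = np.unique(grp)
    ss_total = d[np.triu_indices(m, 1)].sum() / m
    ss_within = 0.0
    for k in labels:
        idx = np.flatnonzero(grp == k)
        sub = d[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_among = ss_total - ss_within
    n_pops = len(labels)
    sizes = np.array([(grp == k).sum() for k in labels], dtype=float)
    df_among, df_within = n_pops - 1, m - n_pops
    n_prime = (m - (sizes**2).sum() / m) / df_among
    var_within = ss_within / df_within
    var_among = (ss_among / df_among - var_within) / n_prime
    fst = var_among / (var_among + var_within)
    return ss_among, ss_within, var_among, var_within, fst


def random_ultrametric(labels: list[str], rng: np.random.Generator):
    """Random ultrametric distance matrix built from a random merge order."""
    clusters = [[l] for l in labels]
    heights = []
    h = 0.0
    merges = []
    while len(clusters) > 1:
        h += float(rng.uniform(0.05, 1.0))
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        merges.append((list(clusters[i]), list(clusters[j]), h))
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
        heights.append(h)
    n = len(labels)
    ix = {l: i for i, l in enumerate(labels)}
    d = np.zeros((n, n))
    for left, right, h in merges:
        for a in left:
            for b in right:
                d[ix[a], ix[b]] = d[ix[b], ix[a]] = 2.0 * h
    return d
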