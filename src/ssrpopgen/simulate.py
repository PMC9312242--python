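"""Synthetic test data: planted-SSR genomes and island-model genotypes.

Two generators back the whole pipeline without any external download:

* :func:`simulate_genome` plants perfect SSR tracts (and optional PCR
  amplicons) at known coordinates in random background sequence, returning
  the truth table alongside the FASTA records.
* :func:`simulate_genotypes` draws multi-population diploid genotypes under
  the Balding-Nichols island model: population allele frequencies are
  Dirichlet-distributed around ancestral frequencies with concentration
  (1-F)/F, giving expected differentiation F; individuals are two
  independent copies per locus (Hardy-Weinberg within populations).

Defaults mirror a typical four-population perch microsatellite survey:
sample sizes 34/77/68/89, 29 multiallelic loci, moderate differentiation
(F = 0.074), allele codes on tetranucleotide fragment-size ladders in the
86-265 bp range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import MISSING
from .genotypes import GenotypeMatrix
from .mining import SSRThresholds, find_ssrs
from .screening import PrimerPair, _revcomp

__all__ = [
    "PlantedSSR",
    "PlantedAmplicon",
    "PlantedGenomeSpec",
    "IslandModelSpec",
    "simulate_genome",
    "simulate_genotypes",
]


@dataclass(frozen=True)
class PlantedSSR:
    motif: str
    n_repeats: int
    seq_index: int = 0
    position: int | None = None  # None -> placed at random


@dataclass(frozen=True)
class PlantedAmplicon:
    pair: PrimerPair
    product_len: int
    seq_index: int = 0
    position: int | None = None


@dataclass
class PlantedGenomeSpec:
    n_sequences: int = 1
    lengths: list[int] = field(default_factory=lambda: [10_000])
    gc: float = 0.41
    ssrs: list[PlantedSSR] = field(default_factory=list)
    amplicons: list[PlantedAmplicon] = field(default_factory=list)
    seed: int = 0


@dataclass
class IslandModelSpec:
    pop_sizes: dict[str, int] = field(
        default_factory=lambda: {"KR": 34, "WR": 77, "JL": 68, "WL": 89}
    )
    n_loci: int = 29
    n_alleles: int | list[int] = 12
    f_by_pop: float | dict[str, float] = 0.074
    missing_rate: float = 0.02
    seed: int = 0


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=p)


def simulate_genome(
    spec: PlantedGenomeSpec, max_tries: int = 50
) -> tuple[dict[str, str], pd.DataFrame]:
    """Generate FASTA records with planted features and their truth table.

    Background bases are i.i.d. at the requested GC. Around every planted
    feature (within two motif periods) the background is rejection-checked:
    if an accidental SSR meeting the default thresholds touches that
    neighbourhood, the sequence is redrawn. Infeasible packing raises,
    never silently truncates.
    """
    if len(spec.lengths) != spec.n_sequences:
        raise ValueError("one length per sequence required")
    rng = np.random.default_rng(spec.seed)
    thresholds = SSRThresholds()

    # features per sequence with concrete inserts
    inserts: list[list[tuple[int | None, str, str, dict]]] = [
        [] for _ in range(spec.n_sequences)
    ]
    for s in spec.ssrs:
        inserts[s.seq_index].append(
            (s.position, s.motif.upper() * s.n_repeats, "ssr",
             {"motif": s.motif.upper(), "n_repeats": s.n_repeats})
        )
    for a in spec.amplicons:
        fwd, rev = a.pair.forward.upper(), a.pair.reverse.upper()
        filler_len = a.product_len - len(fwd) - len(rev)
        if filler_len < 0:
            raise ValueError(
                f"amplicon for {a.pair.locus_id} shorter than its primers"
            )
        filler = "".join(
            chr(c) for c in _random_seq(rng, filler_len, spec.gc)
        )
        inserts[a.seq_index].append(
            (a.position, fwd + filler + _revcomp(rev), "amplicon",
             {"locus_id": a.pair.locus_id, "product_len": a.product_len})
        )

    records: dict[str, str] = {}
    truth_rows = []
    for si in range(spec.n_sequences):
        length = spec.lengths[si]
        seq_id = f"chr{si + 1}"
        feats = inserts[si]
        total_feat = sum(len(txt) for _, txt, _, _ in feats)
        if total_feat > length:
            raise ValueError(
                f"sequence {seq_id}: planted features ({total_feat} bp) exceed "
                f"length {length}"
            )
        placed = None
        for _ in range(max_tries):
            seq, placed = _try_place(rng, length, spec.gc, feats)
            if seq is None:
                continue
            if _clean_neighbourhoods(seq, placed, thresholds):
                break
            placed = None
        else:
            placed = None
        if placed is None:
            raise ValueError(
                f"sequence {seq_id}: could not pack {len(feats)} features into "
                f"{length} bp without accidental repeats (after {max_tries} tries)"
            )
        records[seq_id] = seq
        for (start, text, kind, meta) in placed:
            truth_rows.append(
                {"seq_id": seq_id, "start": start, "end": start + len(text),
                 "kind": kind, **meta}
            )
    truth = pd.DataFrame(
        truth_rows,
        columns=["seq_id", "start", "end", "kind", "motif", "n_repeats",
                 "locus_id", "product_len"],
    )
    return records, truth


def _try_place(rng, length, gc, feats):
    background = _random_seq(rng, length, gc)
    seq = bytearray(background.tobytes())
    occupied: list[tuple[int, int]] = []
    placed = []
    for (pos, text, kind, meta) in feats:
        L = len(text)
        margin = 2 * (len(meta.get("motif", "")) or 10)
        if pos is None:
            ok = None
            for _ in range(200):
                cand = int(rng.integers(0, max(1, length - L + 1)))
                if all(
                    cand + L + margin <= s or cand >= e + margin
                    for s, e in occupied
                ):
                    ok = cand
                    break
            if ok is None:
                return None, None
            pos = ok
        else:
            if pos + L > length:
                raise ValueError(f"feature at {pos} exceeds sequence length {length}")
            if any(pos < e and s < pos + L for s, e in occupied):
                raise ValueError(f"planted features overlap at {pos}")
        seq[pos : pos + L] = text.encode()
        occupied.append((pos, pos + L))
        placed.append((pos, text, kind, meta))
    return seq.decode(), placed


def _clean_neighbourhoods(seq, placed, thresholds) -> bool:
    """True when no accidental SSR touches any feature's +/- 2-period margin."""
    found = find_ssrs(seq, "check", thresholds)
    truth_spans = []
    for (start, text, kind, meta) in placed:
        margin = 2 * (len(meta.get("motif", "")) or 10)
        truth_spans.append((start - margin, start + len(text) + margin, start,
                            start + len(text), kind))
    for locus in found:
        for (lo, hi, t_start, t_end, kind) in truth_spans:
            if locus.start < hi and lo < locus.end:
                if kind == "ssr" and locus.start == t_start and locus.end == t_end:
                    continue  # the planted tract itself
                return False
    return True


def simulate_genotypes(
    spec: IslandModelSpec,
) -> tuple[GenotypeMatrix, dict]:
    """Balding-Nichols genotypes plus a truth dict.

    Truth holds the ancestral and per-population allele frequencies, the F
    parameters and the allele fragment-size codes per locus. F = 0 means
    every population uses the ancestral frequencies exactly (no Dirichlet
    draw), the null of no differentiation.
    """
    rng = np.random.default_rng(spec.seed)
    pops = list(spec.pop_sizes)
    n_alleles = (
        [spec.n_alleles] * spec.n_loci
        if isinstance(spec.n_alleles, int) else list(spec.n_alleles)
    )
    if len(n_alleles) != spec.n_loci:
        raise ValueError("one allele count per locus required")
    if any(a < 1 for a in n_alleles):
        raise ValueError("allele counts must be >= 1")
    f_of = (
        {p: spec.f_by_pop for p in pops}
        if isinstance(spec.f_by_pop, (int, float)) else dict(spec.f_by_pop)
    )
    if any(not (0 <= f < 1) for f in f_of.values()):
        raise ValueError("F must be in [0, 1)")

    loci = [f"LOC{j + 1:03d}" for j in range(spec.n_loci)]
    ancestral, pop_freqs, codes = [], {p: [] for p in pops}, []
    for j in range(spec.n_loci):
        k = n_alleles[j]
        anc = rng.dirichlet(np.ones(k))
        ancestral.append(anc)
        # tetranucleotide-like fragment-size ladder within 86-265 bp
        base = int(rng.integers(86, max(87, 266 - 4 * (k - 1))))
        codes.append(base + 4 * np.arange(k))
        for p in pops:
            f = f_of[p]
            if f == 0:
                pop_freqs[p].append(anc.copy())
            else:
                pop_freqs[p].append(rng.dirichlet(anc * (1 - f) / f))

    individuals, populations, blocks = [], [], []
    for p in pops:
        n_ind = spec.pop_sizes[p]
        individuals.extend(f"{p}_{i + 1:03d}" for i in range(n_ind))
        populations.extend([p] * n_ind)
        block = np.empty((n_ind, spec.n_loci, 2), dtype=np.int64)
        for j in range(spec.n_loci):
            draws = rng.choice(codes[j], size=(n_ind, 2), p=pop_freqs[p][j])
            block[:, j, :] = draws
        blocks.append(block)
    calls = np.concatenate(blocks, axis=0)
    if spec.missing_rate > 0:
        mask = rng.random(calls.shape[:2]) < spec.missing_rate
        calls[mask] = MISSING

    g = GenotypeMatrix(individuals, populations, loci, calls)
    truth = {
        "ancestral_freqs": ancestral,
        "pop_freqs": pop_freqs,
        "allele_codes": codes,
        "f_by_pop": f_of,
        "loci": loci,
    }
    return g, truth
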