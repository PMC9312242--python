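"""Perfect microsatellite (SSR) detection and motif-class summaries.

A microsatellite is a tandem repeat of a short motif (here 2-5 bp). Motifs
are grouped into canonical classes under cyclic rotation and reverse
complementation, the convention used by genome-wide SSR surveys: GT, TG, CA
and AC are all one (AC)n class, because a repeat tract can be read from
either strand and from any phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SSRThresholds",
    "SSRLocus",
    "MotifSummary",
    "canonical_motif",
    "find_ssrs",
    "summarize_ssrs",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class SSRThresholds:
    """Minimum repeat counts per motif period.

    Defaults follow the common survey criterion read inclusively: at least
    5 dinucleotide, 4 trinucleotide, 3 tetranucleotide and 2 pentanucleotide
    copies.
    """

    min_repeats_by_period: dict[int, int] = field(
        default_factory=lambda: {2: 5, 3: 4, 4: 3, 5: 2}
    )

    def __post_init__(self) -> None:
        for period, thr in self.min_repeats_by_period.items():
            if period < 1 or period > 6:
                raise ValueError(f"unsupported motif period {period}")
            if thr < 2:
                raise ValueError(f"threshold for period {period} must be >= 2, got {thr}")

    @property
    def periods(self) -> list[int]:
        return sorted(self.min_repeats_by_period)


@dataclass(frozen=True)
class SSRLocus:
    """One perfect microsatellite tract.

    Coordinates are 0-based half-open; ``end - start == period * n_repeats``.
    The motif is primitive (not itself a repetition of a shorter motif).
    """

    seq_id: str
    start: int
    end: int
    motif: str
    canonical: str
    n_repeats: int

    @property
    def period(self) -> int:
        return len(self.motif)

    @property
    def tract_length(self) -> int:
        return self.end - self.start


@dataclass
class MotifSummary:
    """Counts and proportions of SSR loci per canonical motif class."""

    table: pd.DataFrame  # columns: period, canonical, count, prop_in_period, prop_total
    period_totals: pd.Series  # index period -> count

    @property
    def n_loci(self) -> int:
        return int(self.table["count"].sum())


def _reverse_complement(motif: str) -> str:
    return motif.translate(_COMPLEMENT)[::-1]


def canonical_motif(motif: str) -> str:
    """Canonical representative of *motif* under rotation + reverse complement.

    Returns the lexicographically smallest string among all cyclic rotations
    of the motif and of its reverse complement. Idempotent by construction.
    """
    motif = motif.upper()
    if not motif or any(b not in "ACGT" for b in motif):
        raise ValueError(f"motif must be non-empty over ACGT, got {motif!r}")
    if len(motif) > 6:
        raise ValueError(f"motif longer than 6 bp: {motif!r}")
    candidates = []
    for s in (motif, _reverse_complement(motif)):
        doubled = s + s
        candidates.extend(doubled[i : i + len(s)] for i in range(len(s)))
    return min(candidates)


def is_primitive(motif: str) -> bool:
    """True if *motif* is not a whole-number repetition of a shorter motif."""
    p = len(motif)
    for d in range(1, p):
        if p % d == 0 and motif == motif[:d] * (p // d):
            return False
    return True


def find_ssrs(
    sequence: str,
    seq_id: str = "seq",
    thresholds: SSRThresholds | None = None,
) -> list[SSRLocus]:
    """Detect maximal perfect SSR tracts in *sequence*.

    A tract is reported when its whole-copy repeat count meets the period's
    threshold; it cannot be extended by a further motif copy on either side.
    N (or any non-ACGT base) terminates a run; soft-masked lowercase is
    uppercased first. A tract whose motif has a smaller primitive period
    (e.g. ATAT) is reported only at that smaller period.
    """
    thresholds = thresholds or SSRThresholds()
    seq = sequence.upper()
    n = len(seq)
    loci: list[SSRLocus] = []
    if n == 0:
        return loci

    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    valid = (arr == ord("A")) | (arr == ord("C")) | (arr == ord("G")) | (arr == ord("T"))

    for period in thresholds.periods:
        if n < 2 * period:
            continue
        thr = thresholds.min_repeats_by_period[period]
        match = (arr[:-period] == arr[period:]) & valid[:-period] & valid[period:]
        # run-length encode the boolean match track
        padded = np.concatenate(([False], match, [False]))
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        for run_start, run_end in zip(edges[::2], edges[1::2]):
            tract_len = (run_end - run_start) + period
            n_rep = tract_len // period
            if n_rep < thr:
                continue
            motif = seq[run_start : run_start + period]
            if not is_primitive(motif):
                continue  # found at its smaller primitive period instead
            loci.append(
                SSRLocus(
                    seq_id=seq_id,
                    start=int(run_start),
                    end=int(run_start + period * n_rep),
                    motif=motif,
                    canonical=canonical_motif(motif),
                    n_repeats=int(n_rep),
                )
            )

    loci.sort(key=lambda l: (l.start, l.period))
    return loci


def summarize_ssrs(loci: list[SSRLocus]) -> MotifSummary:
    """Tabulate loci per canonical motif class with within-period proportions."""
    if not loci:
        empty = pd.DataFrame(
            columns=["period", "canonical", "count", "prop_in_period", "prop_total"]
        )
        return MotifSummary(table=empty, period_totals=pd.Series(dtype=int))

    df = pd.DataFrame(
        {"period": [l.period for l in loci], "canonical": [l.canonical for l in loci]}
    )
    counts = (
        df.groupby(["period", "canonical"]).size().rename("count").reset_index()
    )
    period_totals = counts.groupby("period")["count"].sum()
    counts["prop_in_period"] = counts.apply(
        lambda r: r["count"] / period_totals[r["period"]], axis=1
    )
    counts["prop_total"] = counts["count"] / len(loci)
    counts = counts.sort_values(
        ["period", "count", "canonical"], ascending=[True, False, True]
    ).reset_index(drop=True)
    return MotifSummary(table=counts, period_totals=period_totals)


def summary_from_counts(counts_by_motif: dict[str, int]) -> MotifSummary:
    """Build a MotifSummary directly from per-motif locus counts.

    Convenience for re-analysing published count tables without the
    underlying loci.
    """
    loci = []
    for motif, count in counts_by_motif.items():
        can = canonical_motif(motif)
        loci.extend(
            SSRLocus("tabulated", 0, len(motif), motif, can, 1) for _ in range(count)
        )
    return summarize_ssrs(loci)


def ssrs_to_dataframe(loci: list[SSRLocus]) -> pd.DataFrame:
    """Loci as a table with 1-based inclusive coordinates (for TSV export)."""
    return pd.DataFrame(
        {
            "seq_id": [l.seq_id for l in loci],
            "start": [l.start + 1 for l in loci],
            "end": [l.end for l in loci],
            "period": [l.period for l in loci],
            "motif": [l.motif for l in loci],
            "canonical_motif": [l.canonical for l in loci],
            "n_repeats": [l.n_repeats for l in loci],
            "tract_length": [l.tract_length for l in loci],
        }
    )
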