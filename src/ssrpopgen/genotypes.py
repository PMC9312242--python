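"""Codominant diploid genotype container and GenePop / long-TSV I/O.

Genotypes are unordered pairs of positive integer allele codes
(conventionally PCR fragment sizes in bp) per individual and locus, with an
explicit missing state. All downstream statistics work from this container.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import MISSING

__all__ = [
    "GenotypeMatrix",
    "AlleleFrequencyTable",
    "GenePopError",
    "read_genepop",
    "write_genepop",
    "read_long_tsv",
    "write_long_tsv",
    "allele_freqs",
]

ALL = "ALL"  # pseudo-population pooling every individual


class GenePopError(ValueError):
    """Malformed GenePop input; message names the offending line."""


@dataclass
class GenotypeMatrix:
    """Individuals x loci diploid genotype matrix.

    ``calls`` has shape (n_individuals, n_loci, 2) with allele codes > 0 and
    ``MISSING`` (-1) marking both slots of an absent genotype. Allele order
    within a genotype carries no meaning.
    """

    individuals: list[str]
    populations: list[str]  # label per individual, parallel to `individuals`
    loci: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int64)
        n, l = len(self.individuals), len(self.loci)
        if len(self.populations) != n:
            raise ValueError("one population label per individual required")
        if self.calls.shape != (n, l, 2):
            raise ValueError(
                f"calls shape {self.calls.shape} != ({n}, {l}, 2)"
            )
        bad = (self.calls <= 0) & (self.calls != MISSING)
        if bad.any():
            raise ValueError("allele codes must be positive (or MISSING)")
        half = (self.calls == MISSING).sum(axis=2)
        if np.any((half != 0) & (half != 2)):
            raise ValueError("a genotype is missing as a whole, never one allele")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def population_labels(self) -> list[str]:
        """Unique population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p)
        return list(seen)

    def population_sizes(self) -> dict[str, int]:
        sizes: dict[str, int] = {p: 0 for p in self.population_labels}
        for p in self.populations:
            sizes[p] += 1
        return sizes

    def pop_indices(self, label: str) -> np.ndarray:
        if label == ALL:
            return np.arange(self.n_individuals)
        idx = np.flatnonzero(np.asarray(self.populations, dtype=object) == label)
        if idx.size == 0:
            raise KeyError(f"unknown population {label!r}")
        return idx

    def subset_populations(self, labels: list[str]) -> "GenotypeMatrix":
        keep = np.concatenate([self.pop_indices(p) for p in labels])
        keep.sort()
        return GenotypeMatrix(
            individuals=[self.individuals[i] for i in keep],
            populations=[self.populations[i] for i in keep],
            loci=list(self.loci),
            calls=self.calls[keep].copy(),
        )

    def missing_mask(self) -> np.ndarray:
        """(n_individuals, n_loci) boolean, True where the genotype is missing."""
        return self.calls[:, :, 0] == MISSING


@dataclass
class AlleleFrequencyTable:
    """Per-locus allele relative frequencies for one (pooled) population.

    ``freqs[locus]`` maps allele code -> frequency; ``n[locus]`` is the
    number of diploid individuals with a non-missing call (so 2n allele
    copies were counted). Loci with no data are present with empty maps and
    n = 0, flagged via :attr:`empty_loci`.
    """

    population: str
    freqs: dict[str, dict[int, float]]
    n: dict[str, int]

    @property
    def empty_loci(self) -> list[str]:
        return [loc for loc, nn in self.n.items() if nn == 0]


def allele_freqs(g: GenotypeMatrix, pool: str = ALL) -> AlleleFrequencyTable:
    """Allele frequencies over the 2n non-missing copies per locus."""
    idx = g.pop_indices(pool)
    freqs: dict[str, dict[int, float]] = {}
    n: dict[str, int] = {}
    for j, locus in enumerate(g.loci):
        col = g.calls[idx, j, :]
        called = col[col[:, 0] != MISSING]
        n[locus] = int(called.shape[0])
        if called.shape[0] == 0:
            freqs[locus] = {}
            continue
        alleles, counts = np.unique(called.ravel(), return_counts=True)
        total = counts.sum()
        freqs[locus] = {int(a): float(c) / total for a, c in zip(alleles, counts)}
    return AlleleFrequencyTable(population=pool, freqs=freqs, n=n)


# ---------------------------------------------------------------------------
# GenePop format


def read_genepop(path: str) -> GenotypeMatrix:
    """Parse a GenePop 4.x file (2- or 3-digit alleles, 000 = missing).

    Populations are separated by lines reading ``Pop`` (case-insensitive)
    and named after their first individual's label.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise GenePopError("empty GenePop file")

    # line 1: title; then locus names until the first Pop line
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        line = lines[i].strip()
        if line:
            # locus names may be comma-separated on one line
            loci.extend(x.strip() for x in line.split(",") if x.strip())
        i += 1
    if not loci:
        raise GenePopError(f"no locus names before first Pop (line {i + 1})")

    individuals: list[str] = []
    populations: list[str] = []
    rows: list[list[tuple[int, int]]] = []
    pop_first_label: str | None = None
    pop_ordinal = 0
    digits: int | None = None

    for lineno in range(i, len(lines)):
        raw = lines[lineno]
        line = raw.strip()
        if not line:
            continue
        if line.lower() == "pop":
            pop_ordinal += 1
            pop_first_label = None
            continue
        if pop_ordinal == 0:
            raise GenePopError(f"genotype row before first Pop at line {lineno + 1}")
        if "," not in line:
            raise GenePopError(f"missing ',' after individual id at line {lineno + 1}")
        ind_id, geno_part = line.split(",", 1)
        ind_id = ind_id.strip()
        tokens = geno_part.split()
        if len(tokens) != len(loci):
            raise GenePopError(
                f"line {lineno + 1}: {len(tokens)} genotypes for {len(loci)} loci"
            )
        row: list[tuple[int, int]] = []
        for tok in tokens:
            if digits is None:
                if len(tok) == 4:
                    digits = 2
                elif len(tok) == 6:
                    digits = 3
                else:
                    raise GenePopError(
                        f"line {lineno + 1}: genotype {tok!r} is neither 4 nor 6 digits"
                    )
            if len(tok) != 2 * digits or not tok.isdigit():
                raise GenePopError(
                    f"line {lineno + 1}: bad genotype token {tok!r} "
                    f"(expected {2 * digits} digits)"
                )
            a, b = int(tok[:digits]), int(tok[digits:])
            if a == 0 and b == 0:
                row.append((MISSING, MISSING))
            elif a == 0 or b == 0:
                raise GenePopError(
                    f"line {lineno + 1}: half-missing genotype {tok!r}"
                )
            else:
                row.append((a, b))
        if pop_first_label is None:
            pop_first_label = ind_id or f"pop{pop_ordinal}"
        individuals.append(ind_id)
        populations.append(pop_first_label)
        rows.append(row)

    if not rows:
        raise GenePopError("no genotype rows found")
    calls = np.array(rows, dtype=np.int64)
    return GenotypeMatrix(individuals, populations, loci, calls)


def write_genepop(g: GenotypeMatrix, path: str, title: str = "ssrpopgen export") -> None:
    """Write GenePop with 3-digit encoding (codes <= 999 stored verbatim).

    Codes above 999 are re-mapped to per-locus rank codes, with the lookup
    recorded in the title line so the mapping is not silently lost.
    """
    max_code = int(g.calls.max(initial=0))
    remap_note = ""
    calls = g.calls
    if max_code > 999:
        calls = g.calls.copy()
        for j in range(g.n_loci):
            col = calls[:, j, :]
            alleles = np.unique(col[col != MISSING])
            lut = {int(a): r + 1 for r, a in enumerate(alleles)}
            for a, r in lut.items():
                col[g.calls[:, j, :] == a] = r
        remap_note = " (allele codes rank-remapped; original codes exceeded 999)"

    out = [title + remap_note]
    out.extend(g.loci)
    prev_pop = None
    for i, ind in enumerate(g.individuals):
        if g.populations[i] != prev_pop:
            out.append("Pop")
            prev_pop = g.populations[i]
        toks = []
        for j in range(g.n_loci):
            a, b = calls[i, j]
            if a == MISSING:
                toks.append("000000")
            else:
                toks.append(f"{a:03d}{b:03d}")
        out.append(f"{ind} ,  " + " ".join(toks))
    from ._util import atomic_write_text

    atomic_write_text(path, "\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# long-format TSV


def write_long_tsv(g: GenotypeMatrix, path: str) -> None:
    rows = []
    for i, ind in enumerate(g.individuals):
        for j, locus in enumerate(g.loci):
            a, b = g.calls[i, j]
            rows.append(
                (ind, g.populations[i], locus,
                 "" if a == MISSING else int(a), "" if b == MISSING else int(b))
            )
    df = pd.DataFrame(rows, columns=["individual", "population", "locus", "allele1", "allele2"])
    df.to_csv(path, sep="\t", index=False)


def read_long_tsv(path: str) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"individual": str, "population": str, "locus": str})
    individuals = list(dict.fromkeys(df["individual"]))
    loci = list(dict.fromkeys(df["locus"]))
    pop_of = dict(zip(df["individual"], df["population"]))
    ind_ix = {x: i for i, x in enumerate(individuals)}
    loc_ix = {x: j for j, x in enumerate(loci)}
    calls = np.full((len(individuals), len(loci), 2), MISSING, dtype=np.int64)
    for _, r in df.iterrows():
        a1, a2 = r["allele1"], r["allele2"]
        if pd.notna(a1) and str(a1) != "":
            calls[ind_ix[r["individual"]], loc_ix[r["locus"]]] = (int(a1), int(a2))
    populations = [pop_of[x] for x in individuals]
    return GenotypeMatrix(individuals, populations, loci, calls)
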