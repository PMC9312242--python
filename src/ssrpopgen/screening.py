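"""Primer-pair screening against design constraint windows.

Primer design itself is out of scope; candidates are screened against the
windows a typical microsatellite-marker study imposes: product size 50-500
bp, primer length 18-30 nt, melting temperature 52-65 degC. The melting
temperature uses the SantaLucia (1998) unified nearest-neighbor model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .mining import SSRLocus

__all__ = [
    "PrimerPair",
    "ScreenConstraints",
    "ScreenReport",
    "extract_flanks",
    "melting_temp",
    "screen_primer_pair",
    "in_silico_pcr",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# SantaLucia (1998) unified NN parameters: dH (kcal/mol), dS (cal/mol/K)
_NN = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
# duplex initiation at a terminal G.C / A.T pair
_INIT_GC = (0.1, -2.8)
_INIT_AT = (2.3, 4.1)
_SYMMETRY_DS = -1.4
_R = 1.9872  # gas constant, cal/mol/K


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse primer pair, both written 5'->3'.

    The reverse primer is the reverse-strand oligo, so its binding site on
    the plus strand is the reverse complement of ``reverse``.
    """

    locus_id: str
    forward: str
    reverse: str
    predicted_product_len: int | None = None

    def __post_init__(self) -> None:
        for name, seq in (("forward", self.forward), ("reverse", self.reverse)):
            if not seq or any(b not in "ACGT" for b in seq.upper()):
                raise ValueError(
                    f"{name} primer of {self.locus_id} must be plain ACGT "
                    f"(degenerate bases are rejected): {seq!r}"
                )


@dataclass(frozen=True)
class ScreenConstraints:
    product_len_range: tuple[int, int] = (50, 500)
    primer_len_range: tuple[int, int] = (18, 30)
    tm_range: tuple[float, float] = (52.0, 65.0)

    def __post_init__(self) -> None:
        for lo, hi in (self.product_len_range, self.primer_len_range, self.tm_range):
            if lo > hi:
                raise ValueError(f"empty constraint window [{lo}, {hi}]")


@dataclass
class ScreenReport:
    locus_id: str
    passed: bool
    violations: list[str]
    tm_forward: float
    tm_reverse: float


def extract_flanks(
    records: dict[str, str], locus: SSRLocus, flank_len: int
) -> tuple[str, str, str]:
    """Return (left flank, repeat tract, right flank) around *locus*.

    Flanks are truncated at sequence ends; the three parts concatenate to
    the genomic slice they came from.
    """
    if flank_len < 0:
        raise ValueError("flank_len must be >= 0")
    if locus.seq_id not in records:
        raise KeyError(f"sequence {locus.seq_id!r} not in record set")
    seq = records[locus.seq_id]
    if not (0 <= locus.start <= locus.end <= len(seq)):
        raise ValueError(f"locus {locus} outside sequence bounds (len {len(seq)})")
    left = seq[max(0, locus.start - flank_len) : locus.start]
    tract = seq[locus.start : locus.end]
    right = seq[locus.end : locus.end + flank_len]
    return left, tract, right


def melting_temp(
    primer: str,
    monovalent_mM: float = 50.0,
    oligo_uM: float = 0.25,
) -> float:
    """Nearest-neighbor duplex melting temperature in degC, to 0.1 degC.

    SantaLucia (1998) unified parameters with the entropic salt correction
    dS += 0.368 (N-1) ln[Na+]. The effective duplex concentration is
    oligo/4 for non-self-complementary sequences (neither strand in excess)
    and oligo/1 with the symmetry entropy term for self-complementary ones.
    By construction the value is a property of the duplex: a primer and its
    reverse complement give the same Tm.
    """
    seq = primer.upper()
    if len(seq) < 8:
        raise ValueError(f"primer too short for NN model ({len(seq)} nt, need >= 8)")
    if any(b not in "ACGT" for b in seq):
        raise ValueError(f"primer must be plain ACGT: {primer!r}")

    dh, ds = 0.0, 0.0
    for terminal in (seq[0], seq[-1]):
        init_h, init_s = _INIT_GC if terminal in "GC" else _INIT_AT
        dh += init_h
        ds += init_s
    for i in range(len(seq) - 1):
        h, s = _NN[seq[i : i + 2]]
        dh += h
        ds += s

    self_comp = seq == _revcomp(seq)
    ct = oligo_uM * 1e-6
    if self_comp:
        ds += _SYMMETRY_DS
    else:
        ct /= 4.0
    ds += 0.368 * (len(seq) - 1) * math.log(monovalent_mM / 1000.0)
    tm = dh * 1000.0 / (ds + _R * math.log(ct)) - 273.15
    return round(tm, 1)


def screen_primer_pair(
    pair: PrimerPair, constraints: ScreenConstraints | None = None
) -> ScreenReport:
    """Check a primer pair against every constraint window.

    All constraints are evaluated (no short-circuit) so the report lists
    every violation; the product-length check is skipped when the product
    length is unknown.
    """
    constraints = constraints or ScreenConstraints()
    violations: list[str] = []

    lo, hi = constraints.primer_len_range
    for name, seq in (("forward", pair.forward), ("reverse", pair.reverse)):
        if not (lo <= len(seq) <= hi):
            violations.append(f"primer_len:{name}")

    tlo, thi = constraints.tm_range
    tm_f = melting_temp(pair.forward)
    tm_r = melting_temp(pair.reverse)
    if not (tlo <= tm_f <= thi):
        violations.append("tm:forward")
    if not (tlo <= tm_r <= thi):
        violations.append("tm:reverse")

    if pair.predicted_product_len is not None:
        plo, phi = constraints.product_len_range
        if not (plo <= pair.predicted_product_len <= phi):
            violations.append("product_len")

    return ScreenReport(
        locus_id=pair.locus_id,
        passed=not violations,
        violations=violations,
        tm_forward=tm_f,
        tm_reverse=tm_r,
    )


def in_silico_pcr(
    records: dict[str, str], pair: PrimerPair, max_product: int = 2000
) -> list[tuple[str, int, int, int]]:
    """Exact-match PCR product prediction.

    The forward primer is matched on the plus strand and the reverse
    complement of the reverse primer downstream of it. Returns
    (seq_id, start, end, product_len) with half-open coordinates covering
    both primer sites; products longer than *max_product* are dropped.
    """
    fwd = pair.forward.upper()
    rev_site = _revcomp(pair.reverse.upper())
    products = []
    for seq_id, seq in records.items():
        seq = seq.upper()
        f_pos = _find_all(seq, fwd)
        r_pos = _find_all(seq, rev_site)
        for f in f_pos:
            for r in r_pos:
                end = r + len(rev_site)
                length = end - f
                if f + len(fwd) <= r and length <= max_product:
                    products.append((seq_id, f, end, length))
    return sorted(products)


def _find_all(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out
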