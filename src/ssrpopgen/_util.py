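"""Shared helpers: rounding, seeding, atomic file output."""

from __future__ import annotations

import decimal
import os
import tempfile
from typing import Iterator

import numpy as np

MISSING = -1  # internal missing-allele sentinel; allele codes are > 0


def round_half_up(x: float, ndigits: int = 3) -> float:
    """Round with ties away from zero, as population-genetics tables print."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


def spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Split one integer seed into *n* independent substreams."""
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(n)]


def atomic_write_text(path: str | os.PathLike, text: str) -> None:
    """Write *text* to *path* via a temp file + rename, so failures never
    leave a truncated output behind."""
    path = os.fspath(path)
    d = os.path.dirname(path) or "."
    fd, tmp = tempfile.mkstemp(dir=d, prefix=".tmp-", text=True)
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def iter_fasta(path: str | os.PathLike) -> Iterator[tuple[str, str]]:
    """Yield (id, sequence) from a FASTA file, gzip-transparent."""
    import gzip

    from Bio import SeqIO

    path = os.fspath(path)
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, "rt") as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            yield rec.id, str(rec.seq)
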