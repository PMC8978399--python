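"""Sequence containers, identity metrics and ORF finding.

Coordinate convention
---------------------
Intervals are 1-based as reported to users, with ``length == end - start``:
an interval ``(start, end)`` covers the 1-based positions ``start .. end-1``
inclusive. This reproduces published arithmetic such as 15648 - 10098 = 5550
for a satellite array span. Converters to the two standard on-disk
conventions are provided: GFF3 (1-based, inclusive: ``(start, end-1)``) and
BED (0-based, half-open: ``(start-1, end-1)``).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "SeqRecord",
    "Interval",
    "read_fasta",
    "write_fasta",
    "revcomp",
    "ungapped_identity",
    "global_align_identity",
    "find_orfs",
    "interval_length",
    "majority_consensus",
    "to_gff3_coords",
    "to_bed_coords",
    "FastaParseError",
]

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHVacgtnryswkmbdhv",
                            "TGCANYRSWMKVHDBtgcanyrswmkvhdb")
_VALID_DNA = re.compile(r"^[ACGTNRYSWKMBDHV]*$")


class FastaParseError(ValueError):
    """Raised on an empty or malformed FASTA input."""


@dataclass(frozen=True)
class Interval:
    """1-based interval with ``length = end - start``; see module docstring."""

    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"end {self.end} < start {self.start}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def slice(self, seq: str) -> str:
        """Extract the covered bases from a sequence string."""
        return seq[self.start - 1:self.end - 1]

    def contains(self, other: "Interval") -> bool:
        return self.start <= other.start and other.end <= self.end

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end

    def shift(self, offset: int) -> "Interval":
        return Interval(self.start + offset, self.end + offset, self.strand)


@dataclass
class SeqRecord:
    """A named DNA sequence over {A,C,G,T,N}; uppercased on construction."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        self.seq = self.seq.upper().replace("U", "T")

    @property
    def length(self) -> int:
        return len(self.seq)


def interval_length(iv: Interval) -> int:
    """Length of an interval under the ``end - start`` convention."""
    return iv.end - iv.start


def to_gff3_coords(iv: Interval) -> tuple[int, int]:
    """Internal interval -> GFF3 (1-based, inclusive) start/end."""
    return iv.start, max(iv.start, iv.end - 1)


def to_bed_coords(iv: Interval) -> tuple[int, int]:
    """Internal interval -> BED (0-based, half-open) start/end."""
    return iv.start - 1, iv.end - 1


def read_fasta(path: str | Path) -> list[SeqRecord]:
    """Read a multi-record FASTA file, order preserved, uppercased, U->T.

    Raises :class:`FastaParseError` on an empty file or a file whose first
    non-blank line is not a FASTA header.
    """
    path = Path(path)
    text_head = ""
    with open(path) as fh:
        for line in fh:
            if line.strip():
                text_head = line
                break
    if not text_head:
        raise FastaParseError(f"{path}: empty FASTA file")
    if not text_head.startswith(">"):
        raise FastaParseError(f"{path}: malformed header line {text_head!r}")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FastaParseError(f"{path}: record with empty header")
        records.append(SeqRecord(id=rec.id, seq=str(rec.seq)))
    if not records:
        raise FastaParseError(f"{path}: no records parsed")
    return records


def write_fasta(records: Iterable[SeqRecord], path: str | Path) -> None:
    """Write records as FASTA wrapped at 60 columns."""
    bio = [_BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(bio)


def revcomp(s: str) -> str:
    """Watson-Crick reverse complement; N (and IUPAC ambiguity codes) map
    to their complements. Non-IUPAC characters raise ``ValueError``."""
    if not _VALID_DNA.match(s.upper()):
        bad = sorted(set(s.upper()) - set("ACGTNRYSWKMBDHV"))
        raise ValueError(f"non-IUPAC characters in sequence: {bad}")
    return s.translate(_COMPLEMENT)[::-1]


def ungapped_identity(a: str, b: str, span: Optional[int] = None) -> float:
    """Position-wise identity between equal-length strings, in [0, 1].

    With ``span`` given, only the first ``span`` positions are compared
    (both strings must be at least that long). N counts as a mismatch
    unless both strings carry N at the position-wise same site -- the
    comparison is literal, which is the conservative deterministic choice.
    """
    if span is not None:
        if span <= 0:
            raise ValueError("span must be positive")
        if span > min(len(a), len(b)):
            raise ValueError("span exceeds sequence length")
        a, b = a[:span], b[:span]
    elif len(a) != len(b):
        raise ValueError(
            f"unequal lengths ({len(a)} vs {len(b)}) and no span given")
    if not a:
        raise ValueError("empty comparison span")
    matches = sum(1 for x, y in zip(a, b) if x == y)
    return matches / len(a)


def global_align_identity(a: str, b: str, match: float = 1.0,
                          mismatch: float = -1.0, gap: float = -2.0) -> float:
    """Identity of a global (Needleman-Wunsch) alignment of two sequences.

    Identity is matched columns / total alignment columns (gap columns
    included in the denominator). Among co-optimal alignments the high-road
    traceback is used (diagonal preferred over up over left), which makes
    the reported identity deterministic.
    """
    if not a or not b:
        raise ValueError("empty input sequence")
    n, m = len(a), len(b)
    import numpy as np

    F = np.empty((n + 1, m + 1), dtype=np.float64)
    F[0, :] = np.arange(m + 1) * gap
    F[:, 0] = np.arange(n + 1) * gap
    bsub = np.frombuffer(b.encode(), dtype=np.uint8)
    for i in range(1, n + 1):
        sub = np.where(bsub == ord(a[i - 1]), match, mismatch)
        row_prev = F[i - 1]
        row = F[i]
        diag = row_prev[:-1] + sub
        up = row_prev[1:] + gap
        # left dependency is sequential within the row
        prev = row_prev[0] + gap  # F[i,0]
        row[0] = prev
        for j in range(1, m + 1):
            best = diag[j - 1]
            if up[j - 1] > best:
                best = up[j - 1]
            left = prev + gap
            if left > best:
                best = left
            row[j] = best
            prev = best
    # high-road traceback: diagonal > up > left
    i, j = n, m
    matches = 0
    columns = 0
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            sub = match if a[i - 1] == b[j - 1] else mismatch
            if F[i, j] == F[i - 1, j - 1] + sub:
                matches += a[i - 1] == b[j - 1]
                i, j = i - 1, j - 1
                columns += 1
                continue
        if i > 0 and F[i, j] == F[i - 1, j] + gap:
            i -= 1
            columns += 1
            continue
        j -= 1
        columns += 1
    return matches / columns


_STOPS = ("TAA", "TAG", "TGA")


def find_orfs(s: str, min_len: int) -> list[Interval]:
    """All six-frame ATG..stop open reading frames of length >= ``min_len``.

    The stop codon is included in the ORF span; every in-frame ATG upstream
    of a stop yields its own ORF (nested starts share the stop). Reverse
    strand ORFs are reported in forward-strand coordinates with strand '-'.
    Returned sorted by (start, end, strand).
    """
    if min_len < 3 or min_len % 3:
        raise ValueError("min_len must be >= 3 and divisible by 3")
    out: list[Interval] = []
    L = len(s)

    def scan(seq: str) -> list[tuple[int, int]]:
        from bisect import bisect_left

        found = []
        for frame in range(3):
            stops: list[int] = []
            starts: list[int] = []
            for i in range(frame, len(seq) - 2, 3):
                codon = seq[i:i + 3]
                if codon in _STOPS:
                    stops.append(i)
                elif codon == "ATG":
                    starts.append(i)
            for i in starts:
                k = bisect_left(stops, i)
                if k < len(stops) and (stops[k] + 3 - i) >= min_len:
                    found.append((i, stops[k] + 3))
        return found

    for i0, i1 in scan(s):
        out.append(Interval(i0 + 1, i1 + 1, "+"))
    rc = revcomp(s)
    for i0, i1 in scan(rc):
        out.append(Interval(L - i1 + 1, L - i0 + 1, "-"))
    out.sort(key=lambda iv: (iv.start, iv.end, iv.strand))
    return out


def majority_consensus(copies: Sequence[str]) -> str:
    """Per-column majority base over equal-length strings; ties broken by
    the fixed base order A < C < G < T (then other characters)."""
    if not copies:
        raise ValueError("no copies given")
    n = len(copies[0])
    if any(len(c) != n for c in copies):
        raise ValueError("copies differ in length")
    order = {b: i for i, b in enumerate("ACGTN")}
    cons = []
    for col in zip(*copies):
        counts: dict[str, int] = {}
        for ch in col:
            counts[ch] = counts.get(ch, 0) + 1
        best = sorted(counts.items(),
                      key=lambda kv: (-kv[1], order.get(kv[0], 99), kv[0]))[0][0]
        cons.append(best)
    return "".join(cons)
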