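"""Coordinate-safe primitives shared by every other module.

All internal coordinates are 0-based half-open (``[start, end)``).  File
formats that use other conventions (GTF: 1-based closed) are converted at
the I/O boundary and nowhere else.
"""

from __future__ import annotations

from dataclasses import dataclass, field

_COMPLEMENT = str.maketrans("ACGUTN", "UGCAAN")
_DNA_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval on a named sequence.

    ``strand`` is ``+``, ``-`` or ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start {self.start} on {self.chrom}")
        if self.start >= self.end:
            raise ValueError(
                f"empty/inverted interval [{self.start},{self.end}) on {self.chrom}"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlap(self, other: "GenomicInterval") -> int:
        """Length of the overlap with *other* (0 if disjoint or other chrom)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def shifted(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(self.chrom, self.start + offset, self.end + offset, self.strand)


@dataclass
class SequenceRecord:
    """An upper-case nucleotide sequence restricted to {A,C,G,U,N}.

    DNA input is accepted; ``T`` is normalized to ``U`` on construction so
    that RNA-structure patterns can be scanned uniformly.
    """

    id: str
    residues: str = field(repr=False)

    def __post_init__(self) -> None:
        seq = self.residues.upper().replace("T", "U")
        if not seq:
            raise ValueError(f"empty sequence for {self.id!r}")
        bad = set(seq) - set("ACGUN")
        if bad:
            raise ValueError(f"invalid characters {sorted(bad)} in sequence {self.id!r}")
        self.residues = seq

    def __len__(self) -> int:
        return len(self.residues)

    def slice(self, start: int, end: int) -> str:
        if start < 0 or end > len(self.residues) or start >= end:
            raise IndexError(
                f"range [{start},{end}) outside sequence {self.id!r} of length {len(self)}"
            )
        return self.residues[start:end]


def revcomp(seq: str) -> str:
    """Reverse complement of an RNA/DNA string (result in RNA alphabet)."""
    s = seq.upper().replace("T", "U")
    return s.translate(_COMPLEMENT)[::-1]


def revcomp_dna(seq: str) -> str:
    return seq.upper().replace("U", "T").translate(_DNA_COMPLEMENT)[::-1]


def merge_intervals(intervals, gap: int = 0):
    """bedtools-merge-style union of intervals within ``gap`` nt of each other.

    Input may be unsorted; output is sorted (chrom, start).  Strand is ignored
    (the unstranded merge bedtools performs by default).
    """
    ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    merged: list[GenomicInterval] = []
    for iv in ivs:
        if merged and merged[-1].chrom == iv.chrom and iv.start - merged[-1].end <= gap:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end, last.strand)
        else:
            merged.append(iv)
    return merged
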