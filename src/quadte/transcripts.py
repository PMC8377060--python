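"""Transcript models: exon/CDS structure and 5'UTR / CDS / 3'UTR / intron regions.

A :class:`TranscriptModel` keeps exons in genomic coordinates and derives

* mature-transcript (spliced) coordinates, oriented 5'->3' on the sense
  strand, for region annotation and motif scanning, and
* intron intervals, in genomic coordinates, as the gaps between exons.

When a CDS is present the three mature regions partition the transcript
exactly: ``len(5'UTR) + len(CDS) + len(3'UTR) == mature length``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .intervals import GenomicInterval, SequenceRecord, revcomp


class AnnotationError(ValueError):
    """Malformed annotation input (bad GTF record, inconsistent CDS)."""


@dataclass
class TranscriptModel:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval]
    cds_span: Optional[tuple[int, int]] = None  # genomic [start, end) bounds
    _tx_starts: list[int] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.transcript_id}: transcript strand must be + or -")
        exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(exons, exons[1:]):
            if a.end > b.start:
                raise AnnotationError(f"{self.transcript_id}: overlapping exons")
        self.exons = exons
        # cumulative mature offsets of exons in genomic (ascending) order
        self._tx_starts = []
        pos = 0
        for e in exons:
            self._tx_starts.append(pos)
            pos += len(e)
        self._mature_len = pos
        if self.cds_span is not None:
            cs, ce = self.cds_span
            if not (cs < ce):
                raise AnnotationError(f"{self.transcript_id}: empty CDS span")
            for g in (cs, ce - 1):
                if not any(e.start <= g < e.end for e in exons):
                    raise AnnotationError(
                        f"{self.transcript_id}: CDS bound {g} outside exons"
                    )

    # ------------------------------------------------------------------ coords
    @property
    def mature_length(self) -> int:
        return self._mature_len

    def genomic_to_transcript(self, gpos: int) -> int:
        """Map a genomic position (inside an exon) to mature 5'->3' coordinates."""
        for e, off in zip(self.exons, self._tx_starts):
            if e.start <= gpos < e.end:
                plus = off + (gpos - e.start)
                return plus if self.strand == "+" else self._mature_len - 1 - plus
        raise ValueError(f"{self.transcript_id}: genomic position {gpos} not exonic")

    def transcript_to_genomic(self, start: int, end: int) -> list[GenomicInterval]:
        """Project a mature-coordinate span back to (possibly split) genomic intervals."""
        if not (0 <= start < end <= self._mature_len):
            raise ValueError(f"{self.transcript_id}: span [{start},{end}) outside transcript")
        if self.strand == "+":
            plus_span = (start, end)
        else:
            plus_span = (self._mature_len - end, self._mature_len - start)
        out = []
        for e, off in zip(self.exons, self._tx_starts):
            lo = max(plus_span[0], off)
            hi = min(plus_span[1], off + len(e))
            if lo < hi:
                out.append(
                    GenomicInterval(self.chrom, e.start + lo - off, e.start + hi - off, self.strand)
                )
        return out

    # ----------------------------------------------------------------- regions
    @property
    def introns(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(self.chrom, a.end, b.start, self.strand)
            for a, b in zip(self.exons, self.exons[1:])
            if b.start > a.end
        ]

    @property
    def cds_transcript_span(self) -> Optional[tuple[int, int]]:
        if self.cds_span is None:
            return None
        cs, ce = self.cds_span
        a = self.genomic_to_transcript(cs)
        b = self.genomic_to_transcript(ce - 1)
        lo, hi = min(a, b), max(a, b)
        return (lo, hi + 1)

    @property
    def five_prime_utr(self) -> Optional[tuple[int, int]]:
        span = self.cds_transcript_span
        if span is None or span[0] == 0:
            return None
        return (0, span[0])

    @property
    def three_prime_utr(self) -> Optional[tuple[int, int]]:
        span = self.cds_transcript_span
        if span is None or span[1] == self._mature_len:
            return None
        return (span[1], self._mature_len)

    def region_lengths(self) -> dict[str, int]:
        """Mature-region and intron lengths; UTR/CDS are 0 for noncoding models."""
        out = {"5'UTR": 0, "CDS": 0, "3'UTR": 0, "intron": sum(len(i) for i in self.introns)}
        span = self.cds_transcript_span
        if span is not None:
            out["5'UTR"] = span[0]
            out["CDS"] = span[1] - span[0]
            out["3'UTR"] = self._mature_len - span[1]
        return out

    def region_genomic_intervals(self) -> dict[str, list[GenomicInterval]]:
        """Genomic projection of each region class (introns included)."""
        out: dict[str, list[GenomicInterval]] = {"intron": self.introns}
        span = self.cds_transcript_span
        if span is None:
            out["noncoding_exon"] = list(self.exons)
            return out
        for name, (lo, hi) in (
            ("5'UTR", (0, span[0])),
            ("CDS", span),
            ("3'UTR", (span[1], self._mature_len)),
        ):
            out[name] = self.transcript_to_genomic(lo, hi) if lo < hi else []
        return out

    # --------------------------------------------------------------- sequences
    def mature_sequence(self, genome: Mapping[str, SequenceRecord]) -> SequenceRecord:
        """Spliced sense-strand (RNA) sequence of the mature transcript."""
        chrom = genome.get(self.chrom)
        if chrom is None:
            raise KeyError(f"chromosome {self.chrom!r} absent from genome")
        parts = [chrom.slice(e.start, e.end) for e in self.exons]
        seq = "".join(parts)
        if self.strand == "-":
            seq = revcomp(seq)
        return SequenceRecord(self.transcript_id, seq)


def extract_sense_sequence(
    interval: GenomicInterval, genome: Mapping[str, SequenceRecord]
) -> SequenceRecord:
    """Sense-strand RNA sequence of a genomic interval (revcomp on minus)."""
    chrom = genome.get(interval.chrom)
    if chrom is None:
        raise KeyError(f"chromosome {interval.chrom!r} absent from genome")
    seq = chrom.slice(interval.start, interval.end)
    if interval.strand == "-":
        seq = revcomp(seq)
    name = f"{interval.chrom}:{interval.start}-{interval.end}({interval.strand})"
    return SequenceRecord(name, seq)


# --------------------------------------------------------------------- GTF I/O

def read_transcript_models(gtf_path: str) -> list[TranscriptModel]:
    """Parse a GTF/GFF annotation into transcript models.

    File coordinates (1-based closed) are converted to the internal 0-based
    half-open convention here and nowhere else.  Transcripts whose CDS falls
    outside their exons are rejected with a warning rather than aborting the
    whole load.
    """
    import gffutils

    try:
        db = gffutils.create_db(
            gtf_path,
            ":memory:",
            merge_strategy="create_unique",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
        )
    except Exception as exc:  # gffutils reports the offending line in its message
        raise AnnotationError(f"failed to parse {gtf_path}: {exc}") from exc

    by_tx: dict[str, dict] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        try:
            tx_id = feat.attributes["transcript_id"][0]
        except KeyError as exc:
            raise AnnotationError(
                f"{gtf_path}: {feat.featuretype} at {feat.seqid}:{feat.start} "
                "lacks transcript_id"
            ) from exc
        gene_id = feat.attributes.get("gene_id", [tx_id])[0]
        entry = by_tx.setdefault(
            tx_id, {"gene_id": gene_id, "chrom": feat.seqid, "strand": feat.strand,
                    "exons": [], "cds": []}
        )
        iv = (feat.start - 1, feat.end)  # GTF 1-based closed -> 0-based half-open
        (entry["exons"] if feat.featuretype == "exon" else entry["cds"]).append(iv)

    models = []
    for tx_id, entry in by_tx.items():
        exons = [
            GenomicInterval(entry["chrom"], s, e, entry["strand"])
            for s, e in sorted(entry["exons"])
        ]
        cds_span = None
        if entry["cds"]:
            cds_span = (min(s for s, _ in entry["cds"]), max(e for _, e in entry["cds"]))
        try:
            models.append(
                TranscriptModel(tx_id, entry["gene_id"], entry["chrom"],
                                entry["strand"], exons, cds_span)
            )
        except AnnotationError as exc:
            warnings.warn(f"rejected transcript {tx_id}: {exc}")
    return models


def write_gtf(models: Iterable[TranscriptModel], path: str, source: str = "quadte") -> None:
    """Write exon and CDS features (GTF2, 1-based closed coordinates)."""
    with open(path, "w") as fh:
        for m in models:
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
            for e in m.exons:
                fh.write(
                    f"{m.chrom}\t{source}\texon\t{e.start + 1}\t{e.end}\t.\t{m.strand}\t.\t{attrs}\n"
                )
            if m.cds_span is not None:
                cs, ce = m.cds_span
                for e in m.exons:
                    lo, hi = max(e.start, cs), min(e.end, ce)
                    if lo < hi:
                        fh.write(
                            f"{m.chrom}\t{source}\tCDS\t{lo + 1}\t{hi}\t.\t{m.strand}\t.\t{attrs}\n"
                        )


def representative_transcripts(models: Sequence[TranscriptModel]) -> dict[str, TranscriptModel]:
    """One transcript per gene: the longest mature transcript (ties: lexicographic id)."""
    best: dict[str, TranscriptModel] = {}
    for m in sorted(models, key=lambda m: (-m.mature_length, m.transcript_id)):
        best.setdefault(m.gene_id, m)
    return best
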