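"""Readers/writers for FASTA, BED6, bedGraph and TSV tables.

BED and bedGraph are 0-based half-open on disk, matching the internal
convention, so these round-trip bit-exactly.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .intervals import GenomicInterval, SequenceRecord

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_fasta(path: str) -> dict[str, SequenceRecord]:
    """Load a (multi-)FASTA into {id: SequenceRecord}; T is normalized to U."""
    records = {}
    for rec in SeqIO.parse(path, "fasta"):
        records[rec.id] = SequenceRecord(rec.id, str(rec.seq))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str, as_dna: bool = False) -> None:
    bio = []
    for r in records:
        seq = r.residues.replace("U", "T") if as_dna else r.residues
        bio.append(BioSeqRecord(Seq(seq), id=r.id, description=""))
    SeqIO.write(bio, path, "fasta")


def read_bed(path: str) -> pd.DataFrame:
    """BED6 (or BED3/4/5 prefix) as a DataFrame with canonical column names."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    df.columns = BED6_COLUMNS[: df.shape[1]]
    for col, default in (("name", "."), ("score", 0.0), ("strand", ".")):
        if col not in df.columns:
            df[col] = default
    return df[BED6_COLUMNS]


def write_bed(df: pd.DataFrame, path: str) -> None:
    df[BED6_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


def intervals_from_bed(df: pd.DataFrame) -> list[GenomicInterval]:
    return [
        GenomicInterval(r.chrom, int(r.start), int(r.end), r.strand)
        for r in df.itertuples()
    ]


def read_bedgraph(path: str) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "value"], dtype={"chrom": str},
    )
    if (df["value"] < 0).any():
        raise ValueError(f"{path}: negative coverage values")
    return df


def write_bedgraph(df: pd.DataFrame, path: str) -> None:
    df[["chrom", "start", "end", "value"]].to_csv(path, sep="\t", header=False, index=False)


def read_table(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_table(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


def validate_files(paths: Mapping[str, str]) -> dict[str, str]:
    """Light-weight validation: {kind: path} -> {path: "ok" | error message}.

    Kinds: fasta, gtf, bed, bedgraph, tsv.
    """
    readers = {
        "fasta": read_fasta,
        "bed": read_bed,
        "bedgraph": read_bedgraph,
        "tsv": read_table,
    }

    def _gtf(path):
        from .transcripts import read_transcript_models

        return read_transcript_models(path)

    readers["gtf"] = _gtf
    report = {}
    for kind, path in paths.items():
        try:
            readers[kind](path)
            report[path] = "ok"
        except Exception as exc:
            report[path] = f"error: {exc}"
    return report
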