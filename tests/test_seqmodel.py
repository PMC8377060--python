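"""Coordinate model, transcript regions and format round-trips."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from quadte.intervals import GenomicInterval, SequenceRecord, merge_intervals, revcomp
from quadte.io import (intervals_from_bed, read_bed, read_bedgraph, read_fasta,
                       write_bed, write_bedgraph, write_fasta)
from quadte.transcripts import (AnnotationError, TranscriptModel,
                                extract_sense_sequence, read_transcript_models,
                                representative_transcripts, write_gtf)

# ---------------------------------------------------------------- intervals


def test_interval_invariants():
    iv = GenomicInterval("chr1", 10, 20, "+")
    assert len(iv) == 10
    with pytest.raises(ValueError):
        GenomicInterval("chr1", 20, 20)
    with pytest.raises(ValueError):
        GenomicInterval("chr1", -1, 5)
    with pytest.raises(ValueError):
        GenomicInterval("chr1", 0, 5, "x")


@given(st.text(alphabet="ACGU", min_size=1, max_size=200))
@settings(deadline=None, max_examples=100, derandomize=True)
def test_revcomp_involution(s):
    assert revcomp(revcomp(s)) == s


def test_sequence_record_normalizes_dna():
    rec = SequenceRecord("r", "gatTACA")
    assert rec.residues == "GAUUACA"
    with pytest.raises(ValueError):
        SequenceRecord("r", "ACGX")
    with pytest.raises(ValueError):
        SequenceRecord("r", "")


# --------------------------------------------------------------- transcripts

def _two_exon_model(strand):
    exons = [GenomicInterval("c", 100, 200, strand), GenomicInterval("c", 300, 400, strand)]
    return TranscriptModel("t1", "g1", "c", strand, exons, cds_span=(150, 350))


@pytest.mark.parametrize("strand", ["+", "-"])
def test_region_partition_two_exons(strand):
    # exonic CDS content of genomic [150,350) is 100 nt (50 in each exon);
    # the mature partition 50 + 100 + 50 must equal the 200-nt transcript
    m = _two_exon_model(strand)
    lengths = m.region_lengths()
    assert lengths["5'UTR"] == 50 and lengths["CDS"] == 100 and lengths["3'UTR"] == 50
    assert m.introns == [GenomicInterval("c", 200, 300, strand)]
    assert sum(v for k, v in lengths.items() if k != "intron") == m.mature_length


def test_minus_strand_utr_side():
    m = _two_exon_model("-")
    utr5 = m.five_prime_utr
    # the 5'UTR occupies mature coords [0,50) which project to genomic [350,400)
    ivs = m.transcript_to_genomic(*utr5)
    assert ivs == [GenomicInterval("c", 350, 400, "-")]


def test_noncoding_model_has_no_utrs():
    m = TranscriptModel("t", "g", "c", "+", [GenomicInterval("c", 0, 90, "+")])
    assert m.five_prime_utr is None and m.three_prime_utr is None
    assert "noncoding_exon" in m.region_genomic_intervals()


def test_cds_outside_exons_rejected():
    with pytest.raises(AnnotationError):
        TranscriptModel("t", "g", "c", "+",
                        [GenomicInterval("c", 100, 200, "+")], cds_span=(250, 260))


def test_transcript_genomic_roundtrip():
    m = _two_exon_model("-")
    for start in range(0, m.mature_length):
        ivs = m.transcript_to_genomic(start, start + 1)
        assert len(ivs) == 1
        assert m.genomic_to_transcript(ivs[0].start) == start


# ----------------------------------------------------------- sense sequences

GENOME = {"c": SequenceRecord("c", "GATTACA")}


def test_extract_sense_plus_minus():
    assert extract_sense_sequence(GenomicInterval("c", 0, 4, "+"), GENOME).residues == "GAUU"
    assert extract_sense_sequence(GenomicInterval("c", 0, 4, "-"), GENOME).residues == "AAUC"


def test_extract_errors():
    with pytest.raises(KeyError):
        extract_sense_sequence(GenomicInterval("nope", 0, 2, "+"), GENOME)
    with pytest.raises(IndexError):
        extract_sense_sequence(GenomicInterval("c", 0, 99, "+"), GENOME)


def test_mature_sequence_splices_and_orients(small_dataset):
    ds = small_dataset
    m = next(mm for mm in ds.models if mm.strand == "-")
    seq = m.mature_sequence(ds.genome)
    assert len(seq) == m.mature_length
    # region partition holds on generated models too
    lens = m.region_lengths()
    assert lens["5'UTR"] + lens["CDS"] + lens["3'UTR"] == m.mature_length


# ------------------------------------------------------------- file formats

def test_fasta_roundtrip(tmp_path):
    recs = [SequenceRecord("a", "ACGU"), SequenceRecord("b", "GGGAUU")]
    p = tmp_path / "x.fa"
    write_fasta(recs, str(p))
    back = read_fasta(str(p))
    assert back["a"].residues == "ACGU" and back["b"].residues == "GGGAUU"


def test_bed_and_bedgraph_roundtrip(tmp_path):
    bed = pd.DataFrame({
        "chrom": ["c1", "c2"], "start": [0, 10], "end": [5, 30],
        "name": ["s1", "s2"], "score": [1.5, 2.0], "strand": ["+", "-"],
    })
    p = tmp_path / "x.bed"
    write_bed(bed, str(p))
    back = read_bed(str(p))
    pd.testing.assert_frame_equal(back, bed)
    ivs = intervals_from_bed(back)
    assert ivs[1] == GenomicInterval("c2", 10, 30, "-")

    bg = pd.DataFrame({"chrom": ["c1"], "start": [0], "end": [100], "value": [7]})
    pb = tmp_path / "x.bedgraph"
    write_bedgraph(bg, str(pb))
    pd.testing.assert_frame_equal(read_bedgraph(str(pb)), bg)


def test_negative_coverage_rejected(tmp_path):
    p = tmp_path / "bad.bedgraph"
    p.write_text("c1\t0\t100\t-3\n")
    with pytest.raises(ValueError):
        read_bedgraph(str(p))


def test_gtf_roundtrip(tmp_path, small_dataset):
    ds = small_dataset
    p = tmp_path / "x.gtf"
    write_gtf(ds.models, str(p))
    back = read_transcript_models(str(p))
    by_id = {m.transcript_id: m for m in back}
    assert len(by_id) == len(ds.models)
    for m in ds.models:
        b = by_id[m.transcript_id]
        assert b.exons == m.exons
        assert b.cds_span == m.cds_span
        assert b.strand == m.strand and b.gene_id == m.gene_id


def test_malformed_gtf_raises(tmp_path):
    p = tmp_path / "bad.gtf"
    p.write_text("chr1\tsrc\texon\tnot_a_number\t200\t.\t+\t.\tgene_id \"g\";\n")
    with pytest.raises(AnnotationError):
        read_transcript_models(str(p))


def test_representative_transcript_longest():
    e1 = [GenomicInterval("c", 0, 100, "+")]
    e2 = [GenomicInterval("c", 0, 300, "+")]
    short = TranscriptModel("t_short", "g", "c", "+", e1)
    long = TranscriptModel("t_long", "g", "c", "+", e2)
    assert representative_transcripts([short, long])["g"].transcript_id == "t_long"


def test_merge_intervals_gap():
    ivs = [GenomicInterval("c", 0, 10), GenomicInterval("c", 13, 20),
           GenomicInterval("c", 40, 50)]
    merged = merge_intervals(ivs, gap=5)
    assert [(m.start, m.end) for m in merged] == [(0, 20), (40, 50)]
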