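"""Synthetic transcriptome, CLIP coverage and FPKM tables with known truth.

The generator emulates the statistical structure the analysis assumes:

* transcript models with 5'UTR / CDS / 3'UTR and one intron, a subset on
  the minus strand;
* background sequence uniform over {A,C,G,U}, rejection-sampled on *both*
  strands so that no unplanned rG4 or ARE exists anywhere in the genome —
  planted-recovery tests are therefore exact, not probabilistic;
* planted rG4 subtypes / ARE classes at recorded coordinates, flanked by
  A so the planted span is exactly what the scanners should report;
* CLIP bin counts drawn from a zero-truncated negative binomial (ZTNB)
  with a configurable fraction of empty bins; bound genes carry one peak
  bin multiplied by the enrichment factor in both replicates (shared
  locus, independent noise);
* FPKM tables drawn lognormal with planted TE / mRNA fold effects and
  multiplicative replicate noise.

Defaults are the study conditions the pipeline is tested under: 200
genes, 40 bound in the 5'UTR with a canonical rG4 and a planted TE fold
change of 0.4, replicate noise sigma 0.1, ZTNB(r=2, p=0.3) background and
10x peak enrichment.  Smaller groups bound in the CDS (no structure
effect) and in the 3'UTR with a class-2 ARE plus an mRNA fold change of
0.4 exercise the remaining region classes.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as qio
from .are import scan_are
from .intervals import GenomicInterval, SequenceRecord, revcomp
from .peaks import ZTNBModel
from .rg4 import scan_rg4
from .transcripts import TranscriptModel, write_gtf

RG4_EXEMPLARS = {
    "canonical": "GGGAGGGAGGGAGGG",
    "long_loop": "GGGAGGGAAAAAAAAAGGGAGGG",
    "bulge": "GGGAGGGAGGAGAGGG",
    "two_quartet": "GGAGGAGGAGG",
}
ARE_EXEMPLARS = {
    "class1": "AAUUUAA",
    "class2": "AUUUAUUUAUUUA",
    "class3": "UUUUUU",
}

_PAD = 100  # flanking genomic padding per chromosome


@dataclass
class SyntheticConfig:
    seed: int = 0
    n_genes: int = 200
    utr5_len: int = 150
    cds_len: int = 450
    utr3_len: int = 300
    intron_len: int = 200
    minus_strand_every: int = 5  # every k-th gene is minus strand
    # planted structure / binding plan
    n_utr5_rg4_bound: int = 40
    utr5_rg4_subtype: str = "canonical"
    n_cds_bound: int = 10
    n_utr3_are_bound: int = 10
    utr3_are_class: str = "class2"
    # CLIP model
    ztnb_r: float = 2.0
    ztnb_p: float = 0.3
    enrichment: float = 10.0
    zero_fraction: float = 0.3
    bin_size: int = 100
    # expression model
    fpkm_log_mean: float = 3.0
    fpkm_log_sigma: float = 1.0
    sigma_rep: float = 0.1
    planted_delta_te: float = 0.4
    planted_delta_mrna: float = 0.4

    def __post_init__(self) -> None:
        n_planted = self.n_utr5_rg4_bound + self.n_cds_bound + self.n_utr3_are_bound
        if n_planted > self.n_genes:
            raise ValueError("more planted genes than genes")
        if not (0 <= self.zero_fraction < 1):
            raise ValueError("zero_fraction must be in [0, 1)")
        if self.planted_delta_te > 0.66:
            raise ValueError("TE-down scenario requires planted_delta_te <= 0.66")
        for name in ("utr5_len", "cds_len", "utr3_len"):
            motif = RG4_EXEMPLARS.get(self.utr5_rg4_subtype, "")
            if getattr(self, name) < len(motif) + 2:
                raise ValueError(f"{name} too short for the planted structure")


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    genome: dict[str, SequenceRecord]
    models: list[TranscriptModel]
    tracks: dict[str, pd.DataFrame]  # replicate id -> bedGraph frame
    fpkm: pd.DataFrame
    ground_truth: dict[str, dict] = field(default_factory=dict)

    def write(self, out_dir: str) -> dict[str, str]:
        os.makedirs(out_dir, exist_ok=True)
        paths = {
            "fasta": os.path.join(out_dir, "genome.fa"),
            "gtf": os.path.join(out_dir, "annotation.gtf"),
            "fpkm": os.path.join(out_dir, "fpkm.tsv"),
            "truth": os.path.join(out_dir, "ground_truth.json"),
        }
        qio.write_fasta(self.genome.values(), paths["fasta"], as_dna=True)
        write_gtf(self.models, paths["gtf"])
        qio.write_table(self.fpkm, paths["fpkm"])
        for rep, track in self.tracks.items():
            paths[rep] = os.path.join(out_dir, f"clip_{rep}.bedgraph")
            qio.write_bedgraph(track, paths[rep])
        with open(paths["truth"], "w") as fh:
            json.dump(self.ground_truth, fh, indent=1, sort_keys=True)
        return paths


def _random_seq(rng: np.random.Generator, n: int) -> list[str]:
    return list(np.array(list("ACGU"))[rng.integers(0, 4, size=n)])


def _scan_spans(s: str) -> list[tuple[int, int]]:
    rec = SequenceRecord("tmp", s)
    return [a.span for a in scan_rg4(rec)] + [a.span for a in scan_are(rec)]


def _clean_chromosome(chars: list[str], protected: list[tuple[int, int]],
                      rng: np.random.Generator, model: "TranscriptModel",
                      max_rounds: int = 200) -> list[str]:
    """Redraw windows until no unplanned rG4/ARE hit remains on either
    genomic strand or in the spliced (mature) sense sequence."""
    prot = sorted(protected)

    def _in_protected(sp: tuple[int, int]) -> bool:
        return any(sp[0] >= a and sp[1] <= b for a, b in prot)

    for _ in range(max_rounds):
        fwd = "".join(chars)
        n = len(fwd)
        bad = list(_scan_spans(fwd))
        bad += [(n - b, n - a) for a, b in _scan_spans(revcomp(fwd))]
        # junction-spanning hits exist only in the spliced sequence
        mature = "".join(fwd[e.start:e.end] for e in model.exons)
        if model.strand == "-":
            mature = revcomp(mature)
        for a, b in _scan_spans(mature):
            for iv in model.transcript_to_genomic(a, b):
                bad.append((iv.start, iv.end))
        bad = [sp for sp in bad if not _in_protected(sp)]
        if not bad:
            return chars
        for lo, hi in bad:
            for i in range(max(0, lo - 1), min(len(chars), hi + 1)):
                if not any(a <= i < b for a, b in prot):
                    chars[i] = "ACGU"[rng.integers(0, 4)]
    raise RuntimeError("could not produce a clean background (plan too dense?)")


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Build the full synthetic dataset.  Same config (incl. seed) -> same bytes."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    mature_len = cfg.utr5_len + cfg.cds_len + cfg.utr3_len

    genome: dict[str, SequenceRecord] = {}
    models: list[TranscriptModel] = []
    truth: dict[str, dict] = {}

    n_a, n_b, n_c = cfg.n_utr5_rg4_bound, cfg.n_cds_bound, cfg.n_utr3_are_bound
    rg4_motif = RG4_EXEMPLARS[cfg.utr5_rg4_subtype]
    are_motif = ARE_EXEMPLARS[cfg.utr3_are_class]

    for gi in range(cfg.n_genes):
        gene = f"g{gi:04d}"
        chrom = f"chr_{gene}"
        strand = "-" if cfg.minus_strand_every and (gi % cfg.minus_strand_every == cfg.minus_strand_every - 1) else "+"

        if gi < n_a:
            group, bound_region = "utr5_rg4", "5'UTR"
        elif gi < n_a + n_b:
            group, bound_region = "cds", "CDS"
        elif gi < n_a + n_b + n_c:
            group, bound_region = "utr3_are", "3'UTR"
        else:
            group, bound_region = "background", None

        # ----- mature sense sequence with planted structure
        mature = _random_seq(rng, mature_len)
        planted: dict[str, tuple[int, int]] = {}
        if group == "utr5_rg4":
            at = (cfg.utr5_len - len(rg4_motif)) // 2
            mature[at - 1] = "A"
            mature[at + len(rg4_motif)] = "A"
            mature[at:at + len(rg4_motif)] = list(rg4_motif)
            planted["rg4"] = (at, at + len(rg4_motif))
        elif group == "utr3_are":
            at = cfg.utr5_len + cfg.cds_len + (cfg.utr3_len - len(are_motif)) // 2
            mature[at - 1] = "C"
            mature[at + len(are_motif)] = "C"
            mature[at:at + len(are_motif)] = list(are_motif)
            planted["are"] = (at, at + len(are_motif))

        # ----- genomic assembly: one intron splitting the CDS
        split = cfg.utr5_len + cfg.cds_len // 2  # mature coordinate of the junction
        sense_genomic = "".join(mature) if strand == "+" else revcomp("".join(mature))
        gsplit = split if strand == "+" else mature_len - split
        intron = _random_seq(rng, cfg.intron_len)
        chars = (
            _random_seq(rng, _PAD)
            + list(sense_genomic[:gsplit]) + intron + list(sense_genomic[gsplit:])
            + _random_seq(rng, _PAD)
        )
        exon1 = GenomicInterval(chrom, _PAD, _PAD + gsplit, strand)
        exon2 = GenomicInterval(chrom, _PAD + gsplit + cfg.intron_len,
                                _PAD + gsplit + cfg.intron_len + mature_len - gsplit, strand)
        model = TranscriptModel(f"{gene}.t1", gene, chrom, strand, [exon1, exon2])
        cds_ivs = model.transcript_to_genomic(cfg.utr5_len, cfg.utr5_len + cfg.cds_len)
        model = TranscriptModel(
            f"{gene}.t1", gene, chrom, strand, [exon1, exon2],
            cds_span=(min(iv.start for iv in cds_ivs), max(iv.end for iv in cds_ivs)),
        )

        protected = []
        for span in planted.values():
            for iv in model.transcript_to_genomic(*span):
                protected.append((iv.start, iv.end))
        chars = _clean_chromosome(chars, protected, rng, model)
        genome[chrom] = SequenceRecord(chrom, "".join(chars))
        models.append(model)

        entry = {
            "group": group,
            "strand": strand,
            "bound_region": bound_region,
            "rg4_subtype": cfg.utr5_rg4_subtype if group == "utr5_rg4" else None,
            "are_class": cfg.utr3_are_class if group == "utr3_are" else None,
            "planted_tx_spans": {k: list(v) for k, v in planted.items()},
            "te_category": "down" if group == "utr5_rg4" else "unchanged",
            "mrna_category": "down" if group == "utr3_are" else "unchanged",
            "stringent": bool(group == "utr5_rg4" and cfg.planted_delta_te < 0.5),
        }

        # ----- peak locus: the bin containing the bound feature's center
        if bound_region is not None:
            if group == "utr5_rg4":
                tx_center = sum(planted["rg4"]) // 2
            elif group == "cds":
                tx_center = cfg.utr5_len + cfg.cds_len // 2 + 10
            else:
                tx_center = sum(planted["are"]) // 2
            giv = model.transcript_to_genomic(tx_center, tx_center + 1)[0]
            b = giv.start // cfg.bin_size
            entry["peak_bin"] = [chrom, b * cfg.bin_size, (b + 1) * cfg.bin_size]
        truth[gene] = entry

    # ----- CLIP tracks: shared peak loci, independent replicate noise
    ztnb = ZTNBModel(r=cfg.ztnb_r, p=cfg.ztnb_p, converged=True)
    tracks = {}
    for rep in ("rep1", "rep2"):
        rows = []
        for gene, entry in truth.items():
            chrom = f"chr_{gene}"
            n_bins = len(genome[chrom]) // cfg.bin_size + 1
            occupied = rng.random(n_bins) >= cfg.zero_fraction
            counts = np.zeros(n_bins, dtype=int)
            counts[occupied] = ztnb.rvs(int(occupied.sum()), rng)
            if "peak_bin" in entry:
                b = entry["peak_bin"][1] // cfg.bin_size
                # peak = enrichment x background mean, Poisson replicate noise
                counts[b] = max(1, int(rng.poisson(cfg.enrichment * ztnb.mean)))
            for b in np.nonzero(counts)[0]:
                rows.append((chrom, b * cfg.bin_size, (b + 1) * cfg.bin_size, int(counts[b])))
        tracks[rep] = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])

    # ----- FPKM tables
    rows = []
    for gene, entry in truth.items():
        base = float(rng.lognormal(cfg.fpkm_log_mean, cfg.fpkm_log_sigma))
        d_te = cfg.planted_delta_te if entry["te_category"] == "down" else 1.0
        d_mrna = cfg.planted_delta_mrna if entry["mrna_category"] == "down" else 1.0
        row = {"gene_id": gene}
        for rep in ("rep1", "rep2"):
            noise = rng.lognormal(0.0, cfg.sigma_rep, size=4)
            row[f"total_ctrl_{rep}"] = base * noise[0]
            row[f"polysome_ctrl_{rep}"] = base * noise[1]
            row[f"total_ko_{rep}"] = base * d_mrna * noise[2]
            row[f"polysome_ko_{rep}"] = base * d_mrna * d_te * noise[3]
        rows.append(row)
    fpkm = pd.DataFrame(rows)

    return SyntheticDataset(cfg, genome, models, tracks, fpkm, truth)


def worked_example_fixture(seed: int = 20240712) -> SyntheticDataset:
    """Deterministic 10-gene miniature dataset used in the documentation.

    One gene carries a canonical 5'UTR rG4 (bound, TE down), one is bound
    in the CDS, one carries a 3'UTR class-2 ARE (bound, mRNA down) and the
    rest are unbound controls.
    """
    cfg = SyntheticConfig(
        seed=seed, n_genes=10,
        n_utr5_rg4_bound=1, n_cds_bound=1, n_utr3_are_bound=1,
        utr5_len=80, cds_len=240, utr3_len=120, intron_len=100,
    )
    return generate(cfg)
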