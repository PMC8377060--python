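"""Join CLIP binding sites with structure annotations and TE categories.

This is the reporting layer: given shared binding sites assigned to
transcript regions, rG4/ARE annotations of the site sequences, and the
categorized expression table, it produces

* per-region and exclusive-region tallies of TE (and mRNA) categories,
* per-site rG4 subtype tallies split by the gene's TE/mRNA category,
* kernel density estimates of log2 fold changes per exclusive region
  class,
* a 9-cell divergence classification of TE vs mRNA changes, and
* folding-energy comparisons of focal gene sets against a sampled
  background of unbound, unchanged genes.

TE categories are per gene; rG4/ARE tallies are per binding site, so one
gene can contribute several sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .energy import (EnergyComparison, EnergyEngine, FoldingEnergyRecord,
                     compare_energy_sets, fold_energies, sample_background,
                     window_for_are)
from .intervals import SequenceRecord
from .peaks import BindingSite
from .rg4 import classify_region_sequence
from .are import scan_are
from .transcripts import TranscriptModel, extract_sense_sequence, representative_transcripts

MRNA_REGIONS = ["5'UTR", "CDS", "3'UTR", "intron"]
DIVERGENCE_THRESHOLD = 0.585  # log2 units, ~log2(1.5)


@dataclass
class IntegratedGeneRecord:
    gene_id: str
    bound: bool
    regions: frozenset[str] = frozenset()
    site_subtypes: list[tuple[str, str]] = field(default_factory=list)  # (region, subtype)
    are_classes: list[str] = field(default_factory=list)
    te_category: Optional[str] = None
    mrna_category: Optional[str] = None
    stringent: bool = False
    expressed: bool = False
    log2_delta_te: float = np.nan
    log2_delta_mrna: float = np.nan

    @property
    def only_region(self) -> Optional[str]:
        mr = self.regions & set(MRNA_REGIONS[:3])
        return next(iter(mr)) if len(mr) == 1 else None


def build_integrated_records(
    sites: Sequence[BindingSite],
    models: Sequence[TranscriptModel],
    genome: Mapping[str, SequenceRecord],
    te_table: pd.DataFrame,
    stringent_ids: Sequence[str] = (),
) -> dict[str, IntegratedGeneRecord]:
    """One record per gene in the expression table.

    ``sites`` must already carry region labels; each site is attributed to
    the gene whose representative transcript it overlaps, its sense-strand
    sequence is classified into an rG4 subtype (best subtype per site) and
    scanned for AREs.
    """
    reps = representative_transcripts(models)
    by_chrom: dict[str, list[tuple[str, TranscriptModel]]] = {}
    for gene, m in reps.items():
        by_chrom.setdefault(m.chrom, []).append((gene, m))

    def _clean_cat(v):
        return v if isinstance(v, str) else None

    records: dict[str, IntegratedGeneRecord] = {}
    for gene_id, row in te_table.iterrows():
        records[gene_id] = IntegratedGeneRecord(
            gene_id, False,
            te_category=_clean_cat(row.get("te_category")),
            mrna_category=_clean_cat(row.get("mrna_category")),
            stringent=gene_id in set(stringent_ids),
            expressed=bool(row.get("expressed", False)),
            log2_delta_te=float(row.get("log2_delta_te", np.nan)),
            log2_delta_mrna=float(row.get("log2_delta_mrna", np.nan)),
        )

    for site in sites:
        for gene, m in by_chrom.get(site.interval.chrom, []):
            lo = min(e.start for e in m.exons)
            hi = max(e.end for e in m.exons)
            if not (site.interval.start < hi and lo < site.interval.end):
                continue
            rec = records.setdefault(gene, IntegratedGeneRecord(gene, True))
            rec.bound = True
            label = site.region_label or "other"
            rec.regions = rec.regions | {label}
            iv = site.interval
            clipped = type(iv)(iv.chrom, max(iv.start, 0), min(iv.end, len(genome[iv.chrom])), m.strand)
            seq = extract_sense_sequence(clipped, genome)
            rec.site_subtypes.append((label, classify_region_sequence(seq)))
            for a in scan_are(seq):
                rec.are_classes.append(a.are_class)
    return records


# ------------------------------------------------------------------ tallies

def tally_by_region_and_category(records: Mapping[str, IntegratedGeneRecord],
                                 category_field: str = "te_category") -> dict:
    """Counts of up/down/unchanged genes per region and exclusive-region
    class, plus per-site rG4 subtype tallies split by gene category and
    ARE presence among 3'UTR-bound genes."""
    cats = ("up", "down", "unchanged")

    def _cat(rec) -> Optional[str]:
        v = getattr(rec, category_field)
        return v if isinstance(v, str) and v in cats else None

    region_tally = {r: {c: 0 for c in cats} for r in MRNA_REGIONS}
    only_tally = {r: {c: 0 for c in cats} for r in MRNA_REGIONS[:3]}
    subtype_tally: dict[str, dict[str, int]] = {}
    are_presence = {c: 0 for c in cats}

    for rec in records.values():
        if not (rec.bound and rec.expressed):
            continue
        c = _cat(rec)
        if c is None:
            continue
        for r in rec.regions & set(MRNA_REGIONS):
            region_tally[r][c] += 1
        if rec.only_region is not None:
            only_tally[rec.only_region][c] += 1
        for region, subtype in rec.site_subtypes:
            subtype_tally.setdefault(c, {}).setdefault(subtype, 0)
            subtype_tally[c][subtype] += 1
        if "3'UTR" in rec.regions and rec.are_classes:
            are_presence[c] += 1
    return {
        "per_region": region_tally,
        "only_region": only_tally,
        "site_subtypes_by_category": subtype_tally,
        "are_bound_3utr_by_category": are_presence,
    }


def delta_density_summary(records: Mapping[str, IntegratedGeneRecord],
                          value_field: str = "log2_delta_te",
                          grid: Optional[np.ndarray] = None,
                          min_genes: int = 5) -> dict[str, dict]:
    """Gaussian KDE (Scott's rule) of log2 fold changes per exclusive class."""
    if grid is None:
        grid = np.linspace(-4.0, 4.0, 513)
    out: dict[str, dict] = {}
    for region in MRNA_REGIONS[:3]:
        vals = np.array([
            getattr(r, value_field) for r in records.values()
            if r.bound and r.expressed and r.only_region == region
            and np.isfinite(getattr(r, value_field))
        ])
        if vals.size < min_genes:
            out[region] = {"skipped": True, "n": int(vals.size)}
            continue
        if np.allclose(vals, vals[0]):
            out[region] = {"skipped": True, "degenerate": True, "n": int(vals.size)}
            continue
        kde = stats.gaussian_kde(vals, bw_method="scott")
        dens = kde(grid)
        out[region] = {"skipped": False, "n": int(vals.size), "grid": grid,
                       "density": dens, "bandwidth": float(kde.factor)}
    return out


def divergence_classes(records: Mapping[str, IntegratedGeneRecord],
                       threshold: float = DIVERGENCE_THRESHOLD) -> pd.DataFrame:
    """9-cell TE-vs-mRNA classification of expressed genes.

    A change must exceed the threshold strictly; the constant band is
    closed.  Returns one row per gene with ``te_state``/``mrna_state`` in
    {up, constant, down} plus bound/stringent flags.
    """
    rows = []
    for rec in records.values():
        if not rec.expressed or not np.isfinite(rec.log2_delta_te):
            continue

        def _state(v: float) -> str:
            if v > threshold:
                return "up"
            if v < -threshold:
                return "down"
            return "constant"

        rows.append({
            "gene_id": rec.gene_id,
            "te_state": _state(rec.log2_delta_te),
            "mrna_state": _state(rec.log2_delta_mrna),
            "bound": rec.bound,
            "stringent": rec.stringent,
        })
    return pd.DataFrame(rows).set_index("gene_id") if rows else pd.DataFrame(
        columns=["te_state", "mrna_state", "bound", "stringent"])


# ----------------------------------------------------------------- energies

def utr5_windows(models: Sequence[TranscriptModel],
                 genome: Mapping[str, SequenceRecord],
                 genes: Sequence[str]) -> dict[str, SequenceRecord]:
    """Sense-strand 5'UTR sequences for the requested genes (>= 4 nt)."""
    reps = representative_transcripts(models)
    out = {}
    for g in genes:
        m = reps.get(g)
        if m is None or m.five_prime_utr is None:
            continue
        lo, hi = m.five_prime_utr
        if hi - lo < 4:
            continue
        seq = m.mature_sequence(genome).residues[lo:hi]
        out[g] = SequenceRecord(g, seq)
    return out


def are_windows(models: Sequence[TranscriptModel],
                genome: Mapping[str, SequenceRecord],
                genes: Sequence[str],
                extension: int = 30) -> dict[str, SequenceRecord]:
    """3'UTR ARE sites extended 30 nt both ways, one window per first hit."""
    reps = representative_transcripts(models)
    out = {}
    for g in genes:
        m = reps.get(g)
        if m is None or m.three_prime_utr is None:
            continue
        mature = m.mature_sequence(genome).residues
        lo, hi = m.three_prime_utr
        hits = scan_are(SequenceRecord(g, mature[lo:hi]))
        if not hits:
            continue
        span = (hits[0].start + lo, hits[0].end + lo)
        w = window_for_are(span, len(mature), extension)
        out[g] = SequenceRecord(g, mature[w[0]:w[1]])
    return out


def energy_report(
    focal_sets: Mapping[str, Sequence[str]],
    background_genes: Sequence[str],
    windows: Mapping[str, SequenceRecord],
    engine: EnergyEngine,
    n_background: int = 1000,
    seed: int = 0,
) -> dict[str, dict[str, EnergyComparison]]:
    """Mann-Whitney energy comparisons of each focal gene set vs background.

    ``windows`` maps gene id -> sequence window; energies are computed
    once per gene.  For each focal set two comparisons are reported on
    length-normalized values: ``dG_rG4`` (alternative: focal greater, more
    stable quadruplexes) and ``dG_dsRNA`` (alternative: focal lower, more
    stable duplexes).
    """
    bg = sample_background(list(background_genes), n=n_background, seed=seed)
    cache: dict[str, FoldingEnergyRecord] = {}

    def _energies(genes) -> list[FoldingEnergyRecord]:
        out = []
        for g in genes:
            if g not in windows:
                continue
            if g not in cache:
                cache[g] = fold_energies(windows[g], engine)
            out.append(cache[g])
        return out

    bg_rec = _energies(bg)
    report: dict[str, dict[str, EnergyComparison]] = {}
    for name, genes in focal_sets.items():
        foc = _energies(genes)
        if not foc or not bg_rec:
            continue
        report[name] = {
            "dG_rG4": compare_energy_sets(
                [r.dG_rG4_norm for r in foc], [r.dG_rG4_norm for r in bg_rec],
                alternative="focal_greater", focal_id=name),
            "dG_dsRNA": compare_energy_sets(
                [r.dG_dsRNA_norm for r in foc], [r.dG_dsRNA_norm for r in bg_rec],
                alternative="focal_lower", focal_id=name),
        }
    return report
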