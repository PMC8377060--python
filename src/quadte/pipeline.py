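"""End-to-end analysis: coverage -> peaks -> annotation -> TE integration.

`run_pipeline` consumes the five inputs (genome FASTA dict, transcript
models, two replicate coverage tracks, FPKM table) and returns a report
with shared binding sites, region tallies and densities, TE category
counts, divergence classes and folding-energy comparisons.  It is the
programmatic equivalent of running every stage in sequence and is what
the example scripts and the acceptance run drive.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import pandas as pd

from . import te as te_mod
from .energy import EnergyEngine, SimplifiedEngine
from .integrate import (build_integrated_records, delta_density_summary,
                        divergence_classes, energy_report,
                        tally_by_region_and_category, utr5_windows)
from .intervals import SequenceRecord
from .peaks import (annotate_sites, bin_coverage, call_peaks,
                    coverage_correlation, fit_ztnb, intersect_replicates,
                    region_density, shared_site_counts)
from .transcripts import TranscriptModel, representative_transcripts


def default_engine() -> EnergyEngine:
    """ViennaRNA when its bindings are importable, else the internal model."""
    try:
        from .energy import ViennaRNAEngine

        return ViennaRNAEngine()
    except ImportError:
        return SimplifiedEngine()


def call_replicate_peaks(track: pd.DataFrame, bin_size: int = 100,
                         alpha: float = 0.05):
    binned = bin_coverage(track, bin_size=bin_size)
    counts = [c for arr in binned.values() for c in arr[arr > 0]]
    model = fit_ztnb(counts)
    return call_peaks(binned, model, alpha=alpha, bin_size=bin_size), model


def run_pipeline(
    genome: Mapping[str, SequenceRecord],
    models: Sequence[TranscriptModel],
    track_rep1: pd.DataFrame,
    track_rep2: pd.DataFrame,
    fpkm: pd.DataFrame,
    bin_size: int = 100,
    alpha: float = 0.05,
    engine: Optional[EnergyEngine] = None,
    n_background: int = 1000,
    seed: int = 0,
) -> dict:
    engine = engine if engine is not None else default_engine()

    # 1. peak calling per replicate, replicate intersection
    sites1, model1 = call_replicate_peaks(track_rep1, bin_size, alpha)
    sites2, model2 = call_replicate_peaks(track_rep2, bin_size, alpha)
    shared = intersect_replicates(sites1, sites2)
    pcc = coverage_correlation(track_rep1, track_rep2)

    # 2. region annotation and density
    shared = annotate_sites(shared, models)
    density = region_density(shared, models)

    # 3. TE table
    tedf = te_mod.compute_te(fpkm)
    tedf = te_mod.consistency_filter(tedf)
    tedf = te_mod.categorize(tedf)
    stringent = te_mod.stringent_te_down(tedf)

    # 4. integration
    records = build_integrated_records(shared, models, genome, tedf, stringent)
    tallies_te = tally_by_region_and_category(records, "te_category")
    tallies_mrna = tally_by_region_and_category(records, "mrna_category")
    kde = delta_density_summary(records)
    div = divergence_classes(records)

    # 5. energy comparisons on 5'UTR windows
    utr5_bound = {
        cat: [g for g, r in records.items()
              if r.bound and r.expressed and "5'UTR" in r.regions and r.te_category == cat]
        for cat in ("up", "down")
    }
    background_pool = [
        g for g, r in records.items()
        if not r.bound and r.te_category == "unchanged" and r.mrna_category == "unchanged"
    ]
    reps = representative_transcripts(models)
    all_genes = [g for g in records if g in reps]
    windows = utr5_windows(models, genome, all_genes)
    energies = {}
    if background_pool:
        energies = energy_report(
            {f"te_{k}_5utr_bound": v for k, v in utr5_bound.items() if v},
            background_pool, windows, engine, n_background=n_background, seed=seed,
        )

    return {
        "sites_rep1": sites1,
        "sites_rep2": sites2,
        "shared_sites": shared,
        "replicate_pcc": pcc,
        "shared_site_counts": shared_site_counts(sites1, sites2),
        "ztnb_models": {"rep1": model1, "rep2": model2},
        "region_density": density,
        "te_table": tedf,
        "stringent_te_down": list(stringent),
        "records": records,
        "tallies_te": tallies_te,
        "tallies_mrna": tallies_mrna,
        "kde": kde,
        "divergence": div,
        "energy_report": energies,
    }
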