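"""ZTNB model, peak calling, replicate intersection, region assignment."""

import numpy as np
import pandas as pd
import pytest

from quadte.intervals import GenomicInterval
from quadte.peaks import (BindingSite, ZTNBModel, assign_region, bin_coverage,
                          call_peaks, coverage_correlation, fit_ztnb,
                          intersect_replicates, region_density,
                          shared_site_counts)
from quadte.transcripts import TranscriptModel


# ----------------------------------------------------------------- binning

def test_bin_coverage_uniform():
    tr = pd.DataFrame({"chrom": ["t"] * 3, "start": [0, 100, 200],
                       "end": [100, 200, 300], "value": [3, 3, 3]})
    assert bin_coverage(tr)["t"].tolist() == [3, 3, 3]


def test_bin_coverage_read_assignment():
    # a single 50-nt read starting at 120 lands in bin [100,200)
    tr = pd.DataFrame({"chrom": ["t"], "start": [120], "end": [170], "value": [1]})
    assert bin_coverage(tr, read_length=50)["t"].tolist() == [0, 1]


def test_bin_coverage_empty_and_errors():
    empty = pd.DataFrame(columns=["chrom", "start", "end", "value"])
    assert bin_coverage(empty) == {}
    bad = pd.DataFrame({"chrom": ["t"], "start": [0], "end": [10], "value": [-1]})
    with pytest.raises(ValueError):
        bin_coverage(bad)
    with pytest.raises(ValueError):
        bin_coverage(empty, bin_size=0)


# ---------------------------------------------------------------- ZTNB fit

def test_ztnb_parameter_recovery(rng):
    true = ZTNBModel(r=2.0, p=0.3, converged=True)
    sample = true.rvs(100_000, rng)
    m = fit_ztnb(sample)
    assert m.converged
    assert m.r == pytest.approx(2.0, rel=0.05)
    assert m.p == pytest.approx(0.3, rel=0.05)


def test_ztnb_pmf_normalizes(rng):
    m = fit_ztnb(ZTNBModel(r=1.5, p=0.4, converged=True).rvs(5000, rng))
    ks = np.arange(1, 10**6)
    assert m.pmf(ks).sum() == pytest.approx(1.0, abs=1e-9)
    # mean identity for the truncated distribution
    assert (ks * m.pmf(ks)).sum() == pytest.approx(m.mean, rel=1e-6)


def test_ztnb_degenerate_all_equal_falls_back():
    with pytest.warns(UserWarning):
        m = fit_ztnb([1] * 50)
    assert m.poisson_limit and m.converged
    assert m.pmf(np.arange(1, 100)).sum() == pytest.approx(1.0)


def test_ztnb_requires_positive_counts():
    with pytest.raises(ValueError):
        fit_ztnb([0, 1, 2] * 20)
    with pytest.raises(ValueError):
        fit_ztnb([1, 2, 3])  # too few


# -------------------------------------------------------------- peak calls

def test_planted_spike_called(rng):
    model = ZTNBModel(r=2.0, p=0.3, converged=True)
    counts = model.rvs(1000, rng)
    counts[500] = int(50 * counts.mean())
    sites = call_peaks({"c": counts}, model, alpha=0.05)
    assert any(s.interval.start <= 50_000 < s.interval.end for s in sites)


def test_alpha_zero_calls_nothing(rng):
    model = ZTNBModel(r=2.0, p=0.3, converged=True)
    counts = model.rvs(200, rng)
    assert call_peaks({"c": counts}, model, alpha=0.0) == []


def test_adjacent_significant_bins_merge():
    model = ZTNBModel(r=2.0, p=0.3, converged=True)
    counts = np.ones(10, dtype=int)
    counts[4] = counts[5] = 500
    sites = call_peaks({"c": counts}, model, alpha=0.05)
    assert len(sites) == 1
    assert (sites[0].interval.start, sites[0].interval.end) == (400, 600)
    assert sites[0].p_value == pytest.approx(float(model.sf(500)))


def test_null_false_positive_rate(rng):
    """At alpha=0.05, the called fraction under the null stays near 0.05."""
    model = ZTNBModel(r=2.0, p=0.3, converged=True)
    called = total = 0
    for _ in range(30):
        counts = model.rvs(500, rng)
        sig = model.sf(counts) < 0.05
        called += int(sig.sum())
        total += counts.size
    se = np.sqrt(0.05 * 0.95 / total)
    assert called / total <= 0.05 + 3 * se


# ------------------------------------------------------------- replicates

def _site(chrom, start, end, p=0.01, count=10):
    return BindingSite(GenomicInterval(chrom, start, end), count, p)


def test_intersect_identical_and_disjoint():
    a = [_site("c", 0, 100), _site("c", 300, 400)]
    assert len(intersect_replicates(a, a)) == 2
    b = [_site("c", 1000, 1100)]
    assert intersect_replicates(a, b) == []


def test_intersect_union_merge():
    a = [_site("c", 100, 200)]
    b = [_site("c", 150, 250)]
    shared = intersect_replicates(a, b)
    assert [(s.interval.start, s.interval.end) for s in shared] == [(100, 250)]
    assert shared[0].replicates == ("rep1", "rep2")


def test_intersect_symmetric_in_locus_count(rng):
    def random_sites():
        out, pos = [], 0
        for _ in range(12):
            pos += int(rng.integers(50, 400))
            ln = int(rng.integers(100, 300))
            out.append(_site("c", pos, pos + ln))
            pos += ln
        return out
    for _ in range(25):
        a, b = random_sites(), random_sites()
        ab = shared_site_counts(a, b)
        ba = shared_site_counts(b, a)
        assert ab["union_loci"] == ba["union_loci"]


def test_coverage_correlation_identical_tracks():
    tr = pd.DataFrame({"chrom": ["c"] * 3, "start": [0, 20_000, 40_000],
                       "end": [10_000, 30_000, 50_000], "value": [5, 2, 9]})
    assert coverage_correlation(tr, tr) == pytest.approx(1.0)


# ------------------------------------------------------------- annotation

def _coding_model():
    exons = [GenomicInterval("c", 0, 400, "+"), GenomicInterval("c", 600, 1000, "+")]
    return TranscriptModel("t", "g", "c", "+", exons, cds_span=(100, 900))


def test_assign_region_examples():
    m = _coding_model()
    assert assign_region(_site("c", 10, 90), [m]) == "5'UTR"
    # 60% CDS / 40% intron
    assert assign_region(_site("c", 340, 440), [m]) == "CDS"
    assert assign_region(_site("c", 450, 550), [m]) == "intron"
    assert assign_region(_site("other", 0, 100), [m]) == "other"


def test_region_density_arithmetic_and_scaling():
    m = _coding_model()
    sites = [_site("c", 0, 100).with_region("5'UTR") for _ in range(2)]
    dens = region_density(sites, [m])
    assert dens["5'UTR"] == pytest.approx(1000 * 2 / 100)  # 100-nt 5'UTR
    assert dens["CDS"] == 0.0
    # doubling region lengths halves density
    exons2 = [GenomicInterval("c", 0, 800, "+"), GenomicInterval("c", 1200, 2000, "+")]
    m2 = TranscriptModel("t", "g", "c", "+", exons2, cds_span=(200, 1800))
    assert region_density(sites, [m2])["5'UTR"] == pytest.approx(dens["5'UTR"] / 2)


def test_region_density_empty_region_is_missing():
    m = TranscriptModel("t", "g", "c", "+", [GenomicInterval("c", 0, 300, "+")])
    dens = region_density([], [m])
    assert dens["5'UTR"] is None  # noncoding models contribute no UTR length
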