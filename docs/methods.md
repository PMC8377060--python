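# Methods

## Coordinate model

All internal coordinates are 0-based half-open; GTF (1-based closed) is
converted at the I/O boundary only. Transcript models keep exons in
genomic order and derive mature (spliced, 5'→3' sense) coordinates; when a
CDS is present, 5'UTR + CDS + 3'UTR partition the mature transcript
exactly, and introns are the inter-exon gaps. Structure scanning always
operates on the sense-strand RNA sequence, since the targets (rG4s, AREs)
are mRNA elements; `T` is normalized to `U` on input and the ambiguity
code `N` matches no pattern.

## rG4 taxonomy

Four subtypes are recognized, ranked by predicted stability
(1 = most stable):

| rank | subtype | pattern |
|---|---|---|
| 1 | canonical | ≥4 G-tracts of ≥3 G, loops 1–7 nt |
| 2 | long-loop | canonical tracts, exactly one loop elongated: lateral (1st/3rd) 8–12 nt or central (2nd) 8–21 nt |
| 3 | bulge | three intact G≥3 tracts plus `GG H1–7 G` / `G H1–7 GG` (H ∈ {A,U,C}) at any tract position, loops 1–9 nt; or two `GGHG`/`GHGG` tracts at any two positions |
| 4 | two-quartet | ≥4 G-tracts of ≥2 G, loops 1–9 nt |

Design choices that the patterns alone do not fix:

* **Tract maximality.** Loops may contain G (a loop position is
  unconstrained), so without a tie-break a G6 run could be read as two G3
  tracts with a zero loop. A tract therefore must be a maximal G-run: the
  characters flanking it are non-G within the decomposition. This makes a
  poly-G region one site, not many.
* **Match semantics.** Scanning is leftmost and non-overlapping per
  subtype with lazy loop quantifiers; overlapping matches of different
  subtypes are clustered into loci, and each locus reports the
  highest-ranked subtype (the `all_matches` flag exposes every per-subtype
  match for BED-style output). Region-level classification
  (`classify_region_sequence`) reports the best subtype over the region,
  else `g_rich_50` when G content strictly exceeds 50%, else `other`.
* **Long-loop bounds.** The central loop class is 8–21 nt, lateral 8–12 nt,
  with exactly one loop long. For tandem arrays longer than four tracts
  the four-tract window is evaluated positionally.
* The motif-overlap rule used when intersecting rG4 sites with 18-nt
  CLIP motifs requires an overlap of more than 9 nt (i.e. ≥ 10).

Every pattern decision is locked by an independent brute-force oracle in
the test suite that enumerates tract/loop decompositions directly; the
two-quartet class is checked exhaustively over all 12-mers via their
G/non-G masks (the pattern constrains only those), the other classes on
10⁴ seeded random 30-mers.

## ARE classes

Class 1 covers dispersed `AUUUA` pentamers in a U-rich context. The
cluster-1 definition of the original ARE literature is not fully printed
anywhere accessible, so the detector is parameterized with explicit,
testable defaults: ≥ 2 non-overlapping pentamers within a 30-nt window of
U fraction ≥ 0.5 (window, count and fraction are arguments), plus the
AREsite2 W-patterns `WWUUUWW`, `WWWUUUWWW`, `WWWWUUUWWWW`. Class 2 is
`A(UUUA){2,5}` — the only geometry in which pentamers can overlap —
capped at five pentamers; pentamers inside such clusters do not also count
as "dispersed". Class 3 is a run of more than five U (≥ 6, read
strictly). Overlapping hits of different classes keep only the longest;
class-1/3 hits with an inter-gap ≤ 5 nt merge into one annotation.

## Folding energetics

For a window the statistic is the MFE gap
`dG_rG4 = dG_dsRNA − dG_dsRNA+rG4`, where the second term allows
quadruplex states. Because the G4-aware state space strictly contains the
duplex-only one, the gap is non-negative, and zero exactly when no
quadruplex improves the fold. Both MFEs are also reported divided by the
window length; for ARE windows (the ARE span ± 30 nt, clipped at
transcript bounds) normalization uses the extended-window length.

Two providers implement the engine contract `mfe(seq, g4_aware)`:

* **ViennaRNA** (Turner model, 37 °C, `dangles=2`, `noLP`, G4 states via
  the model's `gquad` flag) — the quantitative engine.
* **Internal simplified model** — base-pair maximization (AU/GC/GU,
  minimum hairpin loop 3) at a fixed energy per pair (−1 kcal/mol) plus a
  G4 state worth −3 kcal/mol per stacked quartet, where a span's quartet
  count is the shortest tract of its best exact decomposition (tracts ≥ 2,
  loops 1–7). Structures are non-crossing and G4 spans exclude their bases
  from pairing. The model is deliberately small enough that the test
  suite verifies its MFE against exhaustive structure enumeration for
  sequences up to 20 nt; scoring is per pair rather than per stack so the
  enumeration oracle stays elementary.

Gene-set comparisons use a one-tailed Mann–Whitney U test: exact null
distribution when min(n₁,n₂) ≤ 8 without ties, normal approximation with
tie correction otherwise; an all-identical pooled sample is reported as
P = 0.5 with a degenerate flag. The default alternatives are "focal more
stable": larger `dG_rG4`, more negative `dG_dsRNA`. The background set is
a seeded uniform sample (default n = 1000, or the whole pool with a
warning when smaller) from genes with no binding site and unchanged TE
and mRNA categories. Fold difference of means is reported, undefined
(None) when the background mean is zero — which is the expected outcome
for `dG_rG4` over clean synthetic backgrounds, where unbound genes have
no quadruplex potential at all.

## CLIP peak calling

Coverage is binned at 100 nt. A bedGraph segment contributes
value × overlap to each bin; the per-bin total is divided by the read
length when the track encodes reads (recovering counts by start position)
or by the bin size otherwise (mean coverage), then rounded. A single
zero-truncated negative binomial (ZTNB) is fit to the nonzero bin counts
by maximum likelihood (Nelder–Mead on (log r, logit p), method-of-moments
start); underdispersed samples (variance ≤ mean) fall back to a
zero-truncated Poisson, flagged. Each nonzero bin receives the upper-tail
probability of its count; bins below α = 0.05 become sites and adjacent
significant bins merge keeping the minimum P. P values are not
multiplicity-adjusted by default (a Benjamini–Hochberg flag exists).
Replicate QC reports the Pearson correlation of 10-kb binned coverage;
shared sites are the union spans of overlapping replicate sites, with
rep1-anchored, rep2-anchored and union-locus counts all emitted. Sites
are assigned to regions by majority overlap on each gene's representative
transcript (the longest mature one), ties broken
5'UTR > CDS > 3'UTR > intron; density is sites per 1000 nt of summed
region length, with the denominator restrictable to an expressed-gene
set.

Note that a fit to an observed track includes its enriched bins, so the
fitted dispersion on peak-bearing tracks is smaller (more overdispersed)
than the background truth; parameter-recovery checks therefore use
peak-free tracks.

## Translational efficiency

TE = FPKM(polysome)/FPKM(total) per condition; ΔTE = TE(KO)/TE(Ctrl).
The consistency filter keeps genes whose per-replicate ΔTE moves in the
same nonzero direction in both replicates; downstream values use
replicate-averaged FPKMs (inputs averaged before ratios). No pseudocounts:
zero-denominator genes are flagged and excluded, and their count is
carried in the output. Categories are inclusive at the printed bounds
(up ≥ 1.5, down ≤ 0.66, for TE and mRNA alike); the expressed filter is
averaged FPKM(total) > 1 in either condition; the stringent TE-down set
requires log2ΔTE < −1 strictly with |log2ΔFPKM(total)| ≤ 0.585. The
divergence classification places each expressed gene into one of 9 cells
by comparing |log2ΔTE| and |log2ΔFPKM| to 0.585 strictly, so the
"constant" band is closed, consistent with the inclusive 1.5-fold rule
(0.585 ≈ log2 1.5). A corollary of the consistency filter worth knowing:
genes whose TE is exactly flat in both replicates (sign 0) receive no
category at all, including no mRNA category.

## Integration

TE/mRNA categories are per gene; rG4 subtype and ARE tallies are per
binding site, so one gene can contribute several sites. Region tallies
are reported both per region (a gene bound in two regions appears in
both) and for exclusive single-region genes (disjoint classes). Kernel
density summaries of log2 fold changes per exclusive class use a Gaussian
KDE with Scott's-rule bandwidth on a fixed grid; classes with fewer than
5 genes or degenerate (constant) values are skipped with a note.

## Synthetic data

The generator emulates what the analysis assumes about real data: ZTNB
bin counts with a configurable empty-bin fraction, lognormal FPKMs with
multiplicative replicate noise, 1.5-fold-scale planted effects, and
transcripts with UTR/CDS/intron structure on both strands. Backgrounds
are uniform over {A,C,G,U} and rejection-sampled until no unplanned
rG4/ARE exists on either genomic strand or across splice junctions of the
mature sequence, so planted-recovery tests are exact rather than
probabilistic. Planted motifs are flanked by fixed non-extending bases so
the recorded span is exactly what the scanners should report. Peak bins
are shared between replicates (the locus) with independent count noise
(Poisson around enrichment × background mean).

Default scenario (the study conditions the pipeline is tested under):
200 genes; 40 bound in the 5'UTR with a canonical rG4 and planted
ΔTE = 0.4; 10 bound in the CDS with no structure effect; 10 bound in the
3'UTR with a class-2 ARE and planted ΔmRNA = 0.4; ZTNB(r = 2, p = 0.3)
background, 30% empty bins, 10× peak enrichment; FPKM baseline
lognormal(μ = 3, σ = 1), replicate noise σ = 0.1. Region lengths: 150-nt
5'UTR, 450-nt CDS split by one 200-nt intron, 300-nt 3'UTR; every fifth
gene on the minus strand. The CDS/3'UTR group sizes and region lengths
are the package's own choices of a small but realistic exercise of the
remaining region classes.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: read-level artifacts (duplicates, mapping bias,
crosslink-induced truncations), isoform mixtures, overlapping genes,
realistic genome-wide base composition (real backgrounds contain
incidental rG4s and AREs), correlated replicate noise, and library-size
effects on FPKM. The directional end-to-end findings on synthetic data
demonstrate that the machinery is wired correctly, not that the
biological effect sizes are realistic.

## Numerical and size choices

Test and acceptance problem sizes (10⁴ random 30-mers, 10⁵-count ZTNB
fits, 100 simulated tracks, 200-seed null uniformity, the 200-gene
end-to-end scenario) were chosen to make each statistical check decisive
at desk scale while keeping the whole suite fast. The ZTNB fit tolerance
(5% relative) reflects the sampling error of maximum likelihood at
n = 10⁵; the null false-positive tolerance is three binomial standard
errors. Seeds are fixed everywhere; identical inputs give identical
outputs throughout the package.
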