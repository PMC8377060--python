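"""RNA G-quadruplex (rG4) site prediction and subtype classification.

Four rG4 subtypes are recognized, ranked by predicted structural stability
(1 = most stable); when a locus matches several, the highest-ranked wins:

1. ``canonical``   — four or more G-tracts of >=3 Gs, all loops 1-7 nt.
2. ``long_loop``   — canonical tracts but exactly one loop elongated:
                     a lateral (1st/3rd) loop of 8-12 nt or the central
                     (2nd) loop of 8-21 nt; the other loops stay 1-7 nt.
3. ``bulge``       — three intact G>=3 tracts plus one tract carrying a
                     1-7 nt non-G bulge (GG-H(1-7)-G or G-H(1-7)-GG,
                     H in {A,U,C}), loops 1-9 nt; or two tracts each with
                     a single 1-nt bulge (GGHG / GHGG), loops 1-9 nt.
4. ``two_quartet`` — four or more G-tracts of only 2 Gs, loops 1-9 nt.

Two fallback labels exist for region-level classification only:
``g_rich_50`` (G content strictly above 50% but no subtype match) and
``other``.

G-tracts are maximal: a tract may not be extended by an adjacent G within
the same decomposition, so a G6 run is one tract, never two G3 tracts with
a zero-length loop.  Loops may contain Gs (shorter runs that are not used
as tracts).  The ambiguity code N matches nothing.

Scanning is leftmost and non-overlapping per subtype, with loop
quantifiers lazy (shortest loops preferred) so a poly-G region reports one
site rather than many.  Overlapping matches of different subtypes are
clustered into loci and each locus yields exactly one annotation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .intervals import SequenceRecord

SUBTYPE_RANK = {"canonical": 1, "long_loop": 2, "bulge": 3, "two_quartet": 4}
FALLBACK_LABELS = ("g_rich_50", "other")

# tract pieces; lookarounds enforce tract maximality (no flanking G)
_T3 = r"(?<!G)G{3,}(?!G)"
_T2 = r"(?<!G)G{2,}(?!G)"
# bulged composites: lookarounds on the composite boundaries, H = A/U/C
_B = r"(?:(?<!G)GG[AUC]{1,7}?G(?!G)|(?<!G)G[AUC]{1,7}?GG(?!G))"
_B1 = r"(?:(?<!G)GG[AUC]G(?!G)|(?<!G)G[AUC]GG(?!G))"


def _loop(lo: int, hi: int) -> str:
    return rf"[ACGU]{{{lo},{hi}}}?"


def _chain(parts: list[str]) -> str:
    return "".join(parts)


def _build_patterns() -> dict[str, re.Pattern]:
    L17, L19 = _loop(1, 7), _loop(1, 9)
    canonical = rf"{_T3}(?:{L17}{_T3}){{3,}}"
    long_loop = "|".join(
        _chain([_T3, loops[0], _T3, loops[1], _T3, loops[2], _T3])
        for loops in (
            (_loop(8, 12), L17, L17),   # first lateral loop long
            (L17, _loop(8, 21), L17),   # central loop long
            (L17, L17, _loop(8, 12)),   # last lateral loop long
        )
    )
    # one 1-7 nt bulge in any one tract position
    bulge_alts = []
    for j in range(4):
        parts = []
        for i in range(4):
            parts.append(_B if i == j else _T3)
            if i < 3:
                parts.append(L19)
        bulge_alts.append(_chain(parts))
    # two single-nt bulges in any two tract positions
    for j in range(4):
        for k in range(j + 1, 4):
            parts = []
            for i in range(4):
                parts.append(_B1 if i in (j, k) else _T3)
                if i < 3:
                    parts.append(L19)
            bulge_alts.append(_chain(parts))
    bulge = "|".join(bulge_alts)
    two_quartet = rf"{_T2}(?:{L19}{_T2}){{3,}}"
    return {
        "canonical": re.compile(canonical),
        "long_loop": re.compile(long_loop),
        "bulge": re.compile(bulge),
        "two_quartet": re.compile(two_quartet),
    }


_PATTERNS = _build_patterns()


@dataclass(frozen=True)
class RG4Annotation:
    seq_id: str
    start: int
    end: int
    subtype: str
    matched: str
    g_content: float

    @property
    def stability_rank(self) -> int:
        return SUBTYPE_RANK[self.subtype]

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


def _subtype_matches(seq: str) -> list[tuple[int, int, str]]:
    """Leftmost non-overlapping matches of every subtype, as (start, end, subtype)."""
    out = []
    for subtype, pat in _PATTERNS.items():
        for m in pat.finditer(seq):
            out.append((m.start(), m.end(), subtype))
    return out


def scan_rg4(seq: SequenceRecord, all_matches: bool = False) -> list[RG4Annotation]:
    """Predict rG4 sites in a sense-strand RNA sequence.

    Overlapping matches of different subtypes form one locus and report the
    highest-stability subtype; with ``all_matches=True`` every per-subtype
    match is returned instead (for BED-style output).
    """
    s = seq.residues
    hits = _subtype_matches(s)
    if all_matches:
        return [
            RG4Annotation(seq.id, a, b, st, s[a:b], s[a:b].count("G") / (b - a))
            for a, b, st in sorted(hits, key=lambda h: (h[0], SUBTYPE_RANK[h[2]]))
        ]
    # cluster overlapping spans into loci
    hits.sort(key=lambda h: (h[0], h[1]))
    out: list[RG4Annotation] = []
    cluster: list[tuple[int, int, str]] = []
    cluster_end = -1
    for h in hits + [(-1, -1, "")]:  # sentinel flushes the last cluster
        if cluster and (h[0] < 0 or h[0] >= cluster_end):
            a, b, st = min(cluster, key=lambda c: (SUBTYPE_RANK[c[2]], c[0], c[1]))
            out.append(RG4Annotation(seq.id, a, b, st, s[a:b], s[a:b].count("G") / (b - a)))
            cluster = []
            cluster_end = -1
        if h[0] >= 0:
            cluster.append(h)
            cluster_end = max(cluster_end, h[1])
    return out


def classify_region_sequence(seq: SequenceRecord) -> str:
    """Single label for a whole region: best rG4 subtype, else G-rich, else other.

    ``g_rich_50`` requires G content strictly above 50%.
    """
    sites = scan_rg4(seq)
    if sites:
        return min(sites, key=lambda a: a.stability_rank).subtype
    g_frac = seq.residues.count("G") / len(seq)
    return "g_rich_50" if g_frac > 0.5 else "other"


def motif_rg4_overlap(rg4_span: tuple[int, int], motif_span: tuple[int, int]) -> bool:
    """True when the rG4 site overlaps the (18-nt) motif by more than 9 nt."""
    lo = max(rg4_span[0], motif_span[0])
    hi = min(rg4_span[1], motif_span[1])
    return (hi - lo) >= 10
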