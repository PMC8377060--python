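"""AU-rich element (ARE) detection in three classes.

* class 1 — AUUUA pentamers dispersed in a U-rich context, plus the
  AREsite2-style W-patterns ``WWUUUWW``, ``WWWUUUWWW`` and ``WWWWUUUWWWW``
  (W = A or U).
* class 2 — two to five overlapping AUUUA pentamers; overlapping pentamers
  share their bridging A, i.e. ``A(UUUA){2,5}``.  Runs longer than five
  pentamers are capped at five.
* class 3 — U-rich runs: more than five consecutive Us (>=6).

When one locus matches several categories the shorter hit is removed, and
class-1/class-3 hits within 5 nt of each other (inter-gap <= 5) are merged
into a single annotation.  Class 2 never participates in the merge.

The dispersed-AUUUA detector for class 1 is parameterized: by default it
requires at least ``min_pentamers`` (2) non-overlapping AUUUA pentamers
inside a ``window`` (30 nt) whose U fraction is at least ``u_fraction``
(0.5); the annotated span runs from the first to the last such pentamer.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .intervals import SequenceRecord

_CLASS1_W = [re.compile(rf"[AU]{{{k}}}UUU[AU]{{{k}}}") for k in (4, 3, 2)]  # longest first
_CLASS2 = re.compile(r"A(?:UUUA){2,5}")
_CLASS3 = re.compile(r"U{6,}")
_PENTAMER = re.compile(r"AUUUA")

MERGE_GAP = 5  # nt; "within 5 nt"


@dataclass(frozen=True)
class AREAnnotation:
    seq_id: str
    start: int
    end: int
    are_class: str  # class1 | class2 | class3 | merged
    matched: str
    constituents: tuple[str, ...] = field(default_factory=tuple)

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


def _overlapped_matches(pat: re.Pattern, s: str) -> list[tuple[int, int]]:
    """All matches, allowing overlaps (restart one past each match start)."""
    out, i = [], 0
    while True:
        m = pat.search(s, i)
        if m is None:
            return out
        out.append((m.start(), m.end()))
        i = m.start() + 1


def _dispersed_class1(s: str, window: int, min_pentamers: int, u_fraction: float,
                      exclude: list[tuple[int, int]]):
    """Spans of >= min_pentamers non-overlapping AUUUA within a U-rich window.

    Pentamers inside ``exclude`` spans (overlapping-pentamer clusters, which
    are class 2 by definition) do not count as dispersed.
    """
    pentamers = []
    i = 0
    while True:  # non-overlapping, leftmost
        m = _PENTAMER.search(s, i)
        if m is None:
            break
        if not any(m.start() < b and a < m.end() for a, b in exclude):
            pentamers.append((m.start(), m.end()))
        i = m.end()
    spans = []
    n = len(pentamers)
    for a in range(n):
        for b in range(a + min_pentamers - 1, n):
            lo, hi = pentamers[a][0], pentamers[b][1]
            if hi - lo > window:
                break
            ctx = s[lo:hi]
            if ctx.count("U") / len(ctx) >= u_fraction:
                spans.append((lo, hi))
    return spans


def _drop_contained(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    keep = []
    for sp in sorted(set(spans), key=lambda t: (t[0], -t[1])):
        if not any(sp[0] >= a and sp[1] <= b and sp != (a, b) for a, b in keep):
            keep.append(sp)
    return keep


def scan_are(
    seq: SequenceRecord,
    window: int = 30,
    min_pentamers: int = 2,
    u_fraction: float = 0.5,
) -> list[AREAnnotation]:
    """Detect AREs of all three classes, deduplicate and merge.

    Returns annotations sorted by span; class-1/class-3 spans in the output
    are pairwise separated by more than 5 nt (merged otherwise).
    """
    s = seq.residues
    c2 = [(m.start(), m.end()) for m in _CLASS2.finditer(s)]
    c1 = [sp for pat in _CLASS1_W for sp in _overlapped_matches(pat, s)]
    c1 += _dispersed_class1(s, window, min_pentamers, u_fraction, c2)
    raw = [(a, b, "class1") for a, b in _drop_contained(c1)]
    raw += [(a, b, "class2") for a, b in c2]
    raw += [(m.start(), m.end(), "class3") for m in _CLASS3.finditer(s)]
    hits = [AREAnnotation(seq.id, a, b, cls, s[a:b]) for a, b, cls in sorted(raw)]
    out = dedup_and_merge(hits)
    # fill matched text for spans assembled during the merge
    return [
        h if h.matched == s[h.start:h.end]
        else AREAnnotation(h.seq_id, h.start, h.end, h.are_class, s[h.start:h.end], h.constituents)
        for h in out
    ]


def dedup_and_merge(hits: list[AREAnnotation]) -> list[AREAnnotation]:
    """Drop shorter multi-category overlaps, then merge nearby class-1/3 hits.

    ``hits`` must be sorted by span.  Where hits from different categories
    overlap only the longest survives (ties: earliest start).  Surviving
    class-1 and class-3 spans with an inter-gap of at most 5 nt become one
    annotation recording its constituent classes; mixed-class merges are
    labeled ``merged``, single-class merges keep their class.  Class 2 is
    never merged.
    """
    kept: list[AREAnnotation | None] = []
    for h in hits:
        drop = False
        for i, k in enumerate(kept):
            if k is None:
                continue
            if h.start < k.end and k.start < h.end and h.are_class != k.are_class:
                if (h.end - h.start, -h.start) > (k.end - k.start, -k.start):
                    kept[i] = None
                else:
                    drop = True
        if not drop:
            kept.append(h)
    survivors = sorted((k for k in kept if k is not None), key=lambda h: (h.start, h.end))

    out: list[AREAnnotation] = []
    pending: list[AREAnnotation] = []

    def _flush() -> None:
        if not pending:
            return
        if len(pending) == 1:
            out.append(pending[0])
        else:
            classes = tuple(p.are_class for p in pending)
            label = classes[0] if len(set(classes)) == 1 else "merged"
            lo, hi = pending[0].start, max(p.end for p in pending)
            out.append(AREAnnotation(pending[0].seq_id, lo, hi, label, "", classes))
        pending.clear()

    for h in survivors:
        if h.are_class == "class2":
            out.append(h)
            continue
        if pending and h.start - max(p.end for p in pending) <= MERGE_GAP:
            pending.append(h)
        else:
            _flush()
            pending.append(h)
    _flush()
    out.sort(key=lambda h: (h.start, h.end))
    return out
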