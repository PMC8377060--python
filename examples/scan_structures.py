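"""Scan sequences for rG4 subtypes and AU-rich elements.

Builds a few hand-written RNA sequences, runs both scanners and prints
the annotated spans.  The rG4 subtype reported for a locus is always the
highest-stability pattern that matches there (canonical > long-loop >
bulge > two-quartet); AREs of classes 1 and 3 lying within 5 nt of each
other are merged.
"""

from quadte import SequenceRecord, classify_region_sequence, scan_are, scan_rg4

examples = {
    "canonical_rg4": "AUCGGGAGGGAGGGAGGGCUAA",
    "bulged_rg4": "AAGGGAGGGAGGAGAGGGCA",
    "two_quartet": "CAGGAGGAGGAGGAC",
    "class2_are": "GCAUUUAUUUAUUUACG",
    "are_pair_merged": "CCAAUUUAACCCUUUUUUCC",
    "plain": "AUCAUCAUCAUCAUC",
}

for name, seq in examples.items():
    rec = SequenceRecord(name, seq)
    rg4 = scan_rg4(rec)
    are = scan_are(rec)
    print(f"{name:18s} {seq}")
    for a in rg4:
        print(f"    rG4 {a.subtype:12s} span={a.span} matched={a.matched}")
    for a in are:
        print(f"    ARE {a.are_class:12s} span={a.span} matched={a.matched}")
    if not rg4 and not are:
        print(f"    no structure; region label = {classify_region_sequence(rec)}")
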