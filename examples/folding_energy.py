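"""Quadruplex vs duplex folding energetics for a 5'UTR-like window.

Computes, with both energy providers, the duplex-only MFE, the G4-aware
MFE and their gap dG_rG4 = dG_dsRNA - dG_dsRNA+rG4 (>= 0 by construction:
allowing quadruplex states can only lower the minimum).  A positive gap
means a quadruplex is part of the optimal fold; windows without usable
G-tracts give a gap of exactly zero.
"""

from quadte import SequenceRecord, SimplifiedEngine, compare_energy_sets, fold_energies

g4_window = SequenceRecord("g4_utr", "ACUGGGAGGGAGGGAGGGUACUCAAUCCAGUA")
plain_window = SequenceRecord("plain_utr", "ACUAUCAUCAUGAUGAUUACUCAAUCCAGUA")

engines = {"internal": SimplifiedEngine()}
try:
    from quadte import ViennaRNAEngine

    engines["vienna"] = ViennaRNAEngine()
except ImportError:
    pass

for name, engine in engines.items():
    for rec in (g4_window, plain_window):
        r = fold_energies(rec, engine)
        print(f"{name:9s} {rec.id:10s} dG_dsRNA={r.dG_dsRNA:7.2f}  "
              f"dG_dsRNA+rG4={r.dG_dsRNA_plus_rG4:7.2f}  dG_rG4={r.dG_rG4:6.2f} "
              f"(per nt: {r.dG_rG4_norm:.3f})")

# a one-tailed Mann-Whitney comparison of two small energy sets: the exact
# P for {1,2,3} vs {4,5,6} with the 'focal lower' alternative is 1/20
c = compare_energy_sets([1, 2, 3], [4, 5, 6], alternative="focal_lower")
print(f"\nMann-Whitney focal {{1,2,3}} vs background {{4,5,6}}: P = {c.p_value:.3f}")
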