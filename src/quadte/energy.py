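"""Folding energetics: rG4 vs duplex (dsRNA) minimum free energies.

For a sequence window the quantity of interest is the MFE gap

    dG_rG4 = dG_dsRNA - dG_dsRNA+rG4

where ``dG_dsRNA`` is the MFE of ordinary secondary structure and
``dG_dsRNA+rG4`` the MFE when G-quadruplex states are allowed as well.
Because the G4-aware state space contains every duplex-only structure,
``dG_rG4 >= 0`` always, and it is 0 exactly when no quadruplex improves the
fold.  Both MFEs are also reported normalized by the window length.

Two interchangeable energy providers ship:

* :class:`ViennaRNAEngine` — Turner-model MFE via the ViennaRNA bindings
  (37 C, ``-d2 --noLP``, G4 support through the model's ``gquad`` flag).
* :class:`SimplifiedEngine` — a hermetic toy model: base-pair maximization
  (AU/GC/GU pairs, minimum hairpin loop 3, fixed energy per pair) plus an
  optional G4 state worth a fixed bonus per stacked quartet.  Small enough
  to verify against exhaustive structure enumeration.

Gene-set comparisons use a one-tailed Mann-Whitney U test, exact for small
samples and normal-approximated with tie correction otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Protocol, Sequence

import numpy as np
from scipy import stats

from .intervals import SequenceRecord


class EnergyEngine(Protocol):
    def mfe(self, seq: str, g4_aware: bool) -> float:
        """Minimum free energy (kcal/mol) of ``seq``; RNA alphabet."""


@dataclass(frozen=True)
class FoldingEnergyRecord:
    seq_id: str
    length: int
    dG_dsRNA: float
    dG_dsRNA_plus_rG4: float

    @property
    def dG_rG4(self) -> float:
        return self.dG_dsRNA - self.dG_dsRNA_plus_rG4

    @property
    def dG_dsRNA_norm(self) -> float:
        return self.dG_dsRNA / self.length

    @property
    def dG_dsRNA_plus_rG4_norm(self) -> float:
        return self.dG_dsRNA_plus_rG4 / self.length

    @property
    def dG_rG4_norm(self) -> float:
        return self.dG_rG4 / self.length


@dataclass(frozen=True)
class EnergyComparison:
    focal_id: str
    background_id: str
    n_focal: int
    n_background: int
    mean_focal: float
    mean_background: float
    fold_difference: Optional[float]  # mean(focal)/mean(background); None if bg mean 0
    U: float
    p_value: float
    alternative: str
    degenerate: bool = False


# ----------------------------------------------------------------- engines

class ViennaRNAEngine:
    """Turner-model MFE via ViennaRNA (37 C, dangles=2, noLP).

    G4-aware folding toggles the model's ``gquad`` flag.
    """

    def __init__(self, temperature: float = 37.0):
        import RNA  # deferred: optional dependency

        self._RNA = RNA
        self.temperature = temperature

    def mfe(self, seq: str, g4_aware: bool) -> float:
        RNA = self._RNA
        md = RNA.md()
        md.temperature = self.temperature
        md.dangles = 2
        md.noLP = 1
        md.gquad = 1 if g4_aware else 0
        fc = RNA.fold_compound(seq, md)
        _, e = fc.mfe()
        return float(e)


_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def g4_quartets(s: str, min_tract: int = 2, max_loop: int = 7) -> int:
    """Stacked-quartet count of the best exact G4 decomposition of ``s``.

    A decomposition is four G-tracts (each >= ``min_tract``) separated by
    three loops of 1..``max_loop`` nt, covering ``s`` exactly; its quartet
    count is the shortest tract.  Returns 0 when no decomposition exists.
    """
    n = len(s)
    best = 0

    def rec(i: int, tracts_left: int, shortest: int) -> None:
        nonlocal best
        run = 0
        while i + run < n and s[i + run] == "G":
            run += 1
        for tl in range(min_tract, run + 1):
            j = i + tl
            cur = min(shortest, tl)
            if tracts_left == 1:
                if j == n:
                    best = max(best, cur)
            else:
                for ll in range(1, max_loop + 1):
                    if j + ll < n:
                        rec(j + ll, tracts_left - 1, cur)
        return

    rec(0, 4, 10**9)
    return best


class SimplifiedEngine:
    """Base-pair-maximization model with an optional quadruplex state.

    Every base pair (AU, GC, GU; hairpin loops >= 3 nt) contributes
    ``pair_energy``; a G4 state over a span contributes
    ``quartet_energy * quartets`` for the span's best decomposition.
    Structures are non-crossing; G4 spans exclude their bases from pairing.
    """

    def __init__(self, pair_energy: float = -1.0, quartet_energy: float = -3.0,
                 min_hairpin: int = 3):
        self.pair_energy = pair_energy
        self.quartet_energy = quartet_energy
        self.min_hairpin = min_hairpin

    def mfe(self, seq: str, g4_aware: bool) -> float:
        s = seq
        n = len(s)
        g4e = {}
        if g4_aware:
            # candidate G4 spans: length between 11 (4*2+3) and full window
            for i in range(n):
                if s[i] != "G":
                    continue
                for j in range(i + 11, n + 1):
                    q = g4_quartets(s[i:j])
                    if q:
                        g4e[(i, j)] = self.quartet_energy * q
        W = [[0.0] * (n + 1) for _ in range(n + 1)]  # W[i][j] over s[i:j]
        for span in range(2, n + 1):
            for i in range(0, n - span + 1):
                j = i + span  # exclusive
                e = W[i][j - 1]
                last = s[j - 1]
                for k in range(i, j - 1):
                    if (s[k], last) in _PAIRS and (j - 1) - k > self.min_hairpin:
                        cand = self.pair_energy + W[i][k] + W[k + 1][j - 1]
                        e = min(e, cand)
                for (a, b), ge in g4e.items():
                    if b == j and a >= i:
                        e = min(e, W[i][a] + ge)
                W[i][j] = e
        return W[0][n]


# ------------------------------------------------------------- record level

def fold_energies(seq: SequenceRecord, engine: EnergyEngine) -> FoldingEnergyRecord:
    """Duplex-only and G4-aware MFEs for one window, plus the rG4 gap."""
    if len(seq) < 4:
        raise ValueError(f"{seq.id}: sequence shorter than 4 nt")
    try:
        ds = engine.mfe(seq.residues, g4_aware=False)
        both = engine.mfe(seq.residues, g4_aware=True)
    except Exception as exc:
        raise RuntimeError(f"folding engine failed on {seq.id!r}: {exc}") from exc
    return FoldingEnergyRecord(seq.id, len(seq), ds, both)


def window_for_are(span: tuple[int, int], transcript_length: int,
                   extension: int = 30) -> tuple[int, int]:
    """ARE span extended ``extension`` nt both ways, clipped to the transcript."""
    return (max(0, span[0] - extension), min(transcript_length, span[1] + extension))


def sample_background(genes: Sequence[str], n: int = 1000,
                      seed: int | np.random.Generator = 0) -> list[str]:
    """Uniform sample of background gene ids, without replacement, seeded.

    Callers supply the eligibility filter (no binding site, TE and mRNA
    unchanged).  If fewer than ``n`` candidates exist, all are returned with
    a warning.
    """
    if len(genes) == 0:
        raise ValueError("empty background candidate pool")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if len(genes) <= n:
        if len(genes) < n:
            warnings.warn(f"background pool {len(genes)} smaller than requested {n}")
        return list(genes)
    idx = rng.choice(len(genes), size=n, replace=False)
    return [genes[i] for i in sorted(idx)]


def compare_energy_sets(
    focal: Sequence[float],
    background: Sequence[float],
    alternative: str = "focal_lower",
    focal_id: str = "focal",
    background_id: str = "background",
) -> EnergyComparison:
    """One-tailed Mann-Whitney comparison of two energy sets.

    ``alternative='focal_lower'`` tests whether focal values are
    stochastically smaller (more negative = more stable, or a larger rG4
    gap when the inputs are gaps and 'focal_greater' is chosen).  The exact
    null distribution is used when min(n1, n2) <= 8 and there are no ties;
    otherwise the normal approximation with tie correction.
    """
    x = np.asarray(focal, dtype=float)
    y = np.asarray(background, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both sets must be nonempty")
    mean_x, mean_y = float(x.mean()), float(y.mean())
    fold = None if mean_y == 0 else mean_x / mean_y
    alt = {"focal_lower": "less", "focal_greater": "greater"}[alternative]
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return EnergyComparison(focal_id, background_id, x.size, y.size,
                                mean_x, mean_y, fold, x.size * y.size / 2.0,
                                0.5, alternative, degenerate=True)
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (min(x.size, y.size) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alt, method=method)
    return EnergyComparison(focal_id, background_id, x.size, y.size,
                            mean_x, mean_y, fold, float(res.statistic),
                            float(res.pvalue), alternative)
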