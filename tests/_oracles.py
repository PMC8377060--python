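"""Independent brute-force oracles used to validate the main implementations.

Each oracle is written against the *definitions* (tract/loop decompositions,
interval arithmetic, structure enumeration, rank-statistic enumeration) and
shares no code path with the scanners/engines it checks.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

# --------------------------------------------------------------- rG4 oracle

RANK_ORDER = ["canonical", "long_loop", "bulge", "two_quartet"]


def _g_runs(s: str, min_len: int) -> list[tuple[int, int]]:
    runs, i, n = [], 0, len(s)
    while i < n:
        if s[i] == "G":
            j = i
            while j < n and s[j] == "G":
                j += 1
            if j - i >= min_len:
                runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def _bulged_composites(s: str, max_bulge: int) -> list[tuple[int, int]]:
    """Spans of GG-H(1..b)-G and G-H(1..b)-GG composites with non-G flanks."""
    out = []
    n = len(s)
    H = set("AUC")
    for i in range(n):
        if i > 0 and s[i - 1] == "G":
            continue
        for b in range(1, max_bulge + 1):
            # GG H{b} G
            e = i + 3 + b
            if e <= n and s[i:i + 2] == "GG" and s[i + 2] != "G" \
                    and all(c in H for c in s[i + 2:i + 2 + b]) and s[e - 1] == "G" \
                    and (e == n or s[e] != "G"):
                out.append((i, e))
            # G H{b} GG
            if e <= n and s[i] == "G" and s[i + 1] != "G" \
                    and all(c in H for c in s[i + 1:i + 1 + b]) and s[i + 1 + b:e] == "GG" \
                    and (e == n or s[e] != "G"):
                out.append((i, e))
    return sorted(set(out))


def _chains(elements: list[list[tuple[int, int]]], gaps: list[tuple[int, int]], s: str):
    """All exactly-4-element chains with per-position elements and gap bounds;
    the gap text may not contain N (N matches nothing)."""
    out = []

    def rec(pos: int, chain: list[tuple[int, int]]):
        if pos == 4:
            out.append((chain[0][0], chain[-1][1]))
            return
        for el in elements[pos]:
            if pos == 0:
                rec(1, [el])
            else:
                gap = el[0] - chain[-1][1]
                lo, hi = gaps[pos - 1]
                if lo <= gap <= hi and "N" not in s[chain[-1][1]:el[0]]:
                    rec(pos + 1, chain + [el])
    rec(0, [])
    return sorted(set(out))


def _chains_ge4(elements: list[tuple[int, int]], gap: tuple[int, int], s: str):
    """Spans of chains of four OR MORE identical-class tracts (open-ended
    repetition), every consecutive gap within bounds and N-free."""
    out = set()
    lo, hi = gap

    def rec(chain: list[tuple[int, int]]):
        if len(chain) >= 4:
            out.add((chain[0][0], chain[-1][1]))
        for el in elements:
            if el[0] <= chain[-1][1]:
                continue
            g = el[0] - chain[-1][1]
            if lo <= g <= hi and "N" not in s[chain[-1][1]:el[0]]:
                rec(chain + [el])
    for el in elements:
        rec([el])
    return sorted(out)


def oracle_spans(s: str, subtype: str) -> list[tuple[int, int]]:
    """All spans of ``s`` admitting a decomposition of the given subtype."""
    r3 = _g_runs(s, 3)
    r2 = _g_runs(s, 2)
    if subtype == "canonical":
        return _chains_ge4(r3, (1, 7), s)
    if subtype == "two_quartet":
        return _chains_ge4(r2, (1, 9), s)
    if subtype == "long_loop":
        spans = []
        for gaps in ([(8, 12), (1, 7), (1, 7)], [(1, 7), (8, 21), (1, 7)],
                     [(1, 7), (1, 7), (8, 12)]):
            spans += _chains([r3] * 4, gaps, s)
        return sorted(set(spans))
    if subtype == "bulge":
        spans = []
        b7 = _bulged_composites(s, 7)
        b1 = _bulged_composites(s, 1)
        for j in range(4):  # one 1-7 nt bulge at any tract position
            elements = [b7 if i == j else r3 for i in range(4)]
            spans += _chains(elements, [(1, 9)] * 3, s)
        for j, k in itertools.combinations(range(4), 2):  # two 1-nt bulges
            elements = [b1 if i in (j, k) else r3 for i in range(4)]
            spans += _chains(elements, [(1, 9)] * 3, s)
        return sorted(set(spans))
    raise ValueError(subtype)


def oracle_region_label(s: str) -> str:
    """Whole-region label: best-rank subtype with a decomposition, else
    G-content fallback."""
    for subtype in RANK_ORDER:
        if oracle_spans(s, subtype):
            return subtype
    return "g_rich_50" if s.count("G") / len(s) > 0.5 else "other"


# ------------------------------------------------- multi-subtype constructor

def build_multimatch(rng) -> tuple[str, str]:
    """Random sequence whose single locus matches >=2 subtypes; returns
    (sequence, highest-stability subtype it should report).

    Every construction also satisfies the two-quartet pattern, so at least
    two subtypes match by design.
    """
    loop_chars = "AUC"

    def loops(n, lo, hi):
        return ["".join(rng.choice(list(loop_chars), size=rng.integers(lo, hi + 1)))
                for _ in range(n)]

    kind = rng.choice(["canonical", "long_loop", "bulge"])
    if kind == "canonical":
        l = loops(3, 1, 7)
        seq = "GGG" + l[0] + "GGG" + l[1] + "GGG" + l[2] + "GGG"
    elif kind == "long_loop":
        l = loops(2, 1, 7)
        long = "".join(rng.choice(list(loop_chars), size=rng.integers(8, 10)))
        parts = [l[0], long, l[1]]
        rng.shuffle(parts)  # long loop at a random position (8-9 nt: lateral or central ok)
        seq = "GGG" + parts[0] + "GGG" + parts[1] + "GGG" + parts[2] + "GGG"
    else:  # bulge with a single 1-nt bulged tract; loops short enough that
        # the flanking G2 sub-runs still chain as two-quartet
        l = loops(3, 1, 7)
        comp = rng.choice(["GGAG", "GAGG", "GGUG", "GUGG"])
        pos = rng.integers(0, 4)
        tracts = ["GGG"] * 4
        tracts[pos] = comp
        seq = tracts[0] + l[0] + tracts[1] + l[1] + tracts[2] + l[2] + tracts[3]
    return seq, kind


# --------------------------------------------------------------- ARE oracle

def oracle_merge(intervals: list[tuple[int, int]], gap: int = 5) -> list[tuple[int, int]]:
    """Fixpoint interval merge: any two intervals within ``gap`` nt combine."""
    ivs = sorted(intervals)
    changed = True
    while changed:
        changed = False
        for a, b in itertools.combinations(list(ivs), 2):
            if a in ivs and b in ivs and b[0] - a[1] <= gap and a[0] - b[1] <= gap:
                ivs.remove(a)
                ivs.remove(b)
                ivs.append((min(a[0], b[0]), max(a[1], b[1])))
                ivs.sort()
                changed = True
                break
    return ivs


# ------------------------------------------------------------ energy oracle

_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


@lru_cache(maxsize=None)
def _oracle_quartets(s: str) -> int:
    """Best exact G4 decomposition of the whole string, by direct product
    enumeration over tract lengths and loop-length compositions."""
    n = len(s)
    if n < 11 or s[0] != "G" or s[-1] != "G" or s.count("G") < 8:
        return 0
    best = 0
    for t in itertools.product(range(2, 8), repeat=4):
        L = n - sum(t)
        if not 3 <= L <= 21:
            continue
        for l1 in range(1, 8):
            for l2 in range(1, 8):
                l3 = L - l1 - l2
                if not 1 <= l3 <= 7:
                    continue
                pos, ok = 0, True
                for tl, ll in zip(t, (l1, l2, l3, 0)):
                    if s[pos:pos + tl] != "G" * tl:
                        ok = False
                        break
                    pos += tl + ll
                if ok:
                    best = max(best, min(t))
    return best


def oracle_mfe(s: str, g4_aware: bool, pair_energy: float = -1.0,
               quartet_energy: float = -3.0, min_hairpin: int = 3) -> float:
    """Exhaustive first-position recursion over the simplified model's
    structures (every non-crossing pairing plus optional G4 spans)."""

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> float:
        if j - i <= 0:
            return 0.0
        e = best(i + 1, j)  # i unpaired
        for k in range(i + min_hairpin + 1, j):
            if (s[i], s[k]) in _PAIRS:
                e = min(e, pair_energy + best(i + 1, k) + best(k + 1, j))
        if g4_aware and s[i] == "G":
            for end in range(i + 11, j + 1):
                if s[end - 1] != "G":
                    continue
                q = _oracle_quartets(s[i:end])
                if q:
                    e = min(e, quartet_energy * q + best(end, j))
        return e

    return best(0, len(s))


def oracle_structures_count_and_mfe(s: str, g4_aware: bool,
                                    pair_energy: float = -1.0,
                                    quartet_energy: float = -3.0,
                                    min_hairpin: int = 3) -> tuple[int, float]:
    """Fully explicit enumeration (no memoization) for tiny sequences:
    returns (number of structures, minimum energy)."""

    def rec(i: int, j: int):
        if j - i <= 0:
            yield 0.0
            return
        for rest in rec(i + 1, j):
            yield rest
        for k in range(i + min_hairpin + 1, j):
            if (s[i], s[k]) in _PAIRS:
                for a in rec(i + 1, k):
                    for b in rec(k + 1, j):
                        yield pair_energy + a + b
        if g4_aware:
            for end in range(i + 11, j + 1):
                q = _oracle_quartets(s[i:end])
                if q:
                    for rest in rec(end, j):
                        yield quartet_energy * q + rest
    energies = list(rec(0, len(s)))
    return len(energies), min(energies)


# ------------------------------------------------------- Mann-Whitney oracle

def oracle_mw_exact_p(x: list[float], y: list[float], alternative: str = "less") -> float:
    """Exact one-tailed Mann-Whitney P by enumerating all group labelings."""
    pooled = list(x) + list(y)
    n1 = len(x)

    def u_stat(xs, ys):
        # pairs where the x member is the smaller one (ties count half)
        return sum(1.0 if a < b else 0.5 if a == b else 0.0 for a in xs for b in ys)

    obs = u_stat(x, y)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = u_stat(xs, ys)
        # 'less' (x stochastically smaller) is extreme when u is large
        count += (u >= obs) if alternative == "less" else (u <= obs)
        total += 1
    return count / total
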