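"""RNA secondary-structure engines.

Two interchangeable engines return a ``(dot_bracket, mfe)`` pair for an RNA
sequence:

``vienna``
    ViennaRNA's minimum-free-energy fold (default Turner parameters).  This is
    the default engine; published precursor MFE/MFEI values in the plant
    miRNA literature come from RNAfold-style thermodynamics, so screening
    thresholds keep their usual meaning.

``stacking``
    A compact nearest-neighbour dynamic program bundled with the package:
    Zuker-style recursions restricted to nested structures, scoring helix
    stacks from a small editable table plus size-dependent loop penalties.
    Its energies are not numerically identical to ViennaRNA's, but pair sets
    on clean hairpins agree, and all screening criteria are threshold-based,
    so the screen is engine-robust.  Useful where the ViennaRNA bindings are
    unavailable, and as an independent cross-check in the test-suite.
"""

from __future__ import annotations

import math
from typing import Dict, List, Optional, Tuple

from .core import RNA_PAIRS, to_rna

__all__ = ["fold_sequence", "pair_table", "ENGINES"]

# --- compact nearest-neighbour parameter set (kcal/mol) --------------------
# Stack energies keyed by ((i, j), (i+1, j-1)) base pairs, 5'->3' outer pair
# first.  Values are rounded nearest-neighbour magnitudes; the table is
# symmetric under reversal of the helix.
_PAIR_STRENGTH = {("G", "C"): 3.3, ("C", "G"): 3.3, ("A", "U"): 1.1,
                  ("U", "A"): 1.1, ("G", "U"): 0.8, ("U", "G"): 0.8}

STACK_ENERGY: Dict[Tuple[Tuple[str, str], Tuple[str, str]], float] = {
    (p, q): -round(0.4 + 0.5 * (_PAIR_STRENGTH[p] + _PAIR_STRENGTH[q]), 2)
    for p in _PAIR_STRENGTH
    for q in _PAIR_STRENGTH
}

# Hairpin-loop closing penalties by unpaired length (Jacobson-Stockmayer
# style log extrapolation past the table).
_HAIRPIN_LOOP = {3: 5.4, 4: 5.6, 5: 5.7, 6: 5.4, 7: 6.0, 8: 5.5, 9: 6.2}
_MIN_HAIRPIN = 3
_MULTILOOP_CLOSE = 3.4
_MAX_INTERNAL_SIDE = 12  # cap per-side internal/bulge loop size in the DP


def _hairpin_penalty(n: int) -> float:
    if n in _HAIRPIN_LOOP:
        return _HAIRPIN_LOOP[n]
    return 6.2 + 1.75 * 0.616 * math.log(n / 9.0)


def _internal_penalty(left: int, right: int) -> float:
    if left == 0 or right == 0:  # bulge
        return 3.8 + 0.6 * (left + right)
    return 4.0 + 0.4 * (left + right)


def _can_pair(a: str, b: str) -> bool:
    return (a, b) in RNA_PAIRS


def _fold_stacking(seq: str) -> Tuple[str, float]:
    """Zuker-style MFE fold over nested structures with the bundled table."""
    n = len(seq)
    INF = float("inf")
    # V[i][j]: min energy given (i, j) paired; W[i][j]: min energy of i..j
    V = [[INF] * n for _ in range(n)]
    W = [[0.0] * n for _ in range(n)]

    for span in range(_MIN_HAIRPIN + 1, n):
        for i in range(0, n - span):
            j = i + span
            a, b = seq[i], seq[j]
            if _can_pair(a, b):
                best = _hairpin_penalty(j - i - 1)
                # stacked pair / internal loops / bulges
                max_l = min(_MAX_INTERNAL_SIDE, j - i - 2)
                for li in range(0, max_l + 1):
                    ip = i + 1 + li
                    for rj in range(0, min(_MAX_INTERNAL_SIDE, j - ip - 2) + 1):
                        jp = j - 1 - rj
                        if jp - ip < _MIN_HAIRPIN + 1:
                            continue
                        v = V[ip][jp]
                        if v == INF:
                            continue
                        if li == 0 and rj == 0:
                            stack = STACK_ENERGY[((a, b), (seq[ip], seq[jp]))]
                            best = min(best, v + stack)
                        else:
                            best = min(best, v + _internal_penalty(li, rj))
                # multiloop: two or more branches inside
                for k in range(i + 2, j - 1):
                    cand = W[i + 1][k] + W[k + 1][j - 1]
                    if cand < 0:
                        best = min(best, cand + _MULTILOOP_CLOSE)
                V[i][j] = best
            # W recursion
            w = min(W[i + 1][j], W[i][j - 1])
            if V[i][j] < INF:
                w = min(w, V[i][j])
            for k in range(i + 1, j):
                w = min(w, W[i][k] + W[k + 1][j])
            W[i][j] = min(w, 0.0)

    # traceback
    structure = ["."] * n

    def trace_v(i: int, j: int) -> None:
        structure[i], structure[j] = "(", ")"
        e = V[i][j]
        if abs(e - _hairpin_penalty(j - i - 1)) < 1e-9:
            return
        a, b = seq[i], seq[j]
        max_l = min(_MAX_INTERNAL_SIDE, j - i - 2)
        for li in range(0, max_l + 1):
            ip = i + 1 + li
            for rj in range(0, min(_MAX_INTERNAL_SIDE, j - ip - 2) + 1):
                jp = j - 1 - rj
                if jp - ip < _MIN_HAIRPIN + 1 or V[ip][jp] == INF:
                    continue
                cost = (STACK_ENERGY[((a, b), (seq[ip], seq[jp]))]
                        if li == 0 and rj == 0 else _internal_penalty(li, rj))
                if abs(e - (V[ip][jp] + cost)) < 1e-9:
                    trace_v(ip, jp)
                    return
        for k in range(i + 2, j - 1):
            if abs(e - (W[i + 1][k] + W[k + 1][j - 1] + _MULTILOOP_CLOSE)) < 1e-9:
                trace_w(i + 1, k)
                trace_w(k + 1, j - 1)
                return

    def trace_w(i: int, j: int) -> None:
        while i < j:
            e = W[i][j]
            if e >= -1e-12:
                return
            if abs(e - W[i + 1][j]) < 1e-9:
                i += 1
                continue
            if abs(e - W[i][j - 1]) < 1e-9:
                j -= 1
                continue
            if V[i][j] < INF and abs(e - V[i][j]) < 1e-9:
                trace_v(i, j)
                return
            for k in range(i + 1, j):
                if abs(e - (W[i][k] + W[k + 1][j])) < 1e-9:
                    trace_w(i, k)
                    i = k + 1
                    break
            else:
                return

    mfe = W[0][n - 1] if n > 1 else 0.0
    if mfe < 0:
        trace_w(0, n - 1)
    return "".join(structure), round(mfe, 2)


def _fold_vienna(seq: str) -> Tuple[str, float]:
    import RNA  # ViennaRNA python bindings

    structure, mfe = RNA.fold(seq)
    return structure, float(mfe)


ENGINES = {"vienna": _fold_vienna, "stacking": _fold_stacking}


def fold_sequence(sequence: str, engine: str = "vienna") -> Tuple[str, float]:
    """MFE-fold an RNA sequence; returns (dot-bracket, mfe kcal/mol)."""
    seq = to_rna(sequence)
    bad = set(seq) - set("ACGUN")
    if bad:
        raise ValueError(f"non-RNA characters in sequence: {sorted(bad)}")
    try:
        fn = ENGINES[engine]
    except KeyError:
        raise ValueError(f"unknown folding engine {engine!r}; choose from {sorted(ENGINES)}")
    return fn(seq)


def pair_table(dot_bracket: str) -> List[Optional[int]]:
    """0-based partner index per position (None if unpaired); validates nesting."""
    stack: List[int] = []
    partners: List[Optional[int]] = [None] * len(dot_bracket)
    for idx, char in enumerate(dot_bracket):
        if char == "(":
            stack.append(idx)
        elif char == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {idx + 1}")
            other = stack.pop()
            partners[other], partners[idx] = idx, other
        elif char != ".":
            raise ValueError(f"invalid dot-bracket character {char!r} at position {idx + 1}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1] + 1}")
    return partners
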