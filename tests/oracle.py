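"""Brute-force oracles for motif matching, independent of the scan path.

Two routes:

* :func:`expansion_strings` materialises every concrete string a pattern can
  match (wildcards expand to all 20 residues) — feasible only for patterns
  with a bounded expansion count — and :func:`string_oracle_starts` runs
  plain substring search over them.
* :func:`shape_oracle_ends` enumerates every repeat-count combination by
  recursion and checks residues position by position; it handles patterns
  whose wildcard spacers make full string enumeration combinatorially
  infeasible.
"""

from __future__ import annotations

from itertools import product

from nlscan.dialect import STANDARD_RESIDUES, MotifPattern

_STD = sorted(STANDARD_RESIDUES)


def expansion_count(p: MotifPattern) -> int:
    total = 1
    for e in p.elements:
        per_pos = 20 if e.kind == "wildcard" else len(e.residues)
        total *= sum(per_pos**r for r in range(e.repeat_min, e.repeat_max + 1))
        if total > 10**9:
            return total
    return total


def expansion_strings(p: MotifPattern) -> set[str]:
    """Every concrete string matching the pattern (use only when bounded)."""
    results = [""]
    for e in p.elements:
        letters = _STD if e.kind == "wildcard" else sorted(e.residues)
        options = []
        for r in range(e.repeat_min, e.repeat_max + 1):
            options.extend("".join(c) for c in product(letters, repeat=r))
        results = [prefix + opt for prefix in results for opt in options]
    return set(results)


def string_oracle_starts(p: MotifPattern, seq: str) -> dict[int, int]:
    """start -> shortest end via exhaustive substring search of all expansions."""
    best: dict[int, int] = {}
    for exp in expansion_strings(p):
        i = seq.find(exp)
        while i >= 0:
            end = i + len(exp)
            if i not in best or end < best[i]:
                best[i] = end
            i = seq.find(exp, i + 1)
    return best


def _allowed(e) -> frozenset[str]:
    return frozenset(_STD) if e.kind == "wildcard" else e.residues


def shape_oracle_ends(p: MotifPattern, seq: str, start: int) -> set[int]:
    """All end offsets of matches anchored at ``start`` (every repeat shape)."""

    def rec(pos: int, k: int) -> set[int]:
        if k == len(p.elements):
            return {pos}
        e = p.elements[k]
        allowed = _allowed(e)
        ends: set[int] = set()
        for r in range(e.repeat_min, e.repeat_max + 1):
            if pos + r > len(seq):
                break
            if all(seq[pos + j] in allowed for j in range(r)):
                ends |= rec(pos + r, k + 1)
            else:
                break  # longer repeats of this element cannot match either
        return ends

    return rec(start, 0)


def shape_oracle_spans(p: MotifPattern, seq: str) -> dict[int, int]:
    """start -> shortest end over the whole sequence."""
    out: dict[int, int] = {}
    for start in range(len(seq)):
        ends = shape_oracle_ends(p, seq, start)
        if ends:
            out[start] = min(ends)
    return out
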