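"""Independent brute-force oracles used to check the implementation.

These deliberately share no code with the package: alignments are
checked by enumerating every gapped alignment as a move sequence and
scoring the resulting string pair directly; contacts by an explicit
double loop over atom pairs; Venn regions by per-element membership
counting.
"""

from __future__ import annotations

import math
from functools import lru_cache

GAP = "-"


@lru_cache(maxsize=None)
def _move_sequences(m: int, n: int) -> tuple[tuple[str, ...], ...]:
    """Every lattice path from (0,0) to (m,n) with moves D, U, L."""
    if m == 0 and n == 0:
        return ((),)
    out: list[tuple[str, ...]] = []
    if m > 0 and n > 0:
        out.extend(p + ("D",) for p in _move_sequences(m - 1, n - 1))
    if m > 0:
        out.extend(p + ("U",) for p in _move_sequences(m - 1, n))
    if n > 0:
        out.extend(p + ("L",) for p in _move_sequences(m, n - 1))
    return tuple(out)


def score_alignment(aq: str, asub: str, score_pair, gap_open: int, gap_extend: int) -> int:
    """Score an explicit alignment string pair; a gap run of length L
    costs gap_open + gap_extend*(L-1)."""
    total = 0
    in_gap_q = in_gap_s = False
    for a, b in zip(aq, asub):
        if a == GAP:
            total -= gap_extend if in_gap_q else gap_open
            in_gap_q, in_gap_s = True, False
        elif b == GAP:
            total -= gap_extend if in_gap_s else gap_open
            in_gap_q, in_gap_s = False, True
        else:
            total += score_pair(a, b)
            in_gap_q = in_gap_s = False
    return total


def oracle_global_score(q: str, s: str, score_pair, gap_open: int, gap_extend: int) -> int:
    """Max score over every complete gapped alignment of q and s."""
    best = None
    for moves in _move_sequences(len(q), len(s)):
        i = j = 0
        aq: list[str] = []
        asub: list[str] = []
        for mv in moves:
            if mv == "D":
                aq.append(q[i]); asub.append(s[j]); i += 1; j += 1
            elif mv == "U":
                aq.append(q[i]); asub.append(GAP); i += 1
            else:
                aq.append(GAP); asub.append(s[j]); j += 1
        sc = score_alignment("".join(aq), "".join(asub), score_pair, gap_open, gap_extend)
        if best is None or sc > best:
            best = sc
    return best


def oracle_local_score(q: str, s: str, score_pair, gap_open: int, gap_extend: int) -> int:
    """Max over all substring pairs of the global oracle, floored at 0."""
    best = 0
    for i1 in range(len(q)):
        for i2 in range(i1 + 1, len(q) + 1):
            for j1 in range(len(s)):
                for j2 in range(j1 + 1, len(s) + 1):
                    sc = oracle_global_score(
                        q[i1:i2], s[j1:j2], score_pair, gap_open, gap_extend
                    )
                    if sc > best:
                        best = sc
    return best


def oracle_contact_counts(protein_atoms, ligand_atoms, cutoff: float) -> dict[str, int]:
    """Explicit O(n^2) pair loop; heavy atoms only; unordered classes."""
    classes = ("CC", "CO", "CN", "CX", "OO", "OX", "NO", "NN", "NX", "XX")
    counts = {c: 0 for c in classes}
    for p in protein_atoms:
        if p.element.capitalize() == "H":
            continue
        for l in ligand_atoms:
            if l.element.capitalize() == "H":
                continue
            d = math.sqrt((p.x - l.x) ** 2 + (p.y - l.y) ** 2 + (p.z - l.z) ** 2)
            if d <= cutoff:
                a = p.element.capitalize() if p.element.capitalize() in "CNO" else "X"
                b = l.element.capitalize() if l.element.capitalize() in "CNO" else "X"
                key = "".join(sorted(a + b))
                if key not in counts:
                    key = key[::-1]
                counts[key] += 1
    return counts


def oracle_venn(gut: set, oral: set, vaginal: set) -> dict[str, int]:
    """Per-element membership classification over the union."""
    regions = {
        "gut_only": 0, "oral_only": 0, "vaginal_only": 0,
        "gut_oral": 0, "gut_vaginal": 0, "oral_vaginal": 0, "all_three": 0,
    }
    for sp in gut | oral | vaginal:
        member = (sp in gut, sp in oral, sp in vaginal)
        key = {
            (True, False, False): "gut_only",
            (False, True, False): "oral_only",
            (False, False, True): "vaginal_only",
            (True, True, False): "gut_oral",
            (True, False, True): "gut_vaginal",
            (False, True, True): "oral_vaginal",
            (True, True, True): "all_three",
        }[member]
        regions[key] += 1
    return regions
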