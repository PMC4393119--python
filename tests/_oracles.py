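"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own algorithms: structures are
enumerated explicitly, mapping is a per-position Hamming loop, and target
alignments are enumerated recursively over edit operations.
"""

from __future__ import annotations

from itertools import count

_ORACLE_WEIGHTS = {
    ("G", "C"): 3, ("C", "G"): 3,
    ("A", "U"): 2, ("U", "A"): 2,
    ("G", "U"): 1, ("U", "G"): 1,
}


def enumerate_structures(seq: str, min_loop: int = 3) -> list[list[tuple[int, int]]]:
    """All nested pair sets with hairpin loops of at least ``min_loop`` nt."""

    def rec(i: int, j: int) -> list[list[tuple[int, int]]]:
        if i >= j:
            return [[]]
        out = [s for s in rec(i + 1, j)]
        for k in range(i + min_loop + 1, j + 1):
            if (seq[i], seq[k]) not in _ORACLE_WEIGHTS:
                continue
            for inner in rec(i + 1, k - 1):
                for outer in rec(k + 1, j):
                    out.append([(i, k)] + inner + outer)
        return out

    return rec(0, len(seq) - 1)


def max_structure_score(seq: str, min_loop: int = 3) -> int:
    best = 0
    for structure in enumerate_structures(seq, min_loop):
        score = sum(_ORACLE_WEIGHTS[(seq[i], seq[j])] for i, j in structure)
        best = max(best, score)
    return best


def naive_placements(read: str, contig: str, mismatch_max: int) -> set[tuple[int, int]]:
    """All (start, mismatches) by per-position Hamming comparison."""
    out = set()
    for start in range(len(contig) - len(read) + 1):
        mm = 0
        for a, b in zip(read, contig[start : start + len(read)]):
            if a != b or a == "N":
                mm += 1
        if mm <= mismatch_max:
            out.add((start, mm))
    return out


_COMPLEMENT = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C")}
_WOBBLE = {("G", "U"), ("U", "G")}


def min_expectation(
    milrna: str,
    site: str,
    gap_max: int = 2,
    core: tuple[int, int] = (2, 13),
) -> float:
    """Exhaustive minimum over all alignments with at most ``gap_max`` gaps.

    The milRNA is consumed 5'->3', the site 3'->5'; a gap adjacent to milRNA
    positions p/p+1 is weighted by position p (the 5'-ward neighbour).
    """
    m, s = len(milrna), len(site)

    def mult(pos: int) -> float:
        return 2.0 if core[0] <= pos <= core[1] else 1.0

    best = [float("inf")]

    def rec(i: int, j: int, g: int, acc: float) -> None:
        if acc >= best[0]:
            return
        if i == m and j == s:
            best[0] = acc
            return
        if i < m and j < s:
            pair = (milrna[i], site[s - 1 - j])
            if pair in _COMPLEMENT:
                cost = 0.0
            elif pair in _WOBBLE:
                cost = 0.5 * mult(i + 1)
            else:
                cost = 1.0 * mult(i + 1)
            rec(i + 1, j + 1, g, acc + cost)
        if g < gap_max:
            if i < m:
                rec(i + 1, j, g + 1, acc + 2.0 * mult(i + 1))
            if j < s:
                rec(i, j + 1, g + 1, acc + 2.0 * mult(i))
    rec(0, 0, 0, 0.0)
    return best[0]
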