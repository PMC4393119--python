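"""Secondary-structure prediction for transcript contigs.

The built-in folder is a weighted maximum-pairing dynamic program (Nussinov
style): each structure is scored as the sum of pair weights GC=3, AU=2, GU=1
over all base pairs, subject to a minimum hairpin loop length and nestedness
(no pseudoknots).  The DP is exact for this objective; `tests` verify it
against exhaustive enumeration on short sequences.  An external thermodynamic
folder can be plugged in behind the same contract via the ``backend``
argument of :func:`fold`.

Long contigs are folded in overlapping windows so that DP cost stays bounded;
milRNA precursors are local hairpins, so a window that contains the hairpin
folds it identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .io import ParameterError, RunConfig, SequenceRecord

try:  # numba accelerates the O(n^3) fill; pure-python fallback is identical
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        return wrap if not (args and callable(args[0])) else args[0]


_ENC = {"A": 0, "C": 1, "G": 2, "U": 3, "N": 4}

#: pair weights; index order A,C,G,U,N
PAIR_WEIGHTS = np.zeros((5, 5), dtype=np.int64)
PAIR_WEIGHTS[2, 1] = PAIR_WEIGHTS[1, 2] = 3  # G:C
PAIR_WEIGHTS[0, 3] = PAIR_WEIGHTS[3, 0] = 2  # A:U
PAIR_WEIGHTS[2, 3] = PAIR_WEIGHTS[3, 2] = 1  # G:U


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_ENC[c] for c in seq], dtype=np.int64)
    except KeyError as exc:
        raise ParameterError(f"non-RNA character {exc.args[0]!r} in sequence") from exc


@njit(cache=False)
def _fill(enc, weights, min_loop):  # pragma: no cover - exercised via fold()
    n = enc.shape[0]
    m = np.zeros((n, n), dtype=np.int64)
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = m[i + 1, j]
            for k in range(i + min_loop + 1, j + 1):
                w = weights[enc[i], enc[k]]
                if w > 0:
                    s = w + m[i + 1, k - 1]
                    if k + 1 <= j:
                        s += m[k + 1, j]
                    if s > best:
                        best = s
            m[i, j] = best
    return m


def _traceback(enc: np.ndarray, weights: np.ndarray, m: np.ndarray, min_loop: int) -> list[int | None]:
    """Deterministic traceback: prefer pairing position i, smallest partner."""
    n = len(enc)
    partner: list[int | None] = [None] * n
    stack = [(0, n - 1)]
    while stack:
        i, j = stack.pop()
        if i >= j or j - i < min_loop + 1:
            continue
        target = m[i, j]
        if target == 0:
            continue
        paired = False
        for k in range(i + min_loop + 1, j + 1):
            w = weights[enc[i], enc[k]]
            if w == 0:
                continue
            s = w + m[i + 1, k - 1]
            if k + 1 <= j:
                s += m[k + 1, j]
            if s == target:
                partner[i] = k
                partner[k] = i
                stack.append((i + 1, k - 1))
                if k + 1 <= j:
                    stack.append((k + 1, j))
                paired = True
                break
        if not paired:
            stack.append((i + 1, j))
    return partner


def partner_to_dotbracket(partner: Sequence[int | None]) -> str:
    out = []
    for i, p in enumerate(partner):
        if p is None:
            out.append(".")
        elif p > i:
            out.append("(")
        else:
            out.append(")")
    return "".join(out)


def dotbracket_to_partner(dotbracket: str) -> list[int | None]:
    partner: list[int | None] = [None] * len(dotbracket)
    stack: list[int] = []
    for i, c in enumerate(dotbracket):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ParameterError("unbalanced dot-bracket string")
            j = stack.pop()
            partner[i] = j
            partner[j] = i
        elif c != ".":
            raise ParameterError(f"bad dot-bracket character {c!r}")
    if stack:
        raise ParameterError("unbalanced dot-bracket string")
    return partner


_VALID_PAIRS = {("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"), ("G", "U"), ("U", "G")}


@dataclass
class FoldedContig:
    """A contig (or contig window) with its predicted structure.

    ``offset`` is the window start within the parent contig; 0 for
    un-windowed contigs.
    """

    contig_id: str
    sequence: str
    dotbracket: str
    score: int
    partner: list[int | None]
    offset: int = 0

    def __post_init__(self) -> None:
        if len(self.dotbracket) != len(self.sequence):
            raise ParameterError("dot-bracket length != sequence length")
        for i, p in enumerate(self.partner):
            if p is None:
                continue
            if self.partner[p] != i:
                raise ParameterError("partner map not symmetric")
            if i < p and (self.sequence[i], self.sequence[p]) not in _VALID_PAIRS:
                raise ParameterError(
                    f"invalid pair {self.sequence[i]}:{self.sequence[p]} at ({i},{p})"
                )

    def pairs(self) -> list[tuple[int, int]]:
        return [(i, p) for i, p in enumerate(self.partner) if p is not None and p > i]


def score_structure(sequence: str, partner: Sequence[int | None]) -> int:
    """Weighted pair sum of a structure (same objective the DP maximizes)."""
    enc = _encode(sequence)
    total = 0
    for i, p in enumerate(partner):
        if p is not None and p > i:
            total += int(PAIR_WEIGHTS[enc[i], enc[p]])
    return total


FoldBackend = Callable[[str], tuple[str, float]]


def fold(
    contig: SequenceRecord | str,
    min_loop: int = 3,
    backend: FoldBackend | None = None,
    contig_id: str | None = None,
) -> FoldedContig:
    """Predict the maximum weighted-pair structure of an RNA sequence.

    ``backend``, if given, is an external folder mapping sequence to
    ``(dotbracket, score)``; its output is validated against the same
    structural invariants.
    """
    if isinstance(contig, SequenceRecord):
        seq, cid = contig.sequence, contig.id
    else:
        seq, cid = contig.upper(), contig_id or "seq"
    if len(seq) < 2 * min_loop:
        raise ParameterError(f"sequence {cid!r} shorter than 2*min_loop")
    enc = _encode(seq)  # validates alphabet
    if backend is not None:
        dotbracket, score = backend(seq)
        partner = dotbracket_to_partner(dotbracket)
        for i, p in enumerate(partner):
            if p is not None and p > i and p - i - 1 < min_loop:
                raise ParameterError("backend structure violates min_loop")
        return FoldedContig(cid, seq, dotbracket, int(score), partner)
    m = _fill(enc, PAIR_WEIGHTS, min_loop)
    partner = _traceback(enc, PAIR_WEIGHTS, m, min_loop)
    return FoldedContig(cid, seq, partner_to_dotbracket(partner), int(m[0, len(seq) - 1]), partner)


def fold_contig(contig: SequenceRecord, config: RunConfig | None = None) -> list[FoldedContig]:
    """Fold a contig, windowing it when longer than ``fold_max_len``.

    Windows are ``fold_window`` nt with step ``fold_step`` and are folded
    independently; ids get a ``:w<start>`` suffix and carry their offset.
    """
    config = config or RunConfig()
    if len(contig) <= config.fold_max_len:
        return [fold(contig, min_loop=config.min_loop)]
    out = []
    n = len(contig.sequence)
    starts = list(range(0, max(n - config.fold_window, 0) + 1, config.fold_step))
    if starts[-1] + config.fold_window < n:
        starts.append(n - config.fold_window)
    for start in starts:
        window = contig.sequence[start : start + config.fold_window]
        folded = fold(window, min_loop=config.min_loop, contig_id=f"{contig.id}:w{start}")
        folded.offset = start
        out.append(folded)
    return out


@dataclass
class Stem:
    """A maximal run of nested pairs, merged across small bulges."""

    pairs: list[tuple[int, int]]

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def arm5(self) -> tuple[int, int]:
        return (self.pairs[0][0], self.pairs[-1][0] + 1)

    @property
    def arm3(self) -> tuple[int, int]:
        return (self.pairs[-1][1], self.pairs[0][1] + 1)

    def positions(self) -> set[int]:
        out: set[int] = set()
        for i, j in self.pairs:
            out.add(i)
            out.add(j)
        return out


def extract_stems(folded: FoldedContig, gap_max: int = 3) -> list[Stem]:
    """Decompose pairs into stems; gaps <= ``gap_max`` nt per side merge.

    Every pair belongs to exactly one stem; stems come back ordered by the
    start of their 5' arm.
    """
    pairs = sorted(folded.pairs())
    stems: list[Stem] = []
    cur: list[tuple[int, int]] = []
    for i, j in pairs:
        if (
            cur
            and j < cur[-1][1]
            and i - cur[-1][0] - 1 <= gap_max
            and cur[-1][1] - j - 1 <= gap_max
        ):
            cur.append((i, j))
        else:
            if cur:
                stems.append(Stem(cur))
            cur = [(i, j)]
    if cur:
        stems.append(Stem(cur))
    return stems
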