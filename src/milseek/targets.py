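"""Plant-style milRNA target prediction.

A target site is scored against the reverse complement of the milRNA with a
penalty sum: match 0, G:U wobble 0.5, mismatch 1.0, gap 2.0, each doubled
when the milRNA position (counted from its 5' end) lies in the seed-proximal
core (positions 2-13 by default).  At most two gaps are allowed.  Hits at or
under the expectation ceiling are reported, one best site per
milRNA-unigene pair, and the inhibition mode is Translation when any
non-match event touches the central positions (9-11), Cleavage otherwise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .expression import ExpressionRecord
from .io import ParameterError, RunConfig, SequenceRecord

_COMP = str.maketrans("ACGUN", "UGCAN")
_IDX = {"A": 0, "C": 1, "G": 2, "U": 3, "N": 4}
_WOBBLE = {("G", "A"), ("U", "C")}  # milRNA letter vs complemented target letter

_INF = float("inf")


def _mult(pos: int, core: tuple[int, int]) -> float:
    return 2.0 if core[0] <= pos <= core[1] else 1.0


def _sub_cost(mil: str, comp_t: str, pos: int, core: tuple[int, int]) -> float:
    if mil == comp_t and mil != "N":
        return 0.0
    if (mil, comp_t) in _WOBBLE:
        return 0.5 * _mult(pos, core)
    return 1.0 * _mult(pos, core)


@dataclass
class TargetAlignment:
    penalty: float
    #: (milRNA 1-based position, event) with event in match/wobble/mismatch/gap
    ops: list[tuple[int, str]]
    site_len: int


@dataclass
class TargetHit:
    milrna_acc: str
    target_id: str
    expectation: float
    align_start: int
    site_len: int
    inhibition: str
    lib: str | None = None
    f_rpkm: float | None = None
    m_rpkm: float | None = None


def _align_scalar(
    milrna: str,
    comp_window: str,
    end_min: int,
    end_max: int,
    gap_max: int,
    core: tuple[int, int],
) -> TargetAlignment | None:
    """Minimum-penalty alignment with backtrace.

    ``comp_window`` is the complemented (not reversed) target window; the
    milRNA is consumed 3'->5' so that window position 0 faces the milRNA
    3' end.  Site length may end anywhere in [end_min, end_max].
    """
    rm = milrna[::-1]
    m = len(rm)
    w = len(comp_window)
    D = [[[_INF] * (gap_max + 1) for _ in range(w + 1)] for _ in range(m + 1)]
    back: dict[tuple[int, int, int], tuple[int, int, int, tuple[int, str]]] = {}
    D[0][0][0] = 0.0
    for k in range(m + 1):
        for j in range(w + 1):
            for g in range(gap_max + 1):
                cur = D[k][j][g]
                if cur == _INF:
                    continue
                pos = m - k  # milRNA 1-based position of the next consumed base
                if k < m and j < w:
                    cost = _sub_cost(rm[k], comp_window[j], pos, core)
                    if cur + cost < D[k + 1][j + 1][g]:
                        D[k + 1][j + 1][g] = cur + cost
                        if cost == 0.0:
                            ev = "match"
                        elif (rm[k], comp_window[j]) in _WOBBLE:
                            ev = "wobble"
                        else:
                            ev = "mismatch"
                        back[(k + 1, j + 1, g)] = (k, j, g, (pos, ev))
                if k < m and g < gap_max:
                    cost = 2.0 * _mult(pos, core)
                    if cur + cost < D[k + 1][j][g + 1]:
                        D[k + 1][j][g + 1] = cur + cost
                        back[(k + 1, j, g + 1)] = (k, j, g, (pos, "gap"))
                if j < w and g < gap_max:
                    cost = 2.0 * _mult(pos, core)
                    if cur + cost < D[k][j + 1][g + 1]:
                        D[k][j + 1][g + 1] = cur + cost
                        back[(k, j + 1, g + 1)] = (k, j, g, (max(pos, 1), "gap"))
    best: tuple[float, int, int] | None = None
    for j in range(max(end_min, 1), min(end_max, w) + 1):
        for g in range(gap_max + 1):
            if D[m][j][g] < _INF and (best is None or D[m][j][g] < best[0]):
                best = (D[m][j][g], j, g)
    if best is None:
        return None
    penalty, j, g = best
    ops: list[tuple[int, str]] = []
    state = (m, j, g)
    while state != (0, 0, 0):
        k0, j0, g0, op = back[state]
        ops.append(op)
        state = (k0, j0, g0)
    ops.reverse()
    return TargetAlignment(penalty=penalty, ops=ops, site_len=j)


def expectation_score(
    milrna: str, site: str, config: RunConfig | None = None
) -> TargetAlignment:
    """Score one milRNA against one candidate site.

    Returns the minimal penalty and the per-position event list.  Sites whose
    length cannot be bridged by the gap budget come back with infinite
    penalty.
    """
    config = config or RunConfig()
    milrna = milrna.upper().replace("T", "U")
    site = site.upper().replace("T", "U")
    if not (18 <= len(milrna) <= 30):
        raise ParameterError("milRNA length must be within [18, 30]")
    if abs(len(site) - len(milrna)) > 4:
        raise ParameterError("site length must be within 4 nt of the milRNA")
    if abs(len(site) - len(milrna)) > config.gap_max:
        return TargetAlignment(penalty=_INF, ops=[], site_len=len(site))
    core = (config.core_start, config.core_end)
    aln = _align_scalar(
        milrna,
        site.translate(_COMP),
        end_min=len(site),
        end_max=len(site),
        gap_max=config.gap_max,
        core=core,
    )
    assert aln is not None
    return aln


def _scan_penalties(milrna: str, unigene: str, config: RunConfig) -> np.ndarray:
    """Vectorized minimal alignment penalty for a site anchored at every
    unigene offset (same recurrence as :func:`_align_scalar`)."""
    core = (config.core_start, config.core_end)
    gap_max = config.gap_max
    rm = milrna[::-1]
    m = len(rm)
    w = m + gap_max
    cs = np.array([_IDX[c] for c in unigene.translate(_COMP)], dtype=np.int64)
    n_t = len(unigene) - (m - gap_max) + 1
    if n_t <= 0:
        return np.full(0, _INF)
    # substitution cost per milRNA index x target letter (index 5 = off-end)
    letters = "ACGUN"
    sub = np.full((m, 6), _INF)
    gap_cost = np.empty(m + 1)
    for k in range(m + 1):
        gap_cost[k] = 2.0 * _mult(m - k, core)
    for k in range(m):
        for li, letter in enumerate(letters):
            sub[k, li] = _sub_cost(rm[k], letter, m - k, core)
    cs_pad = np.concatenate([cs, np.full(w, 5, dtype=np.int64)])

    D = np.full((m + 1, w + 1, gap_max + 1, n_t), _INF)
    D[0, 0, 0, :] = 0.0
    for k in range(m + 1):
        for j in range(w + 1):
            cost_vec = None
            if k < m and j < w:
                cost_vec = np.concatenate([sub[k], [_INF]])[cs_pad[j : j + n_t]]
            for g in range(gap_max + 1):
                cur = D[k, j, g]
                if k < m and j < w:
                    np.minimum(D[k + 1, j + 1, g], cur + cost_vec, out=D[k + 1, j + 1, g])
                if k < m and g < gap_max:
                    np.minimum(D[k + 1, j, g + 1], cur + gap_cost[k], out=D[k + 1, j, g + 1])
                if j < w and g < gap_max:
                    np.minimum(D[k, j + 1, g + 1], cur + gap_cost[k], out=D[k, j + 1, g + 1])
    return D[m, 1:, :, :].min(axis=(0, 1))


def _inhibition(aln: TargetAlignment, config: RunConfig) -> str:
    for pos, ev in aln.ops:
        if ev != "match" and config.translation_start <= pos <= config.translation_end:
            return "Translation"
    return "Cleavage"


def _as_triples(milrnas: Iterable) -> list[tuple[str, str, str | None]]:
    out = []
    for item in milrnas:
        if isinstance(item, tuple):
            acc, seq, lib = (item + (None,))[:3] if len(item) < 3 else item[:3]
        else:
            acc = item.accession
            seq = item.sequence
            lib = getattr(item, "lib_class", None)
        out.append((acc, seq.upper().replace("T", "U"), lib))
    return out


def scan_targets(
    milrnas: Iterable,
    unigenes: Sequence[SequenceRecord],
    config: RunConfig | None = None,
) -> list[TargetHit]:
    """Scan every unigene window for every milRNA; report the single best
    site per pair when its expectation is at or under the ceiling."""
    config = config or RunConfig()
    hits: list[TargetHit] = []
    for acc, seq, lib in _as_triples(milrnas):
        if not (18 <= len(seq) <= 30):
            raise ParameterError(f"milRNA {acc!r} length out of [18, 30]")
        for unigene in unigenes:
            target = unigene.sequence
            pens = _scan_penalties(seq, target, config)
            if pens.size == 0:
                continue
            t = int(np.argmin(pens))
            if pens[t] > config.expectation_max:
                continue
            window = target[t : t + len(seq) + config.gap_max]
            aln = _align_scalar(
                seq,
                window.translate(_COMP),
                end_min=len(seq) - config.gap_max,
                end_max=len(seq) + config.gap_max,
                gap_max=config.gap_max,
                core=(config.core_start, config.core_end),
            )
            assert aln is not None and math.isclose(aln.penalty, float(pens[t]))
            hits.append(
                TargetHit(
                    milrna_acc=acc,
                    target_id=unigene.id,
                    expectation=aln.penalty,
                    align_start=t,
                    site_len=aln.site_len,
                    inhibition=_inhibition(aln, config),
                    lib=lib,
                )
            )
    return hits


_KEEP_FOR = {
    "M": {"up_FB", "FB_specific"},
    "F": {"up_MY", "MY_specific"},
    "B": {"up_FB", "FB_specific", "up_MY", "MY_specific"},
}


def cross_filter(
    hits: Sequence[TargetHit],
    expression: Sequence[ExpressionRecord] | Mapping[str, ExpressionRecord],
    config: RunConfig | None = None,
) -> list[TargetHit]:
    """Keep hits whose target moves against the milRNA's library of origin.

    An M-class milRNA keeps targets up in FB (or FB-specific) and vice
    versa; B-class milRNAs keep either direction.  Hits whose target has no
    expression record are dropped with a warning.
    """
    if not isinstance(expression, Mapping):
        expression = {r.unigene_id: r for r in expression}
    log = logging.getLogger("milseek.targets")
    kept: list[TargetHit] = []
    for hit in hits:
        rec = expression.get(hit.target_id)
        if rec is None:
            log.warning("target %s has no expression record; hit dropped", hit.target_id)
            continue
        if hit.lib not in _KEEP_FOR:
            log.warning("milRNA %s has no library class; hit dropped", hit.milrna_acc)
            continue
        if rec.deg_class in _KEEP_FOR[hit.lib]:
            hit.f_rpkm = rec.rpkm_FB
            hit.m_rpkm = rec.rpkm_MY
            kept.append(hit)
    return kept
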