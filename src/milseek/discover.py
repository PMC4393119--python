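"""milRNA discovery: mismatch-tolerant read mapping onto folded contigs,
duplex calling on hairpin stems and conserved-miRNA annotation.

A precursor candidate is a folded contig carrying at least two distinct
mapped small RNAs.  A duplex is a pair of reads sitting on opposite arms of
one stem whose paired bases point at each other; within a duplex the read
with the strictly larger total count is the guide (milR) and the other the
passenger (milR*).  Reads on one arm whose 5' ends lie within a couple of
nucleotides are clustered into a single locus family and reported as length
variants under suffixed accessions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .fold import FoldedContig, Stem, extract_stems
from .io import ParameterError, RunConfig, SequenceRecord
from .preprocess import GroupedSRna


@dataclass
class ReadPlacement:
    """An ungapped alignment of a grouped sRNA onto a folded contig."""

    sRNA: GroupedSRna
    contig_id: str
    start: int
    mismatches: int

    @property
    def end(self) -> int:
        return self.start + len(self.sRNA.sequence)

    @property
    def sequence(self) -> str:
        return self.sRNA.sequence


@dataclass
class MilRnaCandidate:
    accession: str
    precursor_id: str
    contig_id: str
    arm: str | None
    role: str  # "milR" or "milRstar"
    sequence: str
    start: int | None
    mismatches: int | None
    count_MY: int
    count_FB: int

    @property
    def lib_class(self) -> str:
        if self.count_FB == 0:
            return "M"
        if self.count_MY == 0:
            return "F"
        return "B"

    @property
    def total(self) -> int:
        return self.count_MY + self.count_FB


@dataclass
class PrecursorCall:
    precursor_id: str
    contig_id: str
    n_candidates: int
    lib_class: str


@dataclass
class ConservedHit:
    sequence: str
    ref_name: str
    mismatches: int
    stem_located: bool


def _encode_bytes(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def map_reads(
    grouped: Sequence[GroupedSRna],
    folded: Sequence[FoldedContig],
    mismatch_max: int = 3,
) -> list[ReadPlacement]:
    """Place every grouped sRNA at every contig offset where the full-length
    ungapped alignment has at most ``mismatch_max`` mismatches.

    ``N`` never matches.  All qualifying positions on all contigs are
    reported; there are no indels.
    """
    placements: list[ReadPlacement] = []
    enc = {f.contig_id: _encode_bytes(f.sequence) for f in folded}
    for g in grouped:
        read = _encode_bytes(g.sequence)
        L = len(read)
        for f in folded:
            contig = enc[f.contig_id]
            if len(contig) < L:
                continue
            windows = sliding_window_view(contig, L)
            mm = (windows != read).sum(axis=1)
            if "N" in g.sequence or "N" in f.sequence:
                # N must count as mismatch even when both sides are N
                n_read = read == ord("N")
                n_win = windows == ord("N")
                mm = ((windows != read) | n_read | n_win).sum(axis=1)
            for pos in np.nonzero(mm <= mismatch_max)[0]:
                placements.append(
                    ReadPlacement(g, f.contig_id, int(pos), int(mm[pos]))
                )
    return placements


def find_precursor_candidates(
    placements: Sequence[ReadPlacement], folded: Sequence[FoldedContig]
) -> dict[str, list[ReadPlacement]]:
    """Contigs (or windows) carrying at least two distinct mapped sRNA
    sequences, in folding order."""
    by_contig: dict[str, list[ReadPlacement]] = {}
    for p in placements:
        by_contig.setdefault(p.contig_id, []).append(p)
    out: dict[str, list[ReadPlacement]] = {}
    for f in folded:
        ps = by_contig.get(f.contig_id, [])
        if len({p.sequence for p in ps}) >= 2:
            out[f.contig_id] = ps
    return out


class StemCheck(NamedTuple):
    ok: bool
    same_stem: bool
    duplex: bool
    stem: Stem | None
    arm_of_p1: str | None  # "5p" or "3p"


def _paired_positions(p: ReadPlacement, folded: FoldedContig) -> list[int]:
    return [
        i
        for i in range(p.start, min(p.end, len(folded.sequence)))
        if folded.partner[i] is not None
    ]


def _arm_of(paired: Sequence[int], stem: Stem) -> str | None:
    """Arm holding the majority of a read's stem-paired bases."""
    a5 = sum(1 for i in paired if stem.arm5[0] <= i < stem.arm5[1])
    a3 = sum(1 for i in paired if stem.arm3[0] <= i < stem.arm3[1])
    if a5 == a3 == 0:
        return None
    return "5p" if a5 >= a3 else "3p"


def same_stem_check(
    p1: ReadPlacement,
    p2: ReadPlacement,
    folded: FoldedContig,
    stems: Sequence[Stem] | None = None,
    overlap_frac: float = 0.6,
    duplex_frac: float = 0.5,
    duplex_slack: int = 3,
    stem_gap_max: int = 3,
) -> StemCheck:
    """Test whether two placements form a stem duplex.

    True requires a stem holding at least ``overlap_frac`` of each read's
    paired bases, the two reads on opposite arms of that stem, and at least
    ``duplex_frac`` of p1's paired bases partnered inside p2's interval
    (extended by ``duplex_slack`` nt).
    """
    if p1.contig_id != p2.contig_id or p1.contig_id != folded.contig_id:
        raise ParameterError("placements must be on the given folded contig")
    if stems is None:
        stems = extract_stems(folded, gap_max=stem_gap_max)
    paired1 = _paired_positions(p1, folded)
    paired2 = _paired_positions(p2, folded)
    if not paired1 or not paired2:
        return StemCheck(False, False, False, None, None)

    in_duplex = sum(
        1
        for i in paired1
        if p2.start - duplex_slack <= folded.partner[i] < p2.end + duplex_slack
    )
    duplex = in_duplex >= duplex_frac * len(paired1)

    for stem in stems:
        positions = stem.positions()
        frac1 = sum(1 for i in paired1 if i in positions) / len(paired1)
        frac2 = sum(1 for i in paired2 if i in positions) / len(paired2)
        if frac1 < overlap_frac or frac2 < overlap_frac:
            continue
        arm1 = _arm_of(paired1, stem)
        arm2 = _arm_of(paired2, stem)
        if arm1 is None or arm2 is None or arm1 == arm2:
            continue
        return StemCheck(duplex, True, duplex, stem, arm1)
    return StemCheck(False, False, duplex, None, None)


def _lib_union(classes: Iterable[str]) -> str:
    s = set(classes)
    if "B" in s or {"M", "F"} <= s:
        return "B"
    return "M" if s == {"M"} else "F"


def call_candidates(
    precursors: dict[str, list[ReadPlacement]],
    folded: Sequence[FoldedContig],
    config: RunConfig | None = None,
) -> tuple[list[MilRnaCandidate], list[PrecursorCall]]:
    """Apply the duplex criteria and emit accessioned candidates.

    Per precursor: reads pass when they sit in a validated duplex whose
    counts are strictly unequal; the higher-count member of a read's best
    duplex is the milR, the other the milR*.  Retained reads are clustered
    into families by arm and 5'-end proximity and named
    ``<prefix>-<locus><family letter>-<variant>`` (letter omitted for a
    single-family precursor, variant omitted for a single-read family).
    """
    config = config or RunConfig()
    folded_map = {f.contig_id: f for f in folded}
    candidates: list[MilRnaCandidate] = []
    precursor_calls: list[PrecursorCall] = []
    locus_no = 0
    for f in folded:
        ps_all = precursors.get(f.contig_id)
        if not ps_all:
            continue
        # one placement per distinct sequence: fewest mismatches, then leftmost
        best_by_seq: dict[str, ReadPlacement] = {}
        for p in sorted(ps_all, key=lambda p: (p.sequence, p.mismatches, p.start)):
            best_by_seq.setdefault(p.sequence, p)
        reads = sorted(best_by_seq.values(), key=lambda p: (p.start, p.sequence))
        stems = extract_stems(f, gap_max=config.stem_gap_max)

        # duplex edges between distinct sequences with unequal counts
        partners: dict[str, list[tuple[ReadPlacement, Stem, str]]] = {}
        for a_idx in range(len(reads)):
            for b_idx in range(a_idx + 1, len(reads)):
                a, b = reads[a_idx], reads[b_idx]
                if a.sRNA.total == b.sRNA.total:
                    continue
                chk = same_stem_check(
                    a,
                    b,
                    f,
                    stems=stems,
                    overlap_frac=config.stem_overlap_frac,
                    duplex_frac=config.duplex_overlap_frac,
                    duplex_slack=config.duplex_slack_nt,
                    stem_gap_max=config.stem_gap_max,
                )
                if not chk.ok:
                    continue
                arm_a = chk.arm_of_p1
                arm_b = "3p" if arm_a == "5p" else "5p"
                partners.setdefault(a.sequence, []).append((b, chk.stem, arm_a))
                partners.setdefault(b.sequence, []).append((a, chk.stem, arm_b))

        retained: list[tuple[ReadPlacement, str, Stem, str]] = []
        for p in reads:
            links = partners.get(p.sequence)
            if not links:
                continue
            best_partner, stem, arm = max(
                links, key=lambda t: (t[0].sRNA.total, t[0].sequence)
            )
            role = "milR" if p.sRNA.total > best_partner.sRNA.total else "milRstar"
            retained.append((p, role, stem, arm))
        if not retained:
            continue

        locus_no += 1
        # family = (stem, arm) group, then chain-cluster 5' starts
        stem_order = {id(s): i for i, s in enumerate(stems)}
        by_group: dict[tuple[int, str], list[tuple[ReadPlacement, str]]] = {}
        for p, role, stem, arm in retained:
            by_group.setdefault((stem_order[id(stem)], arm), []).append((p, role))
        families: list[tuple[tuple[int, int, int], list[tuple[ReadPlacement, str]]]] = []
        for (stem_i, arm), members in by_group.items():
            members.sort(key=lambda t: (t[0].start, t[0].sequence))
            cluster: list[tuple[ReadPlacement, str]] = []
            for item in members:
                if cluster and item[0].start - cluster[-1][0].start > config.locus_cluster_nt:
                    families.append(
                        ((stem_i, 0 if arm == "5p" else 1, cluster[0][0].start), cluster)
                    )
                    cluster = []
                cluster.append(item)
            if cluster:
                families.append(
                    ((stem_i, 0 if arm == "5p" else 1, cluster[0][0].start), cluster)
                )
        families.sort(key=lambda t: t[0])

        n_cand_here = 0
        classes_here: list[str] = []
        for fam_idx, (key, members) in enumerate(families):
            letter = chr(ord("a") + fam_idx) if len(families) > 1 else ""
            arm = "5p" if key[1] == 0 else "3p"
            members = sorted(members, key=lambda t: (-t[0].sRNA.total, t[0].sequence))
            for var_idx, (p, role) in enumerate(members, start=1):
                acc = f"{config.accession_prefix}-{locus_no}{letter}"
                if len(members) > 1:
                    acc += f"-{var_idx}"
                candidates.append(
                    MilRnaCandidate(
                        accession=acc,
                        precursor_id=f.contig_id,
                        contig_id=f.contig_id,
                        arm=arm,
                        role=role,
                        sequence=p.sequence,
                        start=p.start,
                        mismatches=p.mismatches,
                        count_MY=p.sRNA.count_MY,
                        count_FB=p.sRNA.count_FB,
                    )
                )
                classes_here.append(p.sRNA.lib_class)
                n_cand_here += 1
        precursor_calls.append(
            PrecursorCall(
                precursor_id=f.contig_id,
                contig_id=f.contig_id,
                n_candidates=n_cand_here,
                lib_class=_lib_union(classes_here),
            )
        )
    return candidates, precursor_calls


def _best_ungapped_overlap(query: str, ref: str, min_overlap: int) -> int | None:
    """Fewest mismatches over any ungapped overlap of >= ``min_overlap`` nt."""
    best: int | None = None
    for shift in range(-(len(query) - min_overlap), len(ref) - min_overlap + 1):
        q0 = max(0, -shift)
        r0 = max(0, shift)
        span = min(len(query) - q0, len(ref) - r0)
        if span < min_overlap:
            continue
        mm = sum(
            1 for a, b in zip(query[q0 : q0 + span], ref[r0 : r0 + span]) if a != b
        )
        if best is None or mm < best:
            best = mm
    return best


def annotate_conserved(
    grouped: Sequence[GroupedSRna],
    mature_ref: Sequence[SequenceRecord],
    folded: Sequence[FoldedContig],
    config: RunConfig | None = None,
) -> list[ConservedHit]:
    """Annotate grouped sRNAs against a mature miRNA reference.

    A hit needs an ungapped alignment covering at least
    ``conserved_min_overlap`` nt with at most ``conserved_mm_max`` mismatches,
    and the sRNA must itself sit on a stem of some folded contig.
    """
    config = config or RunConfig()
    if not mature_ref:
        raise ParameterError("mature reference is empty")
    hits: list[ConservedHit] = []
    stems_by_contig = {
        f.contig_id: extract_stems(f, gap_max=config.stem_gap_max) for f in folded
    }
    for g in grouped:
        best: tuple[int, str] | None = None
        for ref in mature_ref:
            mm = _best_ungapped_overlap(
                g.sequence, ref.sequence, config.conserved_min_overlap
            )
            if mm is None or mm > config.conserved_mm_max:
                continue
            if best is None or (mm, ref.id) < best:
                best = (mm, ref.id)
        if best is None:
            continue
        stem_located = False
        for p in map_reads([g], folded, mismatch_max=config.mismatch_max):
            f = next(fc for fc in folded if fc.contig_id == p.contig_id)
            read_len = len(p.sequence)
            for stem in stems_by_contig[p.contig_id]:
                positions = stem.positions()
                n_in = sum(1 for i in range(p.start, p.end) if i in positions)
                if n_in >= config.conserved_stem_frac * read_len:
                    stem_located = True
                    break
            if stem_located:
                break
        if stem_located:
            hits.append(
                ConservedHit(
                    sequence=g.sequence,
                    ref_name=best[1],
                    mismatches=best[0],
                    stem_located=True,
                )
            )
    return hits
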