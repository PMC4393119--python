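from __future__ import annotations

import numpy as np
import pytest

from _oracles import naive_placements
from milseek.discover import (
    annotate_conserved,
    call_candidates,
    find_precursor_candidates,
    map_reads,
    same_stem_check,
    ReadPlacement,
)
from milseek.fold import fold
from milseek.io import ParameterError, RunConfig, SequenceRecord
from milseek.preprocess import GroupedSRna
from milseek.simulate import make_hairpin


def _folded(seq, cid="c1"):
    return fold(seq, contig_id=cid)


def _grouped(seq, my=1, fb=0):
    return GroupedSRna(seq, my, fb)


def _rand_rna(rng, n):
    return "".join("ACGU"[i] for i in rng.integers(0, 4, n))


class TestMapReads:
    def test_exact_placement(self):
        rng = np.random.default_rng(1)
        contig = _rand_rna(rng, 60)
        read = contig[10:32]
        f = _folded(contig)
        placements = map_reads([_grouped(read)], [f])
        assert any(p.start == 10 and p.mismatches == 0 for p in placements)

    def test_three_mismatches_placed_four_not(self):
        rng = np.random.default_rng(2)
        contig = _rand_rna(rng, 60)
        read = list(contig[15:37])
        positions = [2, 8, 14, 20]
        for n_mut, expected in ((3, True), (4, False)):
            mutated = list(read)
            for p in positions[:n_mut]:
                mutated[p] = {"A": "C", "C": "A", "G": "U", "U": "G"}[mutated[p]]
            got = map_reads([_grouped("".join(mutated))], [_folded(contig)])
            placed = any(p.start == 15 for p in got)
            assert placed is expected

    def test_matches_naive_oracle(self):
        rng = np.random.default_rng(3)
        for trial in range(50):
            contig = _rand_rna(rng, 80)
            read = _rand_rna(rng, 18)
            f = _folded(contig, cid=f"c{trial}")
            for mm in (0, 1, 3):
                got = {
                    (p.start, p.mismatches)
                    for p in map_reads([_grouped(read)], [f], mismatch_max=mm)
                }
                assert got == naive_placements(read, contig, mm)

    def test_mismatch_monotonicity(self):
        rng = np.random.default_rng(4)
        contig = _rand_rna(rng, 120)
        reads = [_grouped(_rand_rna(rng, 20)) for _ in range(10)]
        f = _folded(contig)
        n_prev = None
        for mm in (0, 1, 2, 3, 4):
            n = len(map_reads(reads, [f], mismatch_max=mm))
            if n_prev is not None:
                assert n >= n_prev
            n_prev = n


class TestPrecursorCandidates:
    def test_two_distinct_reads_keep_contig(self):
        rng = np.random.default_rng(5)
        contig = _rand_rna(rng, 60)
        f = _folded(contig)
        g1, g2 = _grouped(contig[5:25]), _grouped(contig[30:50])
        placements = map_reads([g1, g2], [f])
        assert f.contig_id in find_precursor_candidates(placements, [f])

    def test_single_read_high_count_dropped(self):
        rng = np.random.default_rng(6)
        contig = _rand_rna(rng, 60)
        f = _folded(contig)
        placements = map_reads([_grouped(contig[5:25], my=1000)], [f])
        assert find_precursor_candidates(placements, [f]) == {}

    def test_same_sequence_twice_is_one_read(self):
        # a single sequence placed at two offsets is still one distinct sRNA
        unit = "GGAUCCAAGGAUCCAA"
        contig = unit + "UUUU" + unit + "AAAA"
        f = _folded(contig)
        g = _grouped(unit)
        placements = map_reads([g], [f])
        assert len({p.start for p in placements}) >= 2
        assert find_precursor_candidates(placements, [f]) == {}


class TestSameStemCheck:
    def _planted(self, seed=7):
        rng = np.random.default_rng(seed)
        milR = "U" + _rand_rna(rng, 21)
        precursor = make_hairpin(milR, 8, 0)
        star = precursor[len(milR) + 8 :]
        contig = _rand_rna(rng, 30) + precursor + _rand_rna(rng, 30)
        f = _folded(contig)
        p1 = ReadPlacement(_grouped(milR, my=50), "c1", contig.find(milR), 0)
        p2 = ReadPlacement(_grouped(star, my=5), "c1", contig.find(star), 0)
        return f, p1, p2

    def test_planted_duplex_true(self):
        f, p1, p2 = self._planted()
        chk = same_stem_check(p1, p2, f)
        assert chk.ok and chk.same_stem and chk.duplex
        assert chk.arm_of_p1 == "5p"

    def test_same_arm_false(self):
        f, p1, _ = self._planted()
        shifted = ReadPlacement(
            _grouped(f.sequence[p1.start + 2 : p1.start + 20]), "c1", p1.start + 2, 0
        )
        chk = same_stem_check(p1, shifted, f)
        assert not chk.ok

    def test_two_hairpins_false(self):
        rng = np.random.default_rng(8)
        m1 = "U" + _rand_rna(rng, 20)
        m2 = "A" + _rand_rna(rng, 20)
        h1, h2 = make_hairpin(m1, 6, 0), make_hairpin(m2, 6, 0)
        contig = h1 + "AACAACAAC" + h2
        f = _folded(contig)
        s2 = h2[len(m2) + 6 :]
        p1 = ReadPlacement(_grouped(m1, my=50), "c1", contig.find(m1), 0)
        p2 = ReadPlacement(_grouped(s2, my=5), "c1", contig.find(s2), 0)
        assert not same_stem_check(p1, p2, f).same_stem

    def test_different_contigs_raise(self):
        f, p1, p2 = self._planted()
        p2.contig_id = "other"
        with pytest.raises(ParameterError):
            same_stem_check(p1, p2, f)


class TestCallCandidates:
    def _setup(self, count_a, count_b, seed=9):
        rng = np.random.default_rng(seed)
        milR = "U" + _rand_rna(rng, 21)
        precursor = make_hairpin(milR, 8, 0)
        star = precursor[len(milR) + 8 :]
        contig = _rand_rna(rng, 40) + precursor + _rand_rna(rng, 40)
        f = _folded(contig)
        grouped = [_grouped(milR, my=count_a), _grouped(star, my=count_b)]
        placements = map_reads(grouped, [f])
        precursors = find_precursor_candidates(placements, [f])
        return call_candidates(precursors, [f], RunConfig())

    def test_higher_count_is_milR(self):
        candidates, _ = self._setup(100, 5)
        roles = {c.role: c for c in candidates}
        assert roles["milR"].count_MY == 100
        assert roles["milRstar"].count_MY == 5
        assert roles["milR"].arm == "5p" and roles["milRstar"].arm == "3p"

    def test_equal_counts_discarded(self):
        candidates, precursor_calls = self._setup(7, 7)
        assert candidates == [] and precursor_calls == []

    def test_role_antisymmetry(self):
        candidates, _ = self._setup(60, 12)
        by_acc_family = {}
        for c in candidates:
            by_acc_family.setdefault(c.precursor_id, []).append(c)
        for group in by_acc_family.values():
            assert sum(1 for c in group if c.role == "milR") == 1

    def test_lib_class_partition(self, clean_study):
        candidates = clean_study["candidates"]
        counts = {cls: 0 for cls in "MFB"}
        for c in candidates:
            counts[c.lib_class] += 1
        assert sum(counts.values()) == len(candidates)

    def test_accessions_unique_and_prefixed(self, clean_study):
        accs = [c.accession for c in clean_study["candidates"]]
        assert len(accs) == len(set(accs))
        assert all(a.startswith("aci-milR-") for a in accs)

    def test_variant_clustering_groups_shifted_reads(self):
        rng = np.random.default_rng(10)
        milR = "U" + _rand_rna(rng, 21)
        precursor = make_hairpin(milR, 8, 0)
        star = precursor[len(milR) + 8 :]
        contig = _rand_rna(rng, 40) + precursor + _rand_rna(rng, 40)
        f = _folded(contig)
        variant = contig[contig.find(milR) + 1 : contig.find(milR) + 23]
        grouped = [
            _grouped(milR, my=100),
            _grouped(variant, my=40),
            _grouped(star, my=5),
        ]
        placements = map_reads(grouped, [f])
        candidates, _ = call_candidates(
            find_precursor_candidates(placements, [f]), [f], RunConfig()
        )
        milr_accs = sorted(c.accession for c in candidates if c.arm == "5p")
        # same family letter, numbered variants
        assert len(milr_accs) == 2
        prefixes = {a.rsplit("-", 1)[0] for a in milr_accs}
        assert len(prefixes) == 1


class TestAnnotateConserved:
    def _study(self, seed=11):
        rng = np.random.default_rng(seed)
        milR = "U" + _rand_rna(rng, 21)
        precursor = make_hairpin(milR, 8, 0)
        contig = _rand_rna(rng, 30) + precursor + _rand_rna(rng, 30)
        return milR, _folded(contig)

    def test_identical_stem_located_hit(self):
        milR, f = self._study()
        ref = [SequenceRecord("mir-1", milR)]
        hits = annotate_conserved([_grouped(milR, my=3)], ref, [f])
        assert len(hits) == 1 and hits[0].mismatches == 0
        assert hits[0].ref_name == "mir-1"

    def test_loop_only_placement_no_hit(self):
        # sRNA matching a reference but placing on an unpaired region only
        loop_read = "C" * 20  # no G anywhere: nothing can pair
        contig = "A" * 25 + loop_read + "A" * 25  # folds to all dots
        f = _folded(contig)
        assert f.score == 0
        ref = [SequenceRecord("mir-2", loop_read)]
        assert annotate_conserved([_grouped(loop_read)], ref, [f]) == []

    def test_three_mismatches_no_hit(self):
        milR, f = self._study()
        mutated = list(milR)
        for i in (2, 8, 14):
            mutated[i] = {"A": "C", "C": "A", "G": "U", "U": "G"}[mutated[i]]
        ref = [SequenceRecord("mir-3", "".join(mutated))]
        assert annotate_conserved([_grouped(milR)], ref, [f]) == []

    def test_empty_reference_raises(self):
        milR, f = self._study()
        with pytest.raises(ParameterError):
            annotate_conserved([_grouped(milR)], [], [f])
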