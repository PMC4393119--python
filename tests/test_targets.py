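from __future__ import annotations

import numpy as np
import pytest

from _oracles import min_expectation
from milseek.expression import ExpressionRecord
from milseek.io import ParameterError, RunConfig, SequenceRecord, revcomp_rna
from milseek.targets import (
    TargetHit,
    cross_filter,
    expectation_score,
    scan_targets,
)


def _rand_rna(rng, n):
    return "".join("ACGU"[i] for i in rng.integers(0, 4, n))


class TestExpectationScore:
    def test_exact_reverse_complement_scores_zero(self):
        rng = np.random.default_rng(0)
        m = _rand_rna(rng, 22)
        aln = expectation_score(m, revcomp_rna(m))
        assert aln.penalty == 0.0
        assert all(ev == "match" for _, ev in aln.ops)

    def test_wobble_weights_by_position(self):
        # milRNA with G at position 20 (outside core) and position 5 (core)
        m = "UAAAGAAAAAAAAAAAAAAGAA"
        site = list(revcomp_rna(m))
        s1 = site.copy()
        s1[len(m) - 20] = "U"  # faces milRNA position 20: G:U wobble
        assert expectation_score(m, "".join(s1)).penalty == pytest.approx(0.5)
        s2 = site.copy()
        s2[len(m) - 5] = "U"  # same wobble at position 5, inside core
        assert expectation_score(m, "".join(s2)).penalty == pytest.approx(1.0)

    def test_gap_allows_shifted_site(self):
        rng = np.random.default_rng(1)
        m = _rand_rna(rng, 22)
        site = revcomp_rna(m)
        deleted = site[:10] + site[11:]  # one less site base: one gap
        aln = expectation_score(m, deleted)
        assert aln.penalty <= 4.0
        assert any(ev == "gap" for _, ev in aln.ops)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            n = int(rng.integers(18, 25))
            m = _rand_rna(rng, n)
            site = list(revcomp_rna(m))
            for _ in range(int(rng.integers(0, 5))):  # sprinkle mutations
                site[int(rng.integers(0, len(site)))] = "ACGU"[int(rng.integers(0, 4))]
            site = "".join(site)
            got = expectation_score(m, site).penalty
            assert got == pytest.approx(min_expectation(m, site))

    def test_length_bounds(self):
        with pytest.raises(ParameterError):
            expectation_score("ACGU" * 4, "ACGU" * 4)  # 16 nt milRNA

    def test_site_too_different_in_length(self):
        rng = np.random.default_rng(3)
        m = _rand_rna(rng, 22)
        with pytest.raises(ParameterError):
            expectation_score(m, _rand_rna(rng, 28))

    def test_monotone_in_mismatches(self):
        rng = np.random.default_rng(4)
        m = _rand_rna(rng, 22)
        site = list(revcomp_rna(m))
        prev = expectation_score(m, "".join(site)).penalty
        for i in (3, 9, 15):
            site[i] = {"A": "C", "C": "A", "G": "A", "U": "C"}[site[i]]
            cur = expectation_score(m, "".join(site)).penalty
            assert cur >= prev
            prev = cur


class TestScanTargets:
    def test_exact_complement_hit_cleavage(self):
        rng = np.random.default_rng(5)
        m = _rand_rna(rng, 22)
        uni = SequenceRecord("u1", _rand_rna(rng, 40) + revcomp_rna(m) + _rand_rna(rng, 40))
        (hit,) = scan_targets([("mil-1", m, "M")], [uni])
        assert hit.expectation == 0.0
        assert hit.align_start == 40
        assert hit.inhibition == "Cleavage"

    def test_central_mismatch_translation(self):
        rng = np.random.default_rng(6)
        m = _rand_rna(rng, 22)
        site = list(revcomp_rna(m))
        idx = len(m) - 10  # faces milRNA position 10
        comp = {"A": "U", "U": "A", "C": "G", "G": "C"}[m[9]]
        wob = {"G": "U", "U": "G"}.get(m[9])
        site[idx] = next(b for b in "ACGU" if b not in {comp, wob})
        uni = SequenceRecord("u1", "AAAA" + "".join(site) + "AAAA")
        (hit,) = scan_targets([("mil-1", m, "M")], [uni])
        assert hit.inhibition == "Translation"

    def test_no_window_under_threshold(self):
        # poly-A unigene cannot complement a poly-A milRNA
        m = "A" * 22
        uni = SequenceRecord("u1", "A" * 120)
        assert scan_targets([("mil-1", m, "M")], [uni]) == []

    def test_threshold_subset_property(self):
        rng = np.random.default_rng(7)
        milrnas = [("mil-%d" % i, _rand_rna(rng, 22), "M") for i in range(3)]
        unis = []
        for i in range(4):
            site = list(revcomp_rna(milrnas[i % 3][1]))
            for _ in range(int(rng.integers(0, 6))):
                site[int(rng.integers(0, len(site)))] = "ACGU"[int(rng.integers(0, 4))]
            unis.append(
                SequenceRecord(f"u{i}", _rand_rna(rng, 30) + "".join(site) + _rand_rna(rng, 30))
            )
        strict = scan_targets(milrnas, unis, RunConfig(expectation_max=3.0))
        loose = scan_targets(milrnas, unis, RunConfig(expectation_max=4.0))
        strict_pairs = {(h.milrna_acc, h.target_id) for h in strict}
        loose_pairs = {(h.milrna_acc, h.target_id) for h in loose}
        assert strict_pairs <= loose_pairs

    def test_one_hit_per_pair(self):
        rng = np.random.default_rng(8)
        m = _rand_rna(rng, 22)
        site = revcomp_rna(m)
        uni = SequenceRecord("u1", site + "AAAA" + site)
        hits = scan_targets([("mil-1", m, "M")], [uni])
        assert len(hits) == 1
        assert hits[0].align_start == 0  # ties resolve to the leftmost site


def _expr(uid, deg_class, rpkm_my=1.0, rpkm_fb=2.0):
    return ExpressionRecord(
        unigene_id=uid,
        length_bp=1000,
        count_MY=10,
        count_FB=20,
        rpkm_MY=rpkm_my,
        rpkm_FB=rpkm_fb,
        deg_class=deg_class,
    )


def _hit(acc="mil-1", target="u1", lib="M"):
    return TargetHit(
        milrna_acc=acc,
        target_id=target,
        expectation=0.0,
        align_start=0,
        site_len=22,
        inhibition="Cleavage",
        lib=lib,
    )


class TestCrossFilter:
    def test_m_class_keeps_up_fb(self):
        kept = cross_filter([_hit(lib="M")], [_expr("u1", "up_FB")])
        assert len(kept) == 1
        assert kept[0].f_rpkm == 2.0 and kept[0].m_rpkm == 1.0

    def test_m_class_drops_up_my(self):
        assert cross_filter([_hit(lib="M")], [_expr("u1", "up_MY")]) == []

    def test_f_class_drops_not_de(self):
        assert cross_filter([_hit(lib="F")], [_expr("u1", "not_DE")]) == []

    def test_b_class_keeps_both_directions(self):
        for cls in ("up_MY", "up_FB", "MY_specific", "FB_specific"):
            assert len(cross_filter([_hit(lib="B")], [_expr("u1", cls)])) == 1

    def test_missing_expression_dropped_with_warning(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="milseek.targets"):
            kept = cross_filter([_hit(target="unknown")], [_expr("u1", "up_FB")])
        assert kept == []
        assert any("unknown" in r.message for r in caplog.records)
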