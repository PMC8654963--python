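"""Microhomology calls, insertion-origin mapping and spectrum summaries."""

import numpy as np
import pytest

from dsbfoot.allele_caller import RepairEvent, canonicalize, reconstruct
from dsbfoot.junction_classifier import (
    annotate_event,
    chi_square_2x2,
    classify_mh,
    junction_mh,
    map_insertion,
    revcomp,
    spectrum_summary,
)
from dsbfoot.locus_model import Interval
from conftest import random_seq
from oracles import chi2_2x2_hand, deletion_placements


class TestJunctionMh:
    def test_distinct_context_has_no_mh(self):
        # every base around the junction differs
        ref = "AACCGGTTACGTGCATTA"
        mh = junction_mh(ref, Interval(4, 9))
        assert mh.length == 0 and mh.mh_class == "none" and mh.placements == 1

    def test_repeat_context_counts_total_ambiguity(self):
        mh = junction_mh("ACGTACGTAA", Interval(0, 4))
        # placements s=0..5 all give "ACGTAA": enumeration yields 6
        assert deletion_placements("ACGTACGTAA", 4, 0, "ACGTAA") == 6
        assert mh.length == 5 and mh.placements == 6
        assert mh.sequence == "ACGTA"

    def test_placement_invariance_across_equivalent_placements(self):
        ref = "ACGTACGTAA"
        for s in range(6):
            assert junction_mh(ref, Interval(s, s + 4)).length == 5

    def test_empty_deletion_rejected(self):
        with pytest.raises(ValueError):
            junction_mh("ACGT", Interval(2, 2))

    def test_truncation_flagged_at_sequence_edge(self):
        assert junction_mh("ACGTACGTAA", Interval(0, 4)).truncated
        assert not junction_mh("TTACGTACGTAATT", Interval(2, 6)).truncated

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_placement_enumeration_oracle(self, seed):
        """MH length + 1 == number of placements giving an identical product."""
        rng = np.random.default_rng(seed)
        for _ in range(200):
            ref = random_seq(rng, 80)
            L = int(rng.integers(1, 20))
            s = int(rng.integers(0, 80 - L))
            mh = junction_mh(ref, Interval(s, s + L))
            product = ref[:s] + ref[s + L :]
            assert mh.placements == deletion_placements(ref, L, 0, product)
            assert mh.placements == mh.length + 1


class TestClassifyMh:
    @pytest.mark.parametrize(
        "length,cls",
        [(0, "none"), (1, "minute"), (5, "minute"), (6, "extended"), (25, "extended")],
    )
    def test_boundaries(self, length, cls):
        """The minute/extended boundary is >5 bp."""
        assert classify_mh(length) == cls

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_mh(-1)


class TestMapInsertion:
    def _context(self, seed=0, n=700):
        rng = np.random.default_rng(seed)
        return random_seq(rng, n), Interval(300, 380)

    def test_short_insertion_unmappable(self):
        ref, dl = self._context()
        ann = map_insertion("ACG", ref, dl, seg_min=8)
        assert ann.ins_class == "too_short" and ann.segments == ()

    def test_right_flank_copy_is_templated_simple(self):
        ref, dl = self._context()
        ins = ref[dl.end + 30 : dl.end + 42]  # exact 12-mer from the right flank
        ann = map_insertion(ins, ref, dl)
        assert ann.ins_class == "templated_simple"
        assert ann.covered_frac == 1.0
        assert len(ann.segments) == 1
        seg = ann.segments[0]
        assert seg.flank == "right" and seg.strand == "+"
        assert (seg.origin.start, seg.origin.end) == (dl.end + 30, dl.end + 42)

    def test_reverse_complement_segment_mapped(self):
        ref, dl = self._context(seed=1)
        ins = revcomp(ref[dl.start - 50 : dl.start - 38])
        ann = map_insertion(ins, ref, dl)
        assert ann.ins_class == "templated_simple"
        assert ann.segments[0].strand == "-"

    def test_revcomp_disabled(self):
        ref, dl = self._context(seed=1)
        ins = revcomp(ref[dl.start - 50 : dl.start - 38])
        ann = map_insertion(ins, ref, dl, allow_revcomp=False)
        assert ann.ins_class == "unmapped"

    def test_duplicated_stretch_is_patchwork(self):
        ref, dl = self._context(seed=2)
        piece = ref[dl.start - 60 : dl.start - 50]  # 10-mer from the left flank
        ann = map_insertion(piece + piece, ref, dl)
        assert ann.ins_class == "templated_patchwork"
        assert ann.repeated_stretch
        assert len(ann.segments) == 2

    def test_two_distinct_flank_pieces_are_patchwork(self):
        ref, dl = self._context(seed=3)
        ins = ref[dl.start - 40 : dl.start - 30] + ref[dl.end + 10 : dl.end + 20]
        ann = map_insertion(ins, ref, dl)
        assert ann.ins_class == "templated_patchwork"
        assert len(ann.segments) == 2
        assert {s.flank for s in ann.segments} == {"left", "right"}

    def test_random_insert_unmapped(self):
        ref, dl = self._context(seed=4)
        rng = np.random.default_rng(99)
        # insert drawn from an unrelated sequence
        ins = random_seq(rng, 14)
        ann = map_insertion(ins, ref, dl, window=100)
        assert ann.ins_class in ("unmapped", "templated_simple")

    def test_deleted_sequence_origin_labelled_inside_del(self):
        ref, dl = self._context(seed=5)
        ins = ref[dl.start + 20 : dl.start + 32]
        ann = map_insertion(ins, ref, dl)
        assert ann.segments[0].flank == "inside_del"

    def test_label_recovery_on_synthetic_inserts(self):
        """Generator-labelled simple/patchwork events and random (non-flank)
        inserts are recovered at >= 95% each."""
        from dsbfoot import synthetic_data as sd

        n = 200
        ok = {"simple": 0, "patch": 0}
        for key, p_patch, seed in (("patch", 1.0, 41), ("simple", 0.0, 42)):
            cfg = sd.SimConfig(seed=seed)
            cfg.tmej.p_ins = 1.0
            cfg.tmej.p_patch = p_patch
            rng = np.random.default_rng(seed)
            base = sd.make_locus(cfg, rng)
            want = "templated_patchwork" if p_patch else "templated_simple"
            for _ in range(n):
                ev = sd.simulate_tmej(base, cfg, rng)
                ann = map_insertion(ev.event.ins_seq, ev.locus.seq, ev.event.del_iv)
                ok[key] += ann.ins_class == want
        assert ok["simple"] >= 0.95 * n
        assert ok["patch"] >= 0.95 * n

        rng = np.random.default_rng(43)
        unmapped = 0
        for _ in range(n):
            ref = random_seq(rng, 800)
            dl = Interval(350, 430)
            rand = random_seq(rng, 14)  # unrelated sequence, not from the flanks
            unmapped += map_insertion(rand, ref, dl).ins_class == "unmapped"
        assert unmapped >= 0.95 * n


class TestAnnotateEvent:
    def test_simple_deletion_without_mh(self):
        ref = "AACCGGTTACGTGCATTA"
        ev = canonicalize(RepairEvent("L", "deletion", Interval(4, 9), ""), ref)
        ann = annotate_event(ev, ref)
        assert ann.spectrum_code == "simple_no_mh"

    def test_extended_mh_deletion(self):
        rng = np.random.default_rng(21)
        seq = list(random_seq(rng, 400))
        rep = random_seq(rng, 8)
        seq[100:108] = list(rep)
        seq[200:208] = list(rep)
        ref = "".join(seq)
        ev = canonicalize(RepairEvent("L", "deletion", Interval(100, 200), ""), ref)
        ann = annotate_event(ev, ref)
        assert ann.spectrum_code == "simple_mh"
        assert ann.mh.length >= 8 and ann.mh.mh_class == "extended"

    def test_unmappable_insert_is_dark_red(self):
        rng = np.random.default_rng(22)
        ref = random_seq(rng, 500)
        ev = RepairEvent("L", "delins", Interval(200, 260), "TTTTTA")
        ev = canonicalize(ev, ref)
        ann = annotate_event(ev, ref)
        # a 6-mer is below seg_min, hence of undetermined origin
        assert ann.spectrum_code == "delins_unmapped"
        assert ann.insertion.ins_class == "too_short"

    def test_wild_type_carries_no_code(self):
        ev = RepairEvent("L", "wild_type", Interval(0, 0), "")
        ann = annotate_event(ev, "ACGT" * 30)
        assert ann.spectrum_code is None and ann.mh is None


class TestSpectrumSummary:
    def _annotations(self, ref, events):
        return [annotate_event(canonicalize(e, ref), ref) for e in events]

    def test_no_insertions(self):
        rng = np.random.default_rng(31)
        ref = random_seq(rng, 400)
        events = [
            RepairEvent("L", "deletion", Interval(100 + i, 200 + i), "")
            for i in range(10)
        ]
        s = spectrum_summary(self._annotations(ref, events))
        assert s.n_events == 10
        assert s.frac_with_insertion == 0.0

    def test_binomial_recovery_of_insertion_fraction(self):
        """Configured 30% insertion fraction recovered within 3 s.e. at n=1000."""
        rng = np.random.default_rng(32)
        ref = random_seq(rng, 600)
        events = []
        for _ in range(1000):
            ins = random_seq(rng, 10) if rng.random() < 0.30 else ""
            s = int(rng.integers(100, 200))
            events.append(
                RepairEvent(
                    "L", "delins" if ins else "deletion", Interval(s, s + 150), ins
                )
            )
        summ = spectrum_summary(self._annotations(ref, events))
        se = 100 * np.sqrt(0.3 * 0.7 / 1000)
        assert abs(summ.frac_with_insertion - 30.0) <= 3 * se

    def test_additivity_of_counts(self):
        rng = np.random.default_rng(33)
        ref = random_seq(rng, 400)
        a = self._annotations(
            ref, [RepairEvent("L", "deletion", Interval(100, 180), "")] * 3
        )
        b = self._annotations(
            ref, [RepairEvent("L", "delins", Interval(100, 180), "GATTACAGATT")] * 2
        )
        s_all = spectrum_summary(a + b)
        s_a, s_b = spectrum_summary(a), spectrum_summary(b)
        assert s_all.n_events == s_a.n_events + s_b.n_events
        for code in set(s_a.class_counts) | set(s_b.class_counts):
            assert s_all.class_counts.get(code, 0) == s_a.class_counts.get(
                code, 0
            ) + s_b.class_counts.get(code, 0)

    def test_empty_input(self):
        s = spectrum_summary([])
        assert s.n_events == 0 and s.frac_with_insertion == 0.0


class TestChiSquare:
    def test_homogeneous_table(self):
        stat, p = chi_square_2x2(10, 10, 10, 10)
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_value(self):
        stat, _ = chi_square_2x2(50, 50, 80, 20)
        assert stat == pytest.approx(chi2_2x2_hand(50, 50, 80, 20))
        assert stat == pytest.approx(19.7802, abs=1e-4)

    def test_transposition_invariance(self):
        assert chi_square_2x2(12, 34, 56, 7)[0] == pytest.approx(
            chi_square_2x2(12, 56, 34, 7)[0]
        )

    def test_zero_marginal_flagged(self):
        with pytest.raises(ValueError):
            chi_square_2x2(0, 0, 5, 5)
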