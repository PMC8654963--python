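"""Generator ground truth: determinism, engineered MH, pathway footprints."""

import numpy as np
import pandas as pd
import pytest

from dsbfoot import synthetic_data as sd
from dsbfoot.allele_caller import call_event, reconstruct
from dsbfoot.junction_classifier import annotate_event, junction_mh
from dsbfoot.locus_model import find_flanking_repeats, find_g4_motifs
from dsbfoot.sanger_qc import find_hq_window, qc_read
from dsbfoot.sv_spectrum import filter_svs, size_spectrum


@pytest.fixture(scope="module")
def cfg():
    return sd.SimConfig(seed=7)


@pytest.fixture(scope="module")
def base_locus(cfg):
    return sd.make_locus(cfg, np.random.default_rng(cfg.seed))


class TestMakeLocus:
    def test_seeded_determinism(self, cfg):
        a = sd.make_locus(cfg, np.random.default_rng(3))
        b = sd.make_locus(cfg, np.random.default_rng(3))
        assert a.seq == b.seq and a.motif == b.motif

    def test_planted_motif_detected(self, base_locus):
        hits = find_g4_motifs(base_locus.seq)
        assert any(h.interval.start == base_locus.motif.start for h in hits)

    def test_no_coincidental_flank_repeat_without_planting(self, cfg):
        rng = np.random.default_rng(11)
        clean = 0
        n = 30
        for _ in range(n):
            locus = sd.make_locus(cfg, rng)
            clean += find_flanking_repeats(locus, window=300, min_len=20) == []
        assert clean >= 0.99 * n - 1  # collision probability is ~1e-7 per locus

    def test_planted_repeat_recovered(self, cfg):
        plant_cfg = sd.SimConfig(seed=7)
        plant_cfg.emh.plant = True
        locus = sd.make_locus(plant_cfg, np.random.default_rng(5))
        truth = sd.planted_repeat_pair(plant_cfg, locus.motif)
        pairs = find_flanking_repeats(locus, window=300, min_len=20)
        assert pairs
        assert (pairs[0].left, pairs[0].right) == (truth.left, truth.right)


class TestSimulateTmej:
    def test_engineered_mh_is_exact(self, base_locus, cfg):
        rng = np.random.default_rng(1)
        for _ in range(50):
            ev = sd.simulate_tmej(base_locus, cfg, rng)
            mh = junction_mh(ev.locus.seq, ev.event.del_iv)
            assert mh.length == ev.provenance["mh"]

    def test_junction_geometry(self, base_locus, cfg):
        rng = np.random.default_rng(2)
        for _ in range(30):
            ev = sd.simulate_tmej(base_locus, cfg, rng)
            s, e = ev.provenance["del_start"], ev.provenance["del_end"]
            assert base_locus.motif.start - 10 <= s < base_locus.motif.start
            assert base_locus.motif.end + 50 <= e <= base_locus.motif.end + 300

    def test_no_insertions_when_p_ins_zero(self, base_locus):
        cfg = sd.SimConfig(seed=7)
        cfg.tmej.p_ins = 0.0
        rng = np.random.default_rng(3)
        events = [sd.simulate_tmej(base_locus, cfg, rng) for _ in range(50)]
        assert all(ev.event.ins_seq == "" for ev in events)
        assert all(ev.truth_label == "tmej_simple" for ev in events)

    def test_product_matches_reconstruction(self, base_locus, cfg):
        rng = np.random.default_rng(4)
        for _ in range(20):
            ev = sd.simulate_tmej(base_locus, cfg, rng)
            assert reconstruct(ev.locus.seq, ev.event) == ev.product_seq

    def test_patchwork_has_mappable_segments(self, base_locus):
        cfg = sd.SimConfig(seed=7)
        cfg.tmej.p_ins = 1.0
        cfg.tmej.p_patch = 1.0
        rng = np.random.default_rng(5)
        for _ in range(20):
            ev = sd.simulate_tmej(base_locus, cfg, rng)
            ann = annotate_event(ev.event, ev.locus.seq)
            assert len(ann.insertion.segments) >= 2

    def test_cohort_proportions_within_three_se(self):
        """Configured insertion and patchwork fractions recovered at n=600."""
        cfg = sd.SimConfig(seed=7)
        events = sd.generate_tmej_cohort(cfg, 600, np.random.default_rng(6))
        n_ins = sum(ev.event.ins_seq != "" for ev in events)
        p = cfg.tmej.p_ins
        se = np.sqrt(p * (1 - p) / 600)
        assert abs(n_ins / 600 - p) <= 3 * se
        n_patch = sum(ev.truth_label == "tmej_patchwork" for ev in events)
        pp = cfg.tmej.p_ins * cfg.tmej.p_patch
        se_p = np.sqrt(pp * (1 - pp) / 600)
        assert abs(n_patch / 600 - pp) <= 3 * se_p


@pytest.fixture(scope="module")
def planted():
    cfg = sd.SimConfig(seed=9)
    cfg.emh.plant = True
    locus = sd.make_locus(cfg, np.random.default_rng(9))
    return cfg, locus


class TestSimulateEmmej:
    def test_junction_carries_extended_mh(self, planted):
        cfg, locus = planted
        rng = np.random.default_rng(1)
        for _ in range(20):
            ev = sd.simulate_emmej(locus, cfg, rng)
            ann = annotate_event(ev.event, locus.seq)
            assert ann.mh.mh_class == "extended"
            assert ann.mh.length >= cfg.emh.repeat_len - cfg.emh.mismatches
            assert ann.spectrum_code == "simple_mh"

    def test_product_retains_exactly_one_repeat_copy(self, planted):
        cfg, locus = planted
        rng = np.random.default_rng(2)
        pair = sd.planted_repeat_pair(cfg, locus.motif)
        repeat = locus.seq[pair.left.start : pair.left.end]
        ev = sd.simulate_emmej(locus, cfg, rng)
        assert ev.product_seq.count(repeat) == 1
        assert locus.seq.count(repeat) == 2


class TestSimulateSsa:
    def test_product_shorter_by_repeat_plus_spacer(self, cfg):
        locus, ev = sd.simulate_ssa_reporter(cfg, np.random.default_rng(1))
        assert len(locus.seq) - len(ev.product_seq) == cfg.ssa.repeat_len + cfg.ssa.spacer_len

    def test_called_event_has_repeat_length_mh(self, cfg):
        locus, ev = sd.simulate_ssa_reporter(cfg, np.random.default_rng(2))
        called = call_event(ev.product_seq, locus.seq, locus)
        ann = annotate_event(called, locus.seq)
        assert ann.mh.length >= cfg.ssa.repeat_len
        assert ann.mh.mh_class == "extended"

    def test_seeded_determinism(self, cfg):
        a = sd.simulate_ssa_reporter(cfg, np.random.default_rng(3))
        b = sd.simulate_ssa_reporter(cfg, np.random.default_rng(3))
        assert a[0].seq == b[0].seq and a[1].product_seq == b[1].product_seq

    def test_construct_contains_cut_site(self, cfg):
        locus, _ = sd.simulate_ssa_reporter(cfg, np.random.default_rng(4))
        assert sd.I_SCEI_SITE in locus.seq


class TestSimulateTd:
    def test_engineered_mh_recovered(self, cfg):
        from dsbfoot.sv_spectrum import td_junction_analysis

        rng = np.random.default_rng(1)
        for _ in range(25):
            ev = sd.simulate_td(cfg, rng)
            td = td_junction_analysis(ev.event, ev.locus.seq)
            if not ev.event.junction_ins:
                assert td.mh.length == ev.provenance["mh"]

    def test_cohort_median_near_one_kb(self, cfg):
        events = sd.generate_td_cohort(cfg, 300, np.random.default_rng(2))
        out = size_spectrum([ev.event for ev in events])
        median = out["per_type"]["TD"]["median"]
        assert abs(median - 1000) / 1000 <= 0.20
        assert out["per_type"]["TD"]["min"] >= 100
        assert out["per_type"]["TD"]["max"] <= 10_000

    def test_low_support_records_filtered(self, cfg):
        rng = np.random.default_rng(3)
        ev = sd.simulate_td(cfg, rng)
        import dataclasses

        weak = dataclasses.replace(ev.event, support_reads=4)
        assert filter_svs([weak]) == []
        assert filter_svs([ev.event]) == [ev.event]

    def test_rearranged_sequence_length(self, cfg):
        ev = sd.simulate_td(cfg, np.random.default_rng(4))
        expected = len(ev.locus.seq) + ev.event.size + len(ev.event.junction_ins)
        assert len(ev.product_seq) == expected


class TestSimulateSangerReads:
    def test_plateau_passes_qc_and_recovers_event(self, base_locus, cfg):
        rng = np.random.default_rng(1)
        ev = sd.simulate_tmej(base_locus, cfg, rng)
        junction = ev.event.del_iv.start
        reads = sd.simulate_sanger_reads(ev.product_seq, cfg, rng, junction=junction)
        masked = qc_read(reads[0])
        assert masked.passed
        called = call_event(masked.bases, ev.locus.seq, ev.locus)
        assert reconstruct(ev.locus.seq, called) == ev.product_seq

    def test_all_low_quality_read_has_no_window(self, cfg):
        low = sd.SangerParams(base_q=5, tail_decay=0.0, plateau_len=100)
        c = sd.SimConfig(seed=1, sanger=low)
        reads = sd.simulate_sanger_reads("ACGT" * 100, c, np.random.default_rng(1))
        assert find_hq_window(reads[0]) is None

    def test_seeded_determinism(self, cfg):
        a = sd.simulate_sanger_reads("ACGT" * 200, cfg, np.random.default_rng(2))
        b = sd.simulate_sanger_reads("ACGT" * 200, cfg, np.random.default_rng(2))
        assert a[0].phred == b[0].phred


class TestExportTruth:
    def test_row_count_and_round_trip(self, base_locus, cfg, tmp_path):
        rng = np.random.default_rng(1)
        events = [sd.simulate_tmej(base_locus, cfg, rng) for _ in range(10)]
        events.append(sd.simulate_td(cfg, rng))
        df = sd.export_truth(events, seed=cfg.seed)
        assert len(df) == 11
        assert (df["seed"] == cfg.seed).all()
        path = tmp_path / "truth.tsv"
        df.to_csv(path, sep="\t", index=False)
        back = pd.read_csv(path, sep="\t", keep_default_na=False)
        assert list(back["truth_label"]) == list(df["truth_label"])
        assert list(back["del_start"]) == list(df["del_start"])
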