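"""Seeded generators of loci, repair products, reads and SV cohorts.

Every other module is tested against ground truth produced here.  The
generators emulate the footprint each repair pathway leaves:

* **TMEJ** — deletion from just upstream of a G4 motif to a point 50–300 bp
  downstream, junction engineered to carry an exact drawn microhomology of
  0–5 bp, optionally with a flank-templated insertion (either strand),
  sometimes with a patchwork configuration of 2–4 concatenated flank
  stretches, possibly reusing one stretch.
* **eMMEJ** — deletion between two planted ~20–30 bp direct repeats flanking
  the motif, retaining one copy, so the junction MH equals the repeat
  length (minus planted mismatches).
* **SSA** — collapse of a reporter construct carrying two ~250 bp identical
  repeats around an I-SceI cut site into a single copy.
* **TD** — tandem duplication with log-normal size (median 1 kb, the
  100 bp – 10 kb range spanning ±3σ) and a TMEJ-like junction (engineered MH, occasional
  templated insert), emitted both as a rearranged sequence and as an
  :class:`~dsbfoot.sv_spectrum.SVRecord` with configurable support fields.
* **Sanger reads** — full-length copies of a product with a high-quality
  Phred plateau around the junction and decaying tails.

Junction engineering edits a private copy of the locus: the bases right of
the junction are overwritten with a copy of the bases entering the deletion
and both ends of the homology run are forced to mismatch, so the MH oracle
returns exactly the drawn length.  All generators are bit-reproducible
given (seed, config).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
import pandas as pd

from dsbfoot.allele_caller import RepairEvent, canonicalize, reconstruct, _classify
from dsbfoot.locus_model import Interval, Locus, RepeatPair, find_g4_motifs
from dsbfoot.sanger_qc import QualifiedRead
from dsbfoot.sv_spectrum import SVRecord, SV_TD

_BASES = np.array(list("ACGT"))

I_SCEI_SITE = "TAGGGATAACAGGGTAAT"


@dataclass
class EmhParams:
    """Planted flanking-repeat (eMH) geometry around the motif."""

    repeat_len: int = 25  # the observed flanking homology is ~20-30 bp
    left_offset: int = 40  # gap between left copy end and motif start
    right_offset: int = 60  # gap between motif end and right copy start
    mismatches: int = 0
    plant: bool = False


@dataclass
class TmejParams:
    mh_choices: tuple[int, ...] = (0, 1, 2, 3, 4, 5)
    p_ins: float = 0.30  # insertion-bearing fraction among deletions
    p_patch: float = 0.14  # patchwork fraction among insertion-bearing events
    ins_len: tuple[int, int] = (8, 20)  # inclusive range, simple inserts
    patch_seg_len: tuple[int, int] = (8, 14)
    patch_n_segments: tuple[int, int] = (2, 4)
    p_patch_reuse: float = 0.3  # chance a patchwork reuses one stretch
    right_junction_offset: tuple[int, int] = (50, 300)  # bp downstream of motif
    upstream_max: int = 10  # left junction within this many bp upstream of motif
    p_revcomp: float = 0.5  # minus-strand templated inserts
    flank_window: int = 300


@dataclass
class SsaParams:
    repeat_len: int = 250
    spacer_len: int = 30  # carries the I-SceI recognition site
    arm_len: int = 300


@dataclass
class TdParams:
    # log-normal sizes: median 1 kb, +-3 sigma spanning the 100 bp - 10 kb range
    size_range: tuple[int, int] = (100, 10_000)
    mh_choices: tuple[int, ...] = (0, 1, 2, 3, 4, 5)
    p_ins: float = 0.2
    ins_len: tuple[int, int] = (8, 20)
    genome_len: int = 12_000
    support_range: tuple[int, int] = (5, 30)
    flank_window: int = 300


@dataclass
class SangerParams:
    base_q: int = 50
    tail_decay: float = 1.5  # Phred points lost per base outside the plateau
    plateau_len: int = 200  # high-quality stretch centred on the junction
    p_dip: float = 0.0  # chance of a mid-plateau low-quality dip
    dip_len: int = 5


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohorts."""

    seed: int = 0
    locus_len: int = 2000
    gc: float = 0.36
    plant_motif: bool = True
    emh: EmhParams = field(default_factory=EmhParams)
    tmej: TmejParams = field(default_factory=TmejParams)
    ssa: SsaParams = field(default_factory=SsaParams)
    td: TdParams = field(default_factory=TdParams)
    sanger: SangerParams = field(default_factory=SangerParams)


@dataclass
class SimEvent:
    """One simulated repair product with its ground truth."""

    truth_label: str  # tmej_simple | tmej_ins | tmej_patchwork | emmej | ssa | td
    event: Union[RepairEvent, SVRecord]
    product_seq: str
    provenance: dict
    locus: Locus


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(_BASES, size=length, p=p))


def _different_base(base: str, rng: np.random.Generator) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[rng.integers(0, 3)]


def _motif_text(rng: np.random.Generator) -> str:
    """A G4 motif: four G-tracts of 3-4 G's with 1-3 nt non-G loops."""
    parts = []
    for i in range(4):
        parts.append("G" * int(rng.integers(3, 5)))
        if i < 3:
            loop_len = int(rng.integers(1, 4))
            parts.append("".join(rng.choice(np.array(list("ACT")), size=loop_len)))
    return "".join(parts)


def _shared_kmers(a: str, b: str, k: int) -> bool:
    if len(a) < k or len(b) < k:
        return False
    kmers = {a[i : i + k] for i in range(len(a) - k + 1)}
    return any(b[i : i + k] in kmers for i in range(len(b) - k + 1))


def planted_repeat_pair(cfg: SimConfig, motif: Interval) -> RepeatPair:
    """Coordinates of the planted flanking repeat, deterministic from config."""
    e = cfg.emh
    left = Interval(motif.start - e.left_offset - e.repeat_len, motif.start - e.left_offset)
    right = Interval(motif.end + e.right_offset, motif.end + e.right_offset + e.repeat_len)
    return RepeatPair(
        left=left, right=right, length=e.repeat_len, mismatches=e.mismatches,
        side_relation="flanks_motif",
    )


def make_locus(cfg: SimConfig, rng: np.random.Generator, locus_id: str = "synthetic") -> Locus:
    """Random locus at the configured GC, optionally with a planted G4 motif
    and planted flanking repeat pair.

    Rejection sampling guarantees that, beyond any planted pair, the two
    motif flanks (300 bp windows) share no coincidental repeat of
    ``emh.repeat_len`` or longer.
    """
    window = 300
    for _ in range(200):
        seq = list(_random_seq(rng, cfg.locus_len, cfg.gc))
        if not cfg.plant_motif:
            return Locus(id=locus_id, seq="".join(seq))
        motif_text = _motif_text(rng)
        mstart = cfg.locus_len // 2 - len(motif_text) // 2
        motif = Interval(mstart, mstart + len(motif_text))
        seq[motif.start : motif.end] = list(motif_text)
        if cfg.emh.plant:
            pair = planted_repeat_pair(cfg, motif)
            if pair.left.start < 0 or pair.right.end > cfg.locus_len:
                raise ValueError("planted repeat falls outside the locus; enlarge locus_len")
            repeat = _random_seq(rng, cfg.emh.repeat_len, cfg.gc)
            other = list(repeat)
            if cfg.emh.mismatches:
                pos = rng.choice(cfg.emh.repeat_len, size=cfg.emh.mismatches, replace=False)
                for p in pos:
                    other[p] = _different_base(other[p], rng)
            seq[pair.left.start : pair.left.end] = list(repeat)
            seq[pair.right.start : pair.right.end] = other
            # force mismatches just outside both copies so the planted pair
            # has exact boundaries (no coincidental single-base extension)
            if (
                pair.right.start - 1 >= motif.end
                and seq[pair.right.start - 1] == seq[pair.left.start - 1]
            ):
                seq[pair.right.start - 1] = _different_base(seq[pair.left.start - 1], rng)
            if (
                pair.right.end < cfg.locus_len
                and seq[pair.right.end] == seq[pair.left.end]
            ):
                seq[pair.right.end] = _different_base(seq[pair.left.end], rng)
        s = "".join(seq)
        left_win = s[max(0, motif.start - window) : motif.start]
        right_win = s[motif.end : motif.end + window]
        if cfg.emh.plant:
            # mask the planted copies before checking for coincidental repeats
            pair = planted_repeat_pair(cfg, motif)
            lw_off = max(0, motif.start - window)
            # distinct sentinels so the masked copies cannot match each other
            lw = list(left_win)
            lw[pair.left.start - lw_off : pair.left.end - lw_off] = ["l"] * pair.length
            rw = list(right_win)
            rw[pair.right.start - motif.end : pair.right.end - motif.end] = ["r"] * pair.length
            left_chk, right_chk = "".join(lw), "".join(rw)
        else:
            left_chk, right_chk = left_win, right_win
        if _shared_kmers(left_chk, right_chk, cfg.emh.repeat_len):
            continue  # coincidental flank repeat: redraw
        hits = find_g4_motifs(s)
        if not any(h.interval.start == motif.start for h in hits):
            continue  # planted motif got absorbed or broken: redraw
        return Locus(id=locus_id, seq=s, motif=motif, break_site=motif.start)
    raise RuntimeError("could not build a collision-free locus in 200 attempts")


def _engineer_junction(
    seq: list[str], s: int, e: int, m: int, rng: np.random.Generator
) -> None:
    """Edit ``seq`` in place so the junction (s, e) carries exactly MH = m.

    Copies m bases entering the deletion to the right of the junction and
    forces mismatches at both ends of the run, so the placement-enumeration
    oracle returns exactly m.
    """
    if not (1 <= s and e + m < len(seq) and s + m <= e):
        raise ValueError("junction too close to the sequence ends for engineering")
    for i in range(m):
        seq[e + i] = seq[s + i]
    seq[e + m] = _different_base(seq[s + m], rng)
    seq[e - 1] = _different_base(seq[s - 1], rng)


def _draw_flank_insert(
    seq: str, s: int, e: int, length: int, window: int,
    p_revcomp: float, rng: np.random.Generator,
) -> tuple[str, dict]:
    """An insertion copied verbatim (or reverse-complemented) from a flank window."""
    from dsbfoot.junction_classifier import revcomp

    side = "left" if rng.random() < 0.5 else "right"
    if side == "left":
        lo, hi = max(0, s - window), s - length
    else:
        lo, hi = e, min(len(seq), e + window) - length
    if hi <= lo:
        raise ValueError("flank window too small for the requested insert")
    o = int(rng.integers(lo, hi))
    piece = seq[o : o + length]
    strand = "-" if rng.random() < p_revcomp else "+"
    if strand == "-":
        piece = revcomp(piece)
    return piece, {"origin_start": o, "origin_len": length, "flank": side, "strand": strand}


def _insert_is_observable(
    ins: str, seams: list[int], ref: str, s: int, e: int, window: int, seg_min: int
) -> bool:
    """True when the insert's footprint matches its construction label.

    Two constraints keep the truth label observable in the product: the last
    insert base must differ from the base left of the junction's right side
    (otherwise left alignment rotates reference bases into the insert), and
    no seam-crossing stretch of ``seg_min`` bases may occur in any flank
    window on either strand (otherwise a patchwork's pieces merge into one
    apparent template).  Checking length ``seg_min`` suffices: any longer
    seam-crossing match contains a seam-crossing ``seg_min``-mer.
    """
    from dsbfoot.junction_classifier import revcomp

    if ins[-1] == ref[e - 1]:
        return False
    windows = [ref[max(0, s - window) : s], ref[e : e + window], ref[s:e]]
    for seam in seams:
        for start in range(max(0, seam - seg_min + 1), min(seam, len(ins) - seg_min) + 1):
            if not (start < seam < start + seg_min):
                continue
            sub = ins[start : start + seg_min]
            rc = revcomp(sub)
            if any(w.find(sub) >= 0 or w.find(rc) >= 0 for w in windows):
                return False
    return True


def simulate_tmej(locus: Locus, cfg: SimConfig, rng: np.random.Generator) -> SimEvent:
    """One TMEJ product on a private edited copy of ``locus``.

    The left junction sits within ``upstream_max`` bp upstream of the motif,
    the right junction 50–300 bp downstream of it; the drawn MH (0–5 bp) is
    engineered exactly.  With probability ``p_ins`` the product carries a
    flank-templated insertion, which with probability ``p_patch`` has a
    patchwork configuration.
    """
    if locus.motif is None:
        raise ValueError("simulate_tmej needs a locus with a motif")
    t = cfg.tmej
    m = int(rng.choice(np.array(t.mh_choices)))
    s = locus.motif.start - int(rng.integers(1, t.upstream_max + 1))
    e = locus.motif.end + int(rng.integers(t.right_junction_offset[0],
                                           t.right_junction_offset[1] + 1))
    seq = list(locus.seq)
    _engineer_junction(seq, s, e, m, rng)
    ref = "".join(seq)

    ins = ""
    label = "tmej_simple"
    prov: dict = {"mh": m, "del_start": s, "del_end": e}
    if rng.random() < t.p_ins:
        # redraw until the footprint is observable as its own label (no
        # canonical rotation, no seam-crossing flank match merging pieces)
        if rng.random() < t.p_patch:
            label = "tmej_patchwork"
            for _ in range(100):
                n_seg = int(rng.integers(t.patch_n_segments[0], t.patch_n_segments[1] + 1))
                pieces, piece_provs = [], []
                for _ in range(n_seg):
                    length = int(rng.integers(t.patch_seg_len[0], t.patch_seg_len[1] + 1))
                    piece, pp = _draw_flank_insert(
                        ref, s, e, length, t.flank_window, t.p_revcomp, rng
                    )
                    pieces.append(piece)
                    piece_provs.append(pp)
                if rng.random() < t.p_patch_reuse:
                    k = int(rng.integers(0, len(pieces)))
                    pieces.append(pieces[k])
                    piece_provs.append({**piece_provs[k], "reused": True})
                seams = list(np.cumsum([len(p) for p in pieces[:-1]]))
                cand = "".join(pieces)
                if _insert_is_observable(
                    cand, seams, ref, s, e, t.flank_window, t.patch_seg_len[0]
                ):
                    ins = cand
                    prov["segments"] = piece_provs
                    break
            else:
                raise RuntimeError("could not draw an observable patchwork insert")
        else:
            label = "tmej_ins"
            for _ in range(100):
                length = int(rng.integers(t.ins_len[0], t.ins_len[1] + 1))
                cand, pp = _draw_flank_insert(
                    ref, s, e, length, t.flank_window, t.p_revcomp, rng
                )
                if _insert_is_observable(cand, [], ref, s, e, t.flank_window, t.ins_len[0]):
                    ins = cand
                    prov["segments"] = [pp]
                    break
            else:
                raise RuntimeError("could not draw an observable templated insert")

    event = RepairEvent(
        locus_id=locus.id, cls=_classify(e - s, len(ins)),
        del_iv=Interval(s, e), ins_seq=ins,
    )
    event = canonicalize(event, ref)
    private = Locus(id=locus.id, seq=ref, motif=locus.motif, break_site=locus.break_site)
    return SimEvent(
        truth_label=label,
        event=event,
        product_seq=reconstruct(ref, event),
        provenance=prov,
        locus=private,
    )


def simulate_emmej(locus: Locus, cfg: SimConfig, rng: np.random.Generator) -> SimEvent:
    """One eMMEJ product: deletion between the planted repeat copies,
    retaining exactly one copy; junction MH equals the planted repeat length
    minus the effect of planted mismatches."""
    if locus.motif is None or not cfg.emh.plant:
        raise ValueError("simulate_emmej needs a locus with a planted flanking repeat")
    pair = planted_repeat_pair(cfg, locus.motif)
    d = pair.right.start - pair.left.start
    j = int(rng.integers(0, pair.length + 1))  # homologous cut point within the repeat
    s = pair.left.start + j
    event = RepairEvent(
        locus_id=locus.id, cls="deletion", del_iv=Interval(s, s + d), ins_seq="",
    )
    event = canonicalize(event, locus.seq)
    return SimEvent(
        truth_label="emmej",
        event=event,
        product_seq=reconstruct(locus.seq, event),
        provenance={"repeat": dataclasses.asdict(cfg.emh), "cut_offset": j},
        locus=locus,
    )


def simulate_ssa_reporter(
    cfg: SimConfig, rng: np.random.Generator
) -> tuple[Locus, SimEvent]:
    """An SSA reporter construct and its repair product.

    The construct carries two identical ~250 bp repeats around a spacer
    containing the I-SceI recognition site; SSA collapses it to a single
    copy, so the product is shorter by (repeat_len + spacer_len) and the
    junction MH equals the repeat length.
    """
    p = cfg.ssa
    if p.spacer_len < len(I_SCEI_SITE):
        raise ValueError("spacer must be long enough to hold the I-SceI site")
    repeat = _random_seq(rng, p.repeat_len, cfg.gc)
    pad = p.spacer_len - len(I_SCEI_SITE)
    spacer = (
        _random_seq(rng, pad // 2, cfg.gc)
        + I_SCEI_SITE
        + _random_seq(rng, pad - pad // 2, cfg.gc)
    )
    prefix = _random_seq(rng, p.arm_len, cfg.gc)
    suffix = _random_seq(rng, p.arm_len, cfg.gc)
    seq = prefix + repeat + spacer + repeat + suffix
    r1 = len(prefix)
    r2 = r1 + p.repeat_len + p.spacer_len
    break_site = r1 + p.repeat_len + pad // 2 + len(I_SCEI_SITE) // 2
    locus = Locus(
        id="ssa_reporter", seq=seq,
        motif=Interval(r1 + p.repeat_len, r2), break_site=break_site,
    )
    event = RepairEvent(
        locus_id=locus.id, cls="deletion",
        del_iv=Interval(r1, r2), ins_seq="",
    )
    event = canonicalize(event, seq)
    sim = SimEvent(
        truth_label="ssa",
        event=event,
        product_seq=reconstruct(seq, event),
        provenance={"repeat_len": p.repeat_len, "spacer_len": p.spacer_len},
        locus=locus,
    )
    return locus, sim


def simulate_td(cfg: SimConfig, rng: np.random.Generator,
                sample_id: str = "sim", chrom: str = "chrI") -> SimEvent:
    """One tandem duplication on a private random genome segment.

    Size is log-normal with median at the geometric centre of the
    configured range (1 kb for the default 100 bp – 10 kb range, which
    spans ±3σ); the junction between the copies carries
    an engineered MH of 0–5 bp and, with probability ``p_ins``, a templated
    insert copied from the boundary flanks.
    """
    p = cfg.td
    mu = (np.log(p.size_range[0]) + np.log(p.size_range[1])) / 2
    sigma = (np.log(p.size_range[1]) - np.log(p.size_range[0])) / 6
    size = int(round(float(np.exp(rng.normal(mu, sigma)))))
    size = max(p.size_range[0], min(p.size_range[1], size))
    margin = p.flank_window + 10
    if p.genome_len < size + 2 * margin:
        raise ValueError("genome_len too small for the drawn TD size")
    genome = list(_random_seq(rng, p.genome_len, cfg.gc))
    start = int(rng.integers(margin, p.genome_len - size - margin))
    end = start + size
    m = int(rng.choice(np.array(p.mh_choices)))
    _engineer_junction(genome, start, end, m, rng)
    gseq = "".join(genome)

    ins = ""
    prov: dict = {"mh": m, "size": size, "start": start, "end": end}
    if rng.random() < p.p_ins:
        length = int(rng.integers(p.ins_len[0], p.ins_len[1] + 1))
        ins, pp = _draw_flank_insert(gseq, start, end, length, p.flank_window, 0.5, rng)
        prov["ins"] = pp
    support = int(rng.integers(p.support_range[0], p.support_range[1] + 1))
    record = SVRecord(
        sample_id=sample_id, chrom=chrom, start=start, end=end,
        svtype=SV_TD, support_reads=support,
        has_forward=True, has_reverse=True,
        junction_ins=ins, caller="simulated",
    )
    rearranged = gseq[:end] + ins + gseq[start:end] + gseq[end:]
    return SimEvent(
        truth_label="td",
        event=record,
        product_seq=rearranged,
        provenance=prov,
        locus=Locus(id=chrom, seq=gseq),
    )


def simulate_sanger_reads(
    product_seq: str,
    cfg: SimConfig,
    rng: np.random.Generator,
    junction: Optional[int] = None,
    n_reads: int = 1,
    read_id_prefix: str = "read",
) -> list[QualifiedRead]:
    """Sanger-style reads of a product: full-length copies with a Phred
    plateau centred on the junction (sequence centre when none is given)
    and linearly decaying quality tails; optional mid-plateau dips create
    QC failures."""
    p = cfg.sanger
    n = len(product_seq)
    centre = junction if junction is not None else n // 2
    a = max(0, centre - p.plateau_len // 2)
    b = min(n, a + p.plateau_len)
    reads = []
    for i in range(n_reads):
        phred = np.full(n, p.base_q, dtype=float)
        idx = np.arange(n)
        phred[idx < a] = p.base_q - p.tail_decay * (a - idx[idx < a])
        phred[idx >= b] = p.base_q - p.tail_decay * (idx[idx >= b] - b + 1)
        phred = np.clip(np.rint(phred), 0, 93).astype(int)
        if p.p_dip > 0 and rng.random() < p.p_dip and b - a > 2 * p.dip_len:
            dip_at = int(rng.integers(a + 1, b - p.dip_len - 1))
            phred[dip_at : dip_at + p.dip_len] = 2
        reads.append(
            QualifiedRead(
                id=f"{read_id_prefix}_{i}", bases=product_seq, phred=list(map(int, phred))
            )
        )
    return reads


def generate_tmej_cohort(
    cfg: SimConfig, n: int, rng: Optional[np.random.Generator] = None
) -> list[SimEvent]:
    """A cohort of n TMEJ products, each on its own edited copy of one base locus."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    base = make_locus(cfg, rng)
    return [simulate_tmej(base, cfg, rng) for _ in range(n)]


def generate_td_cohort(
    cfg: SimConfig, n: int, rng: Optional[np.random.Generator] = None,
    sample_id: str = "sim",
) -> list[SimEvent]:
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    return [simulate_td(cfg, rng, sample_id=sample_id) for _ in range(n)]


def export_truth(dataset: list[SimEvent], seed: Optional[int] = None) -> pd.DataFrame:
    """One row of ground truth per simulated event, sufficient to score
    every classifier decision; round-trips through ``pandas.read_csv``."""
    rows = []
    for ev in dataset:
        if isinstance(ev.event, RepairEvent):
            row = {
                "truth_label": ev.truth_label,
                "locus_id": ev.event.locus_id,
                "cls": ev.event.cls,
                "del_start": ev.event.del_iv.start,
                "del_end": ev.event.del_iv.end,
                "ins_seq": ev.event.ins_seq,
            }
        else:
            row = {
                "truth_label": ev.truth_label,
                "locus_id": ev.event.chrom,
                "cls": "td",
                "del_start": ev.event.start,
                "del_end": ev.event.end,
                "ins_seq": ev.event.junction_ins,
            }
        row["provenance"] = json.dumps(ev.provenance)
        row["seed"] = seed
        rows.append(row)
    return pd.DataFrame(rows)
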