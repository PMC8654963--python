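"""Reference-locus model, G-quadruplex motif scanning and flanking-repeat discovery.

A locus is a reference sequence carrying an optional motif interval (here a
G4 motif: stacked runs of guanines able to fold into a replication-blocking
quadruplex) and an optional expected break site.  Breaks induced at such
motifs are repaired by end joining between the two flanks, so the amount of
*extended microhomology* (eMH) — direct repeats of ~20–30 bp sitting on
either side of the motif — determines whether polymerase-theta-independent
annealing (eMMEJ) can act.  This module finds the motifs and the repeats.

All coordinates are 0-based, half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGTN")

# default G4 rule: >=4 tracts of >=3 G's separated by 1..7 nt loops
DEFAULT_MIN_TRACT = 3
DEFAULT_MAX_LOOP = 7
DEFAULT_N_TRACTS = 4


@dataclass(frozen=True, order=True)
class Interval:
    """Half-open interval ``[start, end)`` on a named sequence."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"interval start must be >= 0, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"interval end {self.end} < start {self.start}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class Locus:
    """A reference sequence with optional motif interval and break site."""

    id: str
    seq: str
    motif: Optional[Interval] = None
    break_site: Optional[int] = None

    def __post_init__(self) -> None:
        _check_alphabet(self.seq)
        n = len(self.seq)
        if self.motif is not None and self.motif.end > n:
            raise ValueError(
                f"motif {self.motif} outside sequence of length {n} for locus {self.id}"
            )
        if self.break_site is not None and not (0 <= self.break_site <= n):
            raise ValueError(
                f"break_site {self.break_site} outside [0, {n}] for locus {self.id}"
            )


@dataclass(frozen=True)
class MotifHit:
    """One maximal G4 motif match; ``n_tracts`` counts the maximal G (or C) runs
    of tract length inside the interval."""

    interval: Interval
    strand: str  # "+" or "-"
    n_tracts: int
    pattern_text: str


@dataclass(frozen=True)
class RepeatPair:
    """Two same-strand copies of a repeated sequence (direct repeat).

    ``mismatches`` is the Hamming distance between the two copies;
    ``side_relation`` marks pairs that straddle a motif.
    """

    left: Interval
    right: Interval
    length: int
    mismatches: int
    side_relation: str = "generic"  # "flanks_motif" or "generic"

    def __post_init__(self) -> None:
        if self.left.end > self.right.start:
            raise ValueError("left copy must precede right copy")
        if len(self.left) != self.length or len(self.right) != self.length:
            raise ValueError("copy intervals must both have the stated length")


def _check_alphabet(seq: str) -> None:
    bad = set(seq) - _VALID_BASES
    if bad:
        raise ValueError(f"sequence contains non-ACGTN characters: {sorted(bad)}")


def _run_lengths(seq: str, base: str) -> list[int]:
    """run[i] = length of the maximal run of `base` starting at i (0 if seq[i] != base)."""
    n = len(seq)
    run = [0] * n
    for i in range(n - 1, -1, -1):
        if seq[i] == base:
            run[i] = run[i + 1] + 1 if i + 1 < n else 1
    return run


def _max_match_ends(
    seq: str, base: str, min_tract: int, max_loop: int, n_tracts: int
) -> dict[int, int]:
    """For every position where a tract can start, the furthest end of a motif
    match starting there, or nothing if no full match starts there.

    A match is >= ``n_tracts`` runs of >= ``min_tract`` copies of ``base``
    separated by loops of 1..``max_loop`` arbitrary nucleotides; a long base
    run may be carved into several tracts with base-only loops in between.
    Computed right-to-left so later decisions are already known.
    """
    n = len(seq)
    run = _run_lengths(seq, base)
    starts = [i for i in range(n) if run[i] >= min_tract]
    # F[t][q] = furthest end of a block of >= t tracts whose first tract starts at q
    NEG = -1
    F: list[dict[int, int]] = [dict() for _ in range(n_tracts + 1)]
    for q in reversed(starts):
        tract_end_max = q + run[q]
        # candidate starts of the next tract
        nexts = []
        for r in range(q + min_tract + 1, min(tract_end_max + max_loop, n - min_tract) + 1):
            if run[r] < min_tract:
                continue
            c_max = min(run[q], r - q - 1)
            c_min = max(min_tract, r - q - max_loop)
            if c_min <= c_max:
                nexts.append(r)
        for t in range(1, n_tracts + 1):
            t_next = max(t - 1, 1)
            best = tract_end_max if t <= 1 else NEG
            for r in nexts:
                sub = F[t_next].get(r, NEG)
                if sub > best:
                    best = sub
            if best != NEG:
                F[t][q] = best
    return F[n_tracts]


def _count_tracts(seq: str, iv: Interval, base: str, min_tract: int) -> int:
    sub = seq[iv.start : iv.end]
    count, i = 0, 0
    while i < len(sub):
        if sub[i] == base:
            j = i
            while j < len(sub) and sub[j] == base:
                j += 1
            if j - i >= min_tract:
                count += 1
            i = j
        else:
            i += 1
    return count


def find_g4_motifs(
    seq: str,
    min_tract: int = DEFAULT_MIN_TRACT,
    max_loop: int = DEFAULT_MAX_LOOP,
    n_tracts: int = DEFAULT_N_TRACTS,
    both_strands: bool = False,
) -> list[MotifHit]:
    """Scan ``seq`` for G4 motifs: >= ``n_tracts`` runs of >= ``min_tract``
    guanines separated by loops of 1..``max_loop`` nt.

    Matches are selected greedily left to right, each maximal (longest end
    for its start, not extendable leftward) and non-overlapping.  With
    ``both_strands`` the complementary C-tract rule is scanned too and those
    hits carry strand "-"; each strand is selected independently.

    Raises ``ValueError`` on non-ACGTN input or invalid rule parameters.
    """
    _check_alphabet(seq)
    if min_tract < 2 or n_tracts < 2 or max_loop < 1:
        raise ValueError("require min_tract >= 2, n_tracts >= 2, max_loop >= 1")

    hits: list[MotifHit] = []
    strands = [("G", "+")] + ([("C", "-")] if both_strands else [])
    for base, strand in strands:
        ends = _max_match_ends(seq, base, min_tract, max_loop, n_tracts)
        pos = 0
        n = len(seq)
        while pos < n:
            if pos in ends:
                iv = Interval(pos, ends[pos])
                hits.append(
                    MotifHit(
                        interval=iv,
                        strand=strand,
                        n_tracts=_count_tracts(seq, iv, base, min_tract),
                        pattern_text=seq[iv.start : iv.end],
                    )
                )
                pos = iv.end
            else:
                pos += 1
    hits.sort(key=lambda h: (h.interval.start, h.strand))
    return hits


def _maximal_banded_runs(match: list[bool], max_mismatch: int) -> list[tuple[int, int]]:
    """Maximal windows of a boolean match vector containing <= max_mismatch
    False entries, trimmed so both endpoints are matches.

    With mismatch positions P, the maximal windows are exactly the spans from
    just after P[i-1] to just before P[i+k] (sentinels -1 and n), one per i.
    """
    n = len(match)
    k = max_mismatch
    P = [i for i, m in enumerate(match) if not m]
    raw: list[tuple[int, int]] = []
    if len(P) <= k:
        raw.append((0, n))
    else:
        for i in range(len(P) - k + 1):
            a = P[i - 1] + 1 if i > 0 else 0
            b = P[i + k] if i + k < len(P) else n
            raw.append((a, b))
    out = set()
    for a, b in raw:
        while a < b and not match[a]:
            a += 1
        while b > a and not match[b - 1]:
            b -= 1
        if b > a:
            out.add((a, b))
    return sorted(out)


def find_flanking_repeats(
    locus: Locus,
    window: int = 300,
    min_len: int = 10,
    max_mismatch: int = 0,
) -> list[RepeatPair]:
    """Find direct repeats with one copy upstream and one downstream of the
    locus motif — the extended microhomology (eMH) that can drive eMMEJ.

    One copy must lie entirely within ``[motif.start - window, motif.start)``
    and the other within ``[motif.end, motif.end + window)``; copies are
    compared position-wise (Hamming distance <= ``max_mismatch``).  Each
    reported pair is maximal (not extendable in either direction within the
    windows) and pairs contained in a longer reported pair are suppressed.
    Sorted by descending length, ties by leftmost left copy.
    """
    if locus.motif is None:
        raise ValueError(f"locus {locus.id} has no motif; flanking-repeat search needs one")
    if not (window >= min_len >= 4):
        raise ValueError("require window >= min_len >= 4")
    seq = locus.seq
    n = len(seq)
    ls = locus.motif.start - window
    if ls < 0:
        logger.warning("left window clipped to sequence start for locus %s", locus.id)
        ls = 0
    le = locus.motif.start
    rs = locus.motif.end
    re_ = locus.motif.end + window
    if re_ > n:
        logger.warning("right window clipped to sequence end for locus %s", locus.id)
        re_ = n

    left_seq = seq[ls:le]
    right_seq = seq[rs:re_]
    la, lb = len(left_seq), len(right_seq)
    candidates: list[RepeatPair] = []
    if la >= min_len and lb >= min_len:
        # walk every diagonal of the left-window x right-window comparison
        for d in range(-(la - 1), lb):
            a0 = max(0, -d)
            b0 = a0 + d
            m = min(la - a0, lb - b0)
            if m < min_len:
                continue
            match = [left_seq[a0 + i] == right_seq[b0 + i] for i in range(m)]
            for (ta, tb) in _maximal_banded_runs(match, max_mismatch):
                length = tb - ta
                if length < min_len:
                    continue
                li = Interval(ls + a0 + ta, ls + a0 + tb)
                ri = Interval(rs + b0 + ta, rs + b0 + tb)
                mism = sum(
                    1
                    for i in range(length)
                    if seq[li.start + i] != seq[ri.start + i]
                )
                candidates.append(
                    RepeatPair(
                        left=li,
                        right=ri,
                        length=length,
                        mismatches=mism,
                        side_relation="flanks_motif",
                    )
                )

    candidates.sort(key=lambda p: (-p.length, p.left.start, p.right.start))
    kept: list[RepeatPair] = []
    for p in candidates:
        contained = any(
            q.right.start - q.left.start == p.right.start - p.left.start
            and q.left.start <= p.left.start
            and p.left.end <= q.left.end
            for q in kept
        )
        if not contained:
            kept.append(p)
    return kept


def homology_score(pairs: list[RepeatPair]) -> int:
    """Length of the longest flanking repeat, 0 when there is none.

    Summarises a locus's degree of flanking homology as a single number for
    ranking loci by their eMMEJ potential.
    """
    return max((p.length for p in pairs), default=0)
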