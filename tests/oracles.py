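"""Independent brute-force oracles used to check the implementation.

Every oracle here recomputes a quantity from its definition (exhaustive
enumeration, regex full-match, all-pairs scans) without sharing code with
the implementation under test.
"""

from __future__ import annotations

import re

from dsbfoot.locus_model import Interval, Locus


def g4_rule_regex(min_tract: int, max_loop: int, n_tracts: int, base: str = "G"):
    return re.compile(
        f"{base}{{{min_tract},}}"
        f"(?:[ACGTN]{{1,{max_loop}}}{base}{{{min_tract},}}){{{n_tracts - 1},}}"
    )


def g4_exhaustive(
    seq: str, min_tract: int = 3, max_loop: int = 7, n_tracts: int = 4, base: str = "G"
) -> list[tuple[int, int]]:
    """All-substrings oracle: test every substring against the anchored motif
    rule, then select greedily leftmost-longest non-overlapping."""
    rule = g4_rule_regex(min_tract, max_loop, n_tracts, base)
    matches = [
        (i, j)
        for i in range(len(seq))
        for j in range(i + 1, len(seq) + 1)
        if rule.fullmatch(seq[i:j])
    ]
    selected = []
    while matches:
        i = min(m[0] for m in matches)
        j = max(m[1] for m in matches if m[0] == i)
        selected.append((i, j))
        matches = [m for m in matches if m[0] >= j]
    return selected


def flank_repeats_oracle(
    locus: Locus, window: int, min_len: int, max_mismatch: int
) -> list[tuple[int, int, int, int]]:
    """All-pairs oracle for flanking repeats.

    Enumerates every (left start, right start, length) with the left copy in
    the upstream window and the right copy in the downstream window, Hamming
    distance <= max_mismatch and matching endpoints, then suppresses pairs
    contained (same alignment offset) in a longer qualifying pair.  Returns
    (left_start, left_end, right_start, right_end) tuples sorted like the
    implementation.
    """
    seq = locus.seq
    ls = max(0, locus.motif.start - window)
    le = locus.motif.start
    rs = locus.motif.end
    re_ = min(len(seq), locus.motif.end + window)
    cands = []
    for i in range(ls, le):
        for j in range(rs, re_):
            max_l = min(le - i, re_ - j)
            mism = 0
            for L in range(1, max_l + 1):
                if seq[i + L - 1] != seq[j + L - 1]:
                    mism += 1
                if (
                    L >= min_len
                    and mism <= max_mismatch
                    and seq[i] == seq[j]
                    and seq[i + L - 1] == seq[j + L - 1]
                ):
                    cands.append((i, i + L, j, j + L))
    cand_set = set(cands)
    kept = []
    for (a, b, c, d) in cands:
        contained = any(
            (a2, b2, c2, d2) != (a, b, c, d)
            and c2 - a2 == c - a
            and a2 <= a
            and b <= b2
            for (a2, b2, c2, d2) in cand_set
        )
        if not contained:
            kept.append((a, b, c, d))
    kept = sorted(set(kept), key=lambda t: (-(t[1] - t[0]), t[0], t[2]))
    return kept


def hq_window_bruteforce(phred: list[int], min_len: int, max_p: float):
    """Longest (leftmost on ties) contiguous window where every base has
    error probability < max_p, if it reaches min_len; else None."""
    n = len(phred)
    best = None
    for i in range(n):
        for j in range(i + 1, n + 1):
            if all(10 ** (-q / 10) < max_p for q in phred[i:j]):
                if best is None or j - i > best[1] - best[0]:
                    best = (i, j)
    if best is not None and best[1] - best[0] >= min_len:
        return Interval(best[0], best[1])
    return None


def deletion_placements(ref: str, del_len: int, ins_len: int, product: str) -> int:
    """Number of (deletion start, insertion) pairs of the given lengths whose
    reconstruction equals ``product``."""
    count = 0
    for s in range(len(ref) - del_len + 1):
        if ref[:s] + product[s : s + ins_len] + ref[s + del_len :] == product:
            count += 1
    return count


def td_placements(genome: str, size: int, rearranged: str) -> int:
    """Number of (start, end) placements of a tandem duplication of the given
    size whose rearranged sequence equals ``rearranged``."""
    count = 0
    for start in range(len(genome) - size + 1):
        end = start + size
        if genome[:end] + genome[start:end] + genome[end:] == rearranged:
            count += 1
    return count


def chi2_2x2_hand(a: int, b: int, c: int, d: int) -> float:
    """Pearson chi-square via the closed 2x2 formula N(ad-bc)^2 / product of
    marginals."""
    n = a + b + c + d
    return (
        n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    )
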