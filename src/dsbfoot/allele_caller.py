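"""Allele calling: compare a quality-masked read to its reference locus.

A Sanger read of a repair product is assumed to cover the whole amplicon and
to be registered to the reference at both ends (same primers).  The caller
anchors the read to the reference by its longest exact common prefix and
suffix (masked N bases never match and so cannot anchor), takes the
unexplained middles as the deleted reference interval and the inserted read
sequence, and classifies the product as wild type, insertion, deletion or
delins (deletion with insertion).

Junction microhomology makes breakpoint placement ambiguous: several
(deletion, insertion) pairs can reconstruct the same product.  Events are
therefore canonicalized to the leftmost placement (VCF-style left
alignment), so two events are identical iff their reconstructions are
identical strings.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

from dsbfoot.locus_model import Interval, Locus

DEFAULT_ANCHOR_MIN = 15

CLS_WILD_TYPE = "wild_type"
CLS_INSERTION = "insertion"
CLS_DELETION = "deletion"
CLS_DELINS = "delins"


class UnalignableReadError(ValueError):
    """Raised when a read cannot be anchored to its reference."""


@dataclass(frozen=True)
class RepairEvent:
    """Canonical description of one repair product.

    ``del_iv`` is the deleted reference interval (empty allowed) and
    ``ins_seq`` the sequence inserted at the junction (empty allowed); the
    class is fully determined by which of the two is non-empty.
    """

    locus_id: str
    cls: str
    del_iv: Interval
    ins_seq: str
    canonical: bool = False

    def __post_init__(self) -> None:
        expected = _classify(len(self.del_iv), len(self.ins_seq))
        if self.cls != expected:
            raise ValueError(
                f"class {self.cls!r} inconsistent with del length {len(self.del_iv)} "
                f"and insertion length {len(self.ins_seq)} (expect {expected!r})"
            )


@dataclass(frozen=True)
class AnchorAlignment:
    """Read-vs-reference anchoring: matched prefix/suffix and the middles.

    ``read_mid``/``ref_mid`` are the unexplained middle intervals in read and
    reference coordinates.  ``offset`` is the first unmasked read position
    (masked tails are assumed to consume reference positions one for one,
    which holds whenever the junction lies in the unmasked core — events
    violating that are rejected by the anchors or by the QC gate).
    """

    prefix_len: int
    suffix_len: int
    read_mid: Interval
    ref_mid: Interval
    offset: int = 0


def _classify(del_len: int, ins_len: int) -> str:
    if del_len == 0 and ins_len == 0:
        return CLS_WILD_TYPE
    if del_len == 0:
        return CLS_INSERTION
    if ins_len == 0:
        return CLS_DELETION
    return CLS_DELINS


def _match(a: str, b: str) -> bool:
    # N is a masked base: it anchors to nothing
    return a == b and a != "N" and b != "N"


def anchor_align(read: str, ref: str, anchor_min: int = DEFAULT_ANCHOR_MIN) -> AnchorAlignment:
    """Anchor ``read`` against ``ref`` by exact common prefix and suffix.

    Leading/trailing masked (N) stretches are skipped; anchors are measured
    over unmasked bases only.  The prefix anchor runs forward from the first
    unmasked position, the suffix anchor backward from the last; if the two
    would overlap, the suffix is trimmed until both middles are non-negative.
    Both anchors must reach ``anchor_min`` unmasked matching bases, otherwise
    the read cannot be assigned to this locus and
    :class:`UnalignableReadError` is raised.
    """
    if not read or not ref:
        raise UnalignableReadError("empty read or reference")
    t0 = 0
    while t0 < len(read) and read[t0] == "N":
        t0 += 1
    t1 = len(read)
    while t1 > t0 and read[t1 - 1] == "N":
        t1 -= 1
    if t1 - t0 == 0:
        raise UnalignableReadError("read is fully masked")

    # prefix: read position t0 is assumed to sit over reference position t0
    prefix = 0
    while (
        t0 + prefix < t1
        and t0 + prefix < len(ref)
        and _match(read[t0 + prefix], ref[t0 + prefix])
    ):
        prefix += 1

    # suffix: right ends of read and reference are registered; measured on the
    # whole unmasked core (it may overlap the prefix and is trimmed below)
    tail_mask = len(read) - t1
    suffix_raw = 0
    while (
        suffix_raw < t1 - t0
        and suffix_raw + tail_mask < len(ref)
        and _match(read[t1 - 1 - suffix_raw], ref[len(ref) - 1 - tail_mask - suffix_raw])
    ):
        suffix_raw += 1

    if prefix < anchor_min or suffix_raw < anchor_min:
        raise UnalignableReadError(
            f"anchors too short (prefix {prefix}, suffix {suffix_raw}, need {anchor_min})"
        )

    # trim the suffix until both middles are non-negative
    suffix = suffix_raw
    read_mid_start = t0 + prefix
    ref_mid_start = t0 + prefix
    read_mid_end = t1 - suffix
    ref_mid_end = len(ref) - tail_mask - suffix
    while suffix > 0 and (ref_mid_end < ref_mid_start or read_mid_end < read_mid_start):
        suffix -= 1
        read_mid_end += 1
        ref_mid_end += 1
    return AnchorAlignment(
        prefix_len=prefix,
        suffix_len=suffix,
        read_mid=Interval(read_mid_start, read_mid_end),
        ref_mid=Interval(ref_mid_start, ref_mid_end),
        offset=t0,
    )


def call_event(
    read: str,
    ref: str,
    locus: Locus,
    anchor_min: int = DEFAULT_ANCHOR_MIN,
) -> RepairEvent:
    """Call and canonicalize the repair event carried by ``read``.

    The deleted interval is the unexplained reference middle and the inserted
    sequence the unexplained read middle.  Unalignable reads propagate
    :class:`UnalignableReadError`.
    """
    aln = anchor_align(read, ref, anchor_min=anchor_min)
    ins = read[aln.read_mid.start : aln.read_mid.end]
    event = RepairEvent(
        locus_id=locus.id,
        cls=_classify(len(aln.ref_mid), len(ins)),
        del_iv=aln.ref_mid,
        ins_seq=ins,
        canonical=False,
    )
    return canonicalize(event, ref)


def canonicalize(event: RepairEvent, ref: str) -> RepairEvent:
    """Shift an event to the leftmost placement reconstructing the same product.

    Among all (deletion, insertion) pairs of equal lengths that yield an
    identical product string, the one with minimal deletion start (for pure
    insertions, minimal insertion point) is canonical.  A junction can be
    shifted one base left whenever the base entering the insertion from the
    left equals the base leaving it on the right (classic VCF left
    alignment); idempotent.
    """
    s, e = event.del_iv.start, event.del_iv.end
    ins = event.ins_seq
    if event.cls == CLS_WILD_TYPE:
        return replace(event, canonical=True)
    while s > 0:
        if ins:
            if ins[-1] != ref[e - 1]:
                break
            ins = ref[s - 1] + ins[:-1]
        else:
            if ref[s - 1] != ref[e - 1]:
                break
        s -= 1
        e -= 1
    return replace(event, del_iv=Interval(s, e), ins_seq=ins, canonical=True)


def reconstruct(ref: str, event: RepairEvent) -> str:
    """Product sequence implied by an event: reference with the deletion
    excised and the insertion placed at the junction."""
    s, e = event.del_iv.start, event.del_iv.end
    if e > len(ref):
        raise ValueError(f"deletion {event.del_iv} outside reference of length {len(ref)}")
    return ref[:s] + event.ins_seq + ref[e:]


def junction_read_position(aln: AnchorAlignment) -> int:
    """Read coordinate of the junction, for the post-calling QC gate."""
    return aln.read_mid.start
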