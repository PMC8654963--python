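"""Phred-quality filtering and masking of Sanger-style reads.

A read is usable only where its base calls are trustworthy.  The filter
keeps the longest contiguous stretch in which every base has an error
probability below a cutoff (default < 0.05, i.e. Phred >= 14), requires that
stretch to reach a minimum length (default 40 nt), and masks everything
outside it with N.  After allele calling, a second gate discards events
whose junction does not fall strictly inside the high-quality window, so
that every reported footprint is supported by trustworthy bases around the
break site.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from dsbfoot.locus_model import Interval

DEFAULT_MIN_LEN = 40
DEFAULT_MAX_P = 0.05

MAX_PHRED = 93  # Sanger FASTQ encoding ceiling ('~' - '!')


@dataclass
class QualifiedRead:
    """A read with one Phred score per base."""

    id: str
    bases: str
    phred: list[int]

    def __post_init__(self) -> None:
        if len(self.phred) != len(self.bases):
            raise ValueError(
                f"read {self.id}: {len(self.phred)} quality values for "
                f"{len(self.bases)} bases"
            )
        for q in self.phred:
            if not (0 <= q <= MAX_PHRED):
                raise ValueError(f"read {self.id}: Phred score {q} outside [0, {MAX_PHRED}]")


@dataclass
class MaskedRead:
    """A read after quality masking: N outside the high-quality window."""

    id: str
    bases: str
    hq_window: Interval
    passed: bool


def error_prob(q: int) -> float:
    """Error probability of a Phred score: 10^(-q/10)."""
    if q < 0:
        raise ValueError(f"Phred score must be >= 0, got {q}")
    return 10.0 ** (-q / 10.0)


def find_hq_window(
    read: QualifiedRead,
    min_len: int = DEFAULT_MIN_LEN,
    max_p: float = DEFAULT_MAX_P,
) -> Optional[Interval]:
    """Longest contiguous run of bases each with error probability < ``max_p``.

    Returns the run as a read-coordinate interval provided it reaches
    ``min_len``; ties broken by leftmost; ``None`` if no run qualifies.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    best: Optional[Interval] = None
    start = None
    for i, q in enumerate(read.phred):
        good = error_prob(q) < max_p
        if good and start is None:
            start = i
        if (not good or i == len(read.phred) - 1) and start is not None:
            end = i + 1 if good else i
            if best is None or end - start > len(best):
                best = Interval(start, end)
            start = None
    if best is not None and len(best) >= min_len:
        return best
    return None


def mask_read(read: QualifiedRead, window: Interval) -> MaskedRead:
    """Replace every base outside ``window`` with N; idempotent."""
    if window.end > len(read.bases):
        raise ValueError(
            f"window {window} outside read {read.id} of length {len(read.bases)}"
        )
    masked = (
        "N" * window.start
        + read.bases[window.start : window.end]
        + "N" * (len(read.bases) - window.end)
    )
    return MaskedRead(id=read.id, bases=masked, hq_window=window, passed=True)


def qc_gate(annotation_window: Optional[Interval], junction_read_pos: int) -> bool:
    """True iff the called junction lies strictly inside the high-quality window.

    Events failing this gate are excluded from spectra: a junction outside
    the trustworthy stretch cannot be placed with confidence.
    """
    if annotation_window is None:
        return False
    return annotation_window.start < junction_read_pos < annotation_window.end


def qc_read(
    read: QualifiedRead,
    min_len: int = DEFAULT_MIN_LEN,
    max_p: float = DEFAULT_MAX_P,
) -> MaskedRead:
    """Run the window search and masking in one step.

    Reads without a qualifying window come back fully masked with
    ``passed=False`` and an empty window.
    """
    window = find_hq_window(read, min_len=min_len, max_p=max_p)
    if window is None:
        return MaskedRead(
            id=read.id,
            bases="N" * len(read.bases),
            hq_window=Interval(0, 0),
            passed=False,
        )
    return mask_read(read, window)
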