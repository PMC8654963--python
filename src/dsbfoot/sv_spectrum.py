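"""Structural-variant record filtering and tandem-duplication junction analysis.

Whole-genome SV calls (from callers such as Pindel, Manta or GRIDSS) are
filtered record-wise: a variant is considered true only when supported by a
minimum number of reads (default 5) covering the junction in both the
forward and reverse orientation, and only when uniquely present in one
sample of a cohort — shared calls are treated as inherited or systematic
and removed symmetrically.

Tandem duplications (TDs) that pass the filters are annotated at the
junction between the two copies.  A TD junction has the same placement
ambiguity as a deletion junction: shifting both duplication boundaries in
step yields an identical rearranged sequence whenever the boundary contexts
share bases, so the deletion MH formula applies directly and measures the
TMEJ hallmark (microhomology overrepresentation, occasional templated
junction insertions) expected when TDs arise from end joining of abortive
strand-annealing intermediates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from dsbfoot.junction_classifier import (
    InsertionAnnotation,
    MicrohomologyCall,
    junction_mh,
    map_insertion,
)
from dsbfoot.locus_model import Interval

logger = logging.getLogger(__name__)

DEFAULT_MIN_SUPPORT = 5
DEFAULT_TOLERANCE = 10

SV_DEL = "DEL"
SV_TD = "TD"
SV_INS = "INS"
SV_OTHER = "OTHER"


@dataclass(frozen=True)
class SVRecord:
    """One called structural variant (0-based half-open span)."""

    sample_id: str
    chrom: str
    start: int
    end: int
    svtype: str
    support_reads: int
    has_forward: bool
    has_reverse: bool
    junction_ins: str = ""
    caller: str = ""

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"SV end {self.end} < start {self.start}")
        if self.support_reads < 0:
            raise ValueError("support_reads must be >= 0")

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TDJunction:
    """Junction-level annotation of a tandem duplication."""

    record: SVRecord
    size: int
    mh: MicrohomologyCall
    insertion: Optional[InsertionAnnotation]


def filter_svs(
    records: Iterable[SVRecord],
    min_support: int = DEFAULT_MIN_SUPPORT,
    require_both_orientations: bool = True,
) -> list[SVRecord]:
    """Keep records with read support >= ``min_support`` and, when required,
    both forward and reverse supporting reads.  Order preserved; discards
    logged with their reason.  Idempotent."""
    kept: list[SVRecord] = []
    for r in records:
        if r.support_reads < min_support:
            logger.info(
                "discard %s %s:%d-%d: support %d < %d",
                r.sample_id, r.chrom, r.start, r.end, r.support_reads, min_support,
            )
            continue
        if require_both_orientations and not (r.has_forward and r.has_reverse):
            logger.info(
                "discard %s %s:%d-%d: missing %s orientation",
                r.sample_id, r.chrom, r.start, r.end,
                "forward" if not r.has_forward else "reverse",
            )
            continue
        kept.append(r)
    return kept


def unique_to_sample(
    records: Iterable[SVRecord], tolerance: int = DEFAULT_TOLERANCE
) -> list[SVRecord]:
    """Keep only events uniquely present in one sample of the cohort.

    A record is removed when any *other* sample carries a record of the same
    type on the same chromosome with both breakpoints within ``tolerance``
    bp; removal is symmetric (all members of a shared event go).  With a
    single sample the input is returned unchanged with a warning.
    """
    records = list(records)
    samples = {r.sample_id for r in records}
    if len(samples) < 2:
        logger.warning("unique_to_sample: single sample, nothing to compare against")
        return records
    kept = []
    for r in records:
        shared = any(
            o.sample_id != r.sample_id
            and o.svtype == r.svtype
            and o.chrom == r.chrom
            and abs(o.start - r.start) <= tolerance
            and abs(o.end - r.end) <= tolerance
            for o in records
        )
        if shared:
            logger.info(
                "discard %s %s:%d-%d %s: shared with another sample",
                r.sample_id, r.chrom, r.start, r.end, r.svtype,
            )
        else:
            kept.append(r)
    return kept


def td_junction_analysis(
    record: SVRecord,
    genome_seq: str,
    window: int = 300,
    seg_min: int = 8,
    cov_min: float = 0.8,
    allow_revcomp: bool = True,
) -> TDJunction:
    """Annotate a tandem-duplication junction with MH and insertion origin.

    The duplicated interval's placement ambiguity is counted with the
    deletion-junction formula applied to the duplication boundaries: the MH
    length equals the number of alternative (start, end) placements giving
    an identical rearranged sequence, minus one.  A junction insertion, when
    present, is mapped against the flanks of ``start`` and ``end``.
    """
    if record.svtype != SV_TD:
        raise ValueError(f"td_junction_analysis needs a TD record, got {record.svtype}")
    if record.end > len(genome_seq):
        raise ValueError("TD span outside the supplied genome sequence")
    iv = Interval(record.start, record.end)
    mh = junction_mh(genome_seq, iv)
    if mh.truncated:
        logger.warning(
            "TD %s:%d-%d at contig edge: partial MH", record.chrom, record.start, record.end
        )
    ins_ann = None
    if record.junction_ins:
        ins_ann = map_insertion(
            record.junction_ins,
            genome_seq,
            iv,
            window=window,
            seg_min=seg_min,
            cov_min=cov_min,
            allow_revcomp=allow_revcomp,
        )
    return TDJunction(record=record, size=record.size, mh=mh, insertion=ins_ann)


def _lower_median(values: list[int]) -> float:
    """Median taking the lower of the two middle values for even n."""
    v = sorted(values)
    return float(v[(len(v) - 1) // 2])


def size_spectrum(records: Iterable[SVRecord]) -> dict:
    """Per-type size summary: counts, sizes, median (lower-middle convention)
    and quartiles.  Empty input gives an all-zero summary."""
    records = list(records)
    out: dict = {"n_total": len(records), "per_type": {}}
    by_type: dict[str, list[int]] = {}
    for r in records:
        by_type.setdefault(r.svtype, []).append(r.size)
    for svtype, sizes in sorted(by_type.items()):
        arr = np.array(sorted(sizes))
        out["per_type"][svtype] = {
            "n": len(sizes),
            "sizes": sorted(sizes),
            "median": _lower_median(sizes),
            "q1": float(np.percentile(arr, 25, method="lower")),
            "q3": float(np.percentile(arr, 75, method="lower")),
            "min": int(arr.min()),
            "max": int(arr.max()),
        }
    return out
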