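"""End-to-end convenience wiring: reads -> QC -> allele calls -> annotations.

Mirrors the analysis applied to Sanger reads of repair products: quality
masking first, anchored comparison to the reference next, the junction
quality gate after calling, and MH / insertion-origin annotation last.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from dsbfoot import allele_caller, junction_classifier, sanger_qc
from dsbfoot.allele_caller import RepairEvent, UnalignableReadError
from dsbfoot.junction_classifier import EventAnnotation
from dsbfoot.locus_model import Locus
from dsbfoot.sanger_qc import QualifiedRead


@dataclass
class PipelineResult:
    annotations: list[EventAnnotation]
    discarded: list[tuple[str, str]]  # (read id, reason)


def process_reads(
    reads: list[QualifiedRead],
    locus: Locus,
    min_len: int = sanger_qc.DEFAULT_MIN_LEN,
    max_p: float = sanger_qc.DEFAULT_MAX_P,
    anchor_min: int = allele_caller.DEFAULT_ANCHOR_MIN,
    window: int = junction_classifier.DEFAULT_WINDOW,
    seg_min: int = junction_classifier.DEFAULT_SEG_MIN,
    cov_min: float = junction_classifier.DEFAULT_COV_MIN,
) -> PipelineResult:
    """Run QC, calling, the junction quality gate and annotation on a batch
    of reads from one locus.  Reads failing any stage are collected in
    ``discarded`` with the reason; wild-type calls are annotated but carry
    no spectrum code."""
    annotations: list[EventAnnotation] = []
    discarded: list[tuple[str, str]] = []
    for read in reads:
        masked = sanger_qc.qc_read(read, min_len=min_len, max_p=max_p)
        if not masked.passed:
            discarded.append((read.id, "no_hq_window"))
            continue
        try:
            aln = allele_caller.anchor_align(masked.bases, locus.seq, anchor_min=anchor_min)
        except UnalignableReadError as exc:
            discarded.append((read.id, f"unalignable: {exc}"))
            continue
        ins = masked.bases[aln.read_mid.start : aln.read_mid.end]
        event = RepairEvent(
            locus_id=locus.id,
            cls=allele_caller._classify(len(aln.ref_mid), len(ins)),
            del_iv=aln.ref_mid,
            ins_seq=ins,
        )
        event = allele_caller.canonicalize(event, locus.seq)
        if event.cls != allele_caller.CLS_WILD_TYPE and not sanger_qc.qc_gate(
            masked.hq_window, allele_caller.junction_read_position(aln)
        ):
            discarded.append((read.id, "junction_outside_hq_window"))
            continue
        annotations.append(
            junction_classifier.annotate_event(
                event, locus.seq, window=window, seg_min=seg_min, cov_min=cov_min
            )
        )
    return PipelineResult(annotations=annotations, discarded=discarded)
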