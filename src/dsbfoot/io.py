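"""File-format front ends: FASTA, FASTQ, BED, event/annotation TSV, SV VCF/TSV.

Sequence formats go through Biopython; tabular formats through pandas; VCF
reading through cyvcf2.  All genomic coordinates written by this package
are 0-based, half-open.  In the minimal SV-VCF dialect written here, POS is
the 0-based start of the affected span and INFO/END its 0-based exclusive
end; the reader applies the same convention (spans survive a write/read
round trip unchanged).
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Optional, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from dsbfoot.allele_caller import RepairEvent, _classify
from dsbfoot.junction_classifier import EventAnnotation
from dsbfoot.locus_model import Interval, Locus, MotifHit, RepeatPair
from dsbfoot.sanger_qc import MaskedRead, QualifiedRead
from dsbfoot.sv_spectrum import SVRecord, TDJunction

PathLike = Union[str, Path]

# INFO keys used for read support and junction orientation; remappable for
# caller-specific VCFs
DEFAULT_SV_FIELD_MAP = {
    "support": ("SUPPORT", "SU", "RE"),
    "forward": ("FWD",),
    "reverse": ("REV",),
    "insertion": ("INSSEQ",),
}

_BND_RE = re.compile(r"^[ACGTN]*\]([^:\]]+):(\d+)\][ACGTN]*$")


# ---------------------------------------------------------------- sequences

def read_loci_fasta(
    path: PathLike, motifs: Optional[dict[str, Interval]] = None,
    break_sites: Optional[dict[str, int]] = None,
) -> list[Locus]:
    """Load loci from FASTA, optionally attaching motif intervals and break
    sites keyed by record id (e.g. from a sidecar BED)."""
    motifs = motifs or {}
    break_sites = break_sites or {}
    loci = []
    for rec in SeqIO.parse(str(path), "fasta"):
        loci.append(
            Locus(
                id=rec.id,
                seq=str(rec.seq).upper(),
                motif=motifs.get(rec.id),
                break_site=break_sites.get(rec.id),
            )
        )
    return loci


def write_fasta(seqs: dict[str, str], path: PathLike) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fastq(path: PathLike) -> list[QualifiedRead]:
    """Sanger-encoded (Phred+33) FASTQ to qualified reads."""
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        reads.append(
            QualifiedRead(
                id=rec.id,
                bases=str(rec.seq).upper(),
                phred=list(rec.letter_annotations["phred_quality"]),
            )
        )
    return reads


def write_fastq(reads: list[QualifiedRead], path: PathLike) -> None:
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.bases), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = r.phred
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def write_masked_fastq(reads: list[MaskedRead], path: PathLike, q_masked: int = 0,
                       q_kept: int = 40) -> None:
    """Masked reads as FASTQ: masked bases at Phred ``q_masked``."""
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.bases), id=r.id, description="")
        rec.letter_annotations["phred_quality"] = [
            q_kept if b != "N" else q_masked for b in r.bases
        ]
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


# ---------------------------------------------------------------- BED / TSV

def read_motif_bed(path: PathLike) -> dict[str, Interval]:
    """Sidecar BED (chrom, start, end; 0-based half-open) keyed by sequence id."""
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            out[fields[0]] = Interval(int(fields[1]), int(fields[2]))
    return out


def write_motif_bed(hits: dict[str, list[MotifHit]], path: PathLike) -> None:
    with open(path, "w") as fh:
        for seq_id, seq_hits in hits.items():
            for h in seq_hits:
                fh.write(
                    f"{seq_id}\t{h.interval.start}\t{h.interval.end}\t"
                    f"g4_{h.n_tracts}tracts\t0\t{h.strand}\n"
                )


def write_repeats_tsv(pairs: dict[str, list[RepeatPair]], path: PathLike) -> None:
    rows = [
        {
            "locus_id": locus_id,
            "left_start": p.left.start,
            "left_end": p.left.end,
            "right_start": p.right.start,
            "right_end": p.right.end,
            "length": p.length,
            "mismatches": p.mismatches,
        }
        for locus_id, ps in pairs.items()
        for p in ps
    ]
    pd.DataFrame(
        rows,
        columns=[
            "locus_id", "left_start", "left_end", "right_start", "right_end",
            "length", "mismatches",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_qc_report(reads: list[MaskedRead], path: PathLike) -> None:
    pd.DataFrame(
        [
            {
                "read_id": r.id,
                "window_start": r.hq_window.start,
                "window_end": r.hq_window.end,
                "passed": r.passed,
            }
            for r in reads
        ]
    ).to_csv(path, sep="\t", index=False)


_EVENT_COLUMNS = ["locus_id", "cls", "del_start", "del_end", "del_len", "ins_seq"]


def write_events_tsv(events: list[RepairEvent], path: PathLike) -> None:
    pd.DataFrame(
        [
            {
                "locus_id": e.locus_id,
                "cls": e.cls,
                "del_start": e.del_iv.start,
                "del_end": e.del_iv.end,
                "del_len": len(e.del_iv),
                "ins_seq": e.ins_seq,
            }
            for e in events
        ],
        columns=_EVENT_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_events_tsv(path: PathLike) -> list[RepairEvent]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype={"ins_seq": str})
    events = []
    for _, row in df.iterrows():
        events.append(
            RepairEvent(
                locus_id=str(row["locus_id"]),
                cls=str(row["cls"]),
                del_iv=Interval(int(row["del_start"]), int(row["del_end"])),
                ins_seq=str(row["ins_seq"]),
            )
        )
    return events


def write_annotations_tsv(annotations: list[EventAnnotation], path: PathLike) -> None:
    """Annotated event table, ordered by deletion end-point (the pile-sort
    used for deletion spectra)."""
    rows = []
    for a in sorted(annotations, key=lambda x: (x.event.del_iv.end, x.event.del_iv.start)):
        e = a.event
        rows.append(
            {
                "locus_id": e.locus_id,
                "cls": e.cls,
                "del_start": e.del_iv.start,
                "del_end": e.del_iv.end,
                "del_len": len(e.del_iv),
                "ins_seq": e.ins_seq,
                "mh_len": a.mh.length if a.mh else 0,
                "mh_class": a.mh.mh_class if a.mh else "",
                "ins_class": a.insertion.ins_class if a.insertion else "",
                "n_segments": len(a.insertion.segments) if a.insertion else 0,
                "repeated_stretch": a.insertion.repeated_stretch if a.insertion else False,
                "spectrum_code": a.spectrum_code or "",
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_summary_json(summary, path: PathLike) -> None:
    import dataclasses

    if dataclasses.is_dataclass(summary):
        summary = dataclasses.asdict(summary)
    with open(path, "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
        fh.write("\n")


# ---------------------------------------------------------------- SV VCF/TSV

def write_sv_vcf(records: list[SVRecord], path: PathLike, contigs: Optional[dict] = None) -> None:
    """Minimal single-sample SV VCF (POS = 0-based start, END = 0-based
    exclusive end; see module docstring)."""
    sample = records[0].sample_id if records else "sample"
    lines = [
        "##fileformat=VCFv4.2",
        f"##sample={sample}",
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="0-based exclusive end">',
        '##INFO=<ID=SUPPORT,Number=1,Type=Integer,Description="Supporting reads">',
        '##INFO=<ID=FWD,Number=1,Type=Integer,Description="Forward-read support present">',
        '##INFO=<ID=REV,Number=1,Type=Integer,Description="Reverse-read support present">',
        '##INFO=<ID=INSSEQ,Number=1,Type=String,Description="Junction insertion">',
        '##INFO=<ID=CALLER,Number=1,Type=String,Description="Originating caller">',
        '##ALT=<ID=DEL,Description="Deletion">',
        '##ALT=<ID=DUP:TANDEM,Description="Tandem duplication">',
        '##ALT=<ID=INS,Description="Insertion">',
    ]
    for name, length in (contigs or {}).items():
        lines.append(f"##contig=<ID={name},length={length}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    alt_by_type = {"DEL": "<DEL>", "TD": "<DUP:TANDEM>", "INS": "<INS>", "OTHER": "<SV>"}
    for i, r in enumerate(records):
        vcf_type = {"TD": "DUP"}.get(r.svtype, r.svtype)
        info = (
            f"SVTYPE={vcf_type};END={r.end};SUPPORT={r.support_reads};"
            f"FWD={int(r.has_forward)};REV={int(r.has_reverse)}"
        )
        if r.junction_ins:
            info += f";INSSEQ={r.junction_ins}"
        if r.caller:
            info += f";CALLER={r.caller}"
        lines.append(
            f"{r.chrom}\t{r.start}\tsv{i}\tN\t{alt_by_type.get(r.svtype, '<SV>')}\t"
            f".\tPASS\t{info}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def _info_get(variant, keys, default=None):
    for k in keys:
        v = variant.INFO.get(k)
        if v is not None:
            return v
    return default


def read_sv_vcf(
    path: PathLike,
    sample: Optional[str] = None,
    field_map: Optional[dict] = None,
) -> list[SVRecord]:
    """Read SV records from a VCF.

    DUP / DUP:TANDEM become TD, symbolic DEL/INS keep their type; pairs of
    intra-chromosomal breakends in duplication orientation (ALT of the form
    ``]chrom:p]N`` with p beyond POS) are collapsed to one TD.  The sample
    id comes from ``sample``, a ``##sample=`` header line, or the file stem.
    Support and orientation are looked up via ``field_map`` (see
    ``DEFAULT_SV_FIELD_MAP``); a missing support field yields 0 so that
    unannotated records cannot pass the support filter by accident.
    """
    from cyvcf2 import VCF

    fm = {**DEFAULT_SV_FIELD_MAP, **(field_map or {})}
    vcf = VCF(str(path))
    if sample is None:
        m = re.search(r"##sample=(\S+)", vcf.raw_header)
        sample = m.group(1) if m else Path(path).stem
    records = []
    seen_bnd_spans = set()
    for v in vcf:
        svtype = (v.INFO.get("SVTYPE") or "").upper()
        support = int(_info_get(v, fm["support"], 0))
        fwd = bool(int(_info_get(v, fm["forward"], 1)))
        rev = bool(int(_info_get(v, fm["reverse"], 1)))
        ins = str(_info_get(v, fm["insertion"], "") or "")
        caller = str(v.INFO.get("CALLER") or "")
        if svtype == "BND":
            mobj = _BND_RE.match(v.ALT[0]) if v.ALT else None
            if not mobj:
                continue
            mate_chrom, mate_pos = mobj.group(1), int(mobj.group(2))
            if mate_chrom != v.CHROM or mate_pos <= v.POS:
                continue  # other half of the pair, or inter-chromosomal
            span = (v.CHROM, v.POS, mate_pos)
            if span in seen_bnd_spans:
                continue
            seen_bnd_spans.add(span)
            start, end, rtype = v.POS, mate_pos, "TD"
        else:
            start = v.POS
            end = int(v.INFO.get("END") or start)
            if svtype.startswith("DUP"):
                rtype = "TD"
            elif svtype in ("DEL", "INS"):
                rtype = svtype
            else:
                rtype = "OTHER"
        records.append(
            SVRecord(
                sample_id=sample, chrom=v.CHROM, start=start, end=end,
                svtype=rtype, support_reads=support,
                has_forward=fwd, has_reverse=rev,
                junction_ins=ins, caller=caller,
            )
        )
    return records


_SV_TSV_COLUMNS = [
    "sample_id", "chrom", "start", "end", "svtype", "support_reads",
    "has_forward", "has_reverse", "junction_ins", "caller",
]


def write_sv_tsv(records: list[SVRecord], path: PathLike) -> None:
    pd.DataFrame(
        [
            {c: getattr(r, c) for c in _SV_TSV_COLUMNS}
            for r in records
        ],
        columns=_SV_TSV_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def read_sv_tsv(path: PathLike) -> list[SVRecord]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, dtype={"junction_ins": str})
    return [
        SVRecord(
            sample_id=str(row["sample_id"]),
            chrom=str(row["chrom"]),
            start=int(row["start"]),
            end=int(row["end"]),
            svtype=str(row["svtype"]),
            support_reads=int(row["support_reads"]),
            has_forward=_to_bool(row["has_forward"]),
            has_reverse=_to_bool(row["has_reverse"]),
            junction_ins=str(row["junction_ins"]),
            caller=str(row["caller"]),
        )
        for _, row in df.iterrows()
    ]


def write_td_junctions_tsv(junctions: list[TDJunction], path: PathLike) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": j.record.sample_id,
                "chrom": j.record.chrom,
                "start": j.record.start,
                "end": j.record.end,
                "size": j.size,
                "mh_len": j.mh.length,
                "mh_class": j.mh.mh_class,
                "ins_class": j.insertion.ins_class if j.insertion else "",
            }
            for j in junctions
        ]
    ).to_csv(path, sep="\t", index=False)


def _to_bool(value) -> bool:
    if isinstance(value, str):
        return value.strip().lower() in ("true", "1", "yes")
    return bool(value)
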