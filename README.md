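# dsbfoot

Mutational footprint analysis of DNA double-strand-break (DSB) repair
products.

When a chromosome breaks, the mutagenic repair pathways each leave a
characteristic scar at the junction:

* **TMEJ** (polymerase theta-mediated end joining) — deletions whose
  junctions carry only minute microhomology (0–5 bp), frequently with
  insertions templated from the sequence flanking the break; iterative
  abortive rounds of synthesis produce "patchwork" insertions built from
  several flank-derived stretches.
* **eMMEJ** (extended-microhomology end joining) — deletions whose junctions
  reuse pre-existing direct repeats of ~20–30 bp ("eMH") that flank a
  G-quadruplex (G4) motif, leaving >5 bp of junction microhomology.
* **SSA** (single-strand annealing) — collapse of long (~250 bp) direct
  repeats into a single copy, deleting one repeat and everything between.
* **Tandem duplications** — head-to-tail duplications (median ~1 kb, range
  ~100 bp–10 kb) arising when an extended end from abortive
  synthesis-dependent strand annealing is end-joined back by TMEJ; their
  junctions carry the TMEJ signature.

`dsbfoot` turns Sanger reads of repair products (and structural-variant
calls from whole-genome sequencing) into classified, junction-annotated
event tables, and ships a seeded generator that simulates each pathway's
footprint so the whole pipeline can be validated against ground truth.

## The statistics at the core

**Junction microhomology (MH).** For a deletion with bounds (s, e) on
reference `r`, the right extension is the largest k with
`r[s:s+k] == r[e:e+k]` and the left extension the largest k with
`r[s-k:s] == r[e-k:e]`. Their sum is the MH length, and MH + 1 equals the
number of distinct breakpoint placements that reconstruct an identical
product — the score is therefore independent of the alignment convention.
MH of 1–5 bp is the TMEJ range ("minute"); >5 bp marks homology-driven
junctions ("extended", the eMMEJ/SSA range). Tandem-duplication boundaries
have exactly the same placement ambiguity, so the same formula scores TD
junctions.

**Insertion-origin mapping.** Insertions are segmented greedily, longest
match first, against windows of ±300 bp around the deletion (both strands).
Insertions covered ≥80 % by segments of ≥8 bp are *templated*; two or more
segments, or a reused stretch, make a *patchwork*; everything else is of
undetermined origin.

**Quality filtering.** A Sanger read is used only if it contains a stretch
of ≥40 nt in which every base has an error probability 10^(−Q/10) < 0.05;
all other bases are masked, and events whose junction falls outside the
stretch are discarded.

**SV filtering.** A structural variant is considered true when supported by
≥5 reads covering the junction in both orientations and uniquely present in
one sample of the cohort.

## Worked example

Simulate 500 TMEJ products at a G4 locus, sequence each one with a
Sanger-style read, and push the reads through QC → allele calling →
junction annotation:

```python
import numpy as np
from dsbfoot import synthetic_data as sd
from dsbfoot.pipeline import process_reads
from dsbfoot.junction_classifier import spectrum_summary

cfg = sd.SimConfig(seed=1)
rng = np.random.default_rng(1)
locus = sd.make_locus(cfg, rng)

annotations = []
for _ in range(500):
    event = sd.simulate_tmej(locus, cfg, rng)
    reads = sd.simulate_sanger_reads(
        event.product_seq, cfg, rng, junction=event.event.del_iv.start
    )
    annotations += process_reads(reads, event.locus).annotations

summary = spectrum_summary(annotations)
print(f"events analysed:        {summary.n_events}")
print(f"with insertion:         {summary.frac_with_insertion:.1f}%")
print(f"patchwork (of mapped):  {summary.frac_patchwork_among_insertions:.1f}%")
print(f"spectrum codes:         {summary.class_counts}")
print(f"MH length histogram:    {summary.mh_length_histogram}")
```

prints

```
events analysed:        500
with insertion:         28.0%
patchwork (of mapped):  11.0%
spectrum codes:         {'simple_mh': 300, 'delins_mapped': 136, 'simple_no_mh': 60, 'delins_unmapped': 4}
MH length histogram:    {0: 60, 1: 75, 2: 50, 3: 54, 4: 71, 5: 50}
```

Every simulated read survived QC and calling; the recovered insertion
fraction (28.0 %) matches the generator's configured 30 % within binomial
noise, and the MH histogram is flat over the engineered 0–5 bp range, as
drawn. The spectrum codes mirror the conventional colour-coded deletion
spectra: grey (`simple_no_mh`), blue (`simple_mh`), bright red
(`delins_mapped`) and dark red (`delins_unmapped`).

The same stages are available from the shell:

```bash
dsbfoot simulate --preset tmej --n 500 --seed 7 --outdir sim/
dsbfoot qc --fastq reads.fq --min-len 40 --max-p 0.05
dsbfoot call --ref locus.fa --fastq masked.fq
dsbfoot classify --events events.tsv --ref locus.fa
dsbfoot find-emh --fasta loci.fa --window 300 --min-len 20
dsbfoot sv-filter --vcf a.vcf --vcf b.vcf --min-support 5
dsbfoot td-junctions --tsv filtered.tsv --fasta genome.fa
```

All coordinates in inputs and outputs are 0-based, half-open.

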