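# Methods

This note documents the models, conventions and numerical choices behind
`dsbfoot`, and what the synthetic validation does and does not demonstrate.

## Coordinates and event representation

All coordinates are 0-based, half-open, on the reference locus. A repair
product is represented canonically as a pair (deleted interval, inserted
sequence); the class (wild type / insertion / deletion / delins) is fully
determined by which member is non-empty. Junction microhomology makes the
breakpoint placement ambiguous — several (deletion, insertion) pairs of the
same lengths reconstruct the same product string — so events are
left-aligned (minimal deletion start, the VCF convention) before any
comparison. Two events are the same event if and only if their
reconstructions are identical strings. All microhomology statistics are
placement-invariant by construction, so the choice of left over right
alignment affects only reported coordinates, never MH lengths or class
calls.

## Junction microhomology

For deletion bounds (s, e) the MH length is the sum of the left and right
junction extensions (see README for the formula); MH + 1 equals the number
of equivalent breakpoint placements, which is the property the test suite
checks against exhaustive enumeration. Classes: 0 → none, 1–5 bp → minute
(the TMEJ range), ≥6 bp → extended (the eMMEJ/SSA range; the >5 bp boundary
is the conventional threshold separating polymerase-theta-dependent from
homology-driven end joining). Deletions touching a sequence end get their
MH computed over the available bases and are flagged `truncated`.
Tandem-duplication boundaries are scored with the same formula: shifting
both TD boundaries in step yields an identical rearranged sequence exactly
when the boundary contexts share bases.

## Allele calling

Reads are assumed to be full-length Sanger reads of the PCR product,
registered to the reference at both ends (fixed primers). The caller
anchors the read by its longest exact common prefix and suffix; masked (N)
bases never match and leading/trailing masked stretches are assumed to
consume reference positions one for one — valid whenever the junction lies
inside the unmasked core, which is exactly the condition the post-calling
QC gate enforces. The suffix anchor is measured on the whole unmasked core
and then trimmed if it overlaps the prefix; both anchors must reach 15 nt
(`anchor_min`) of unmasked matches or the read is rejected as unalignable.
Exact anchoring (no mismatches, no gap model) is a deliberate choice: reads
are quality-masked first and the products of interest are single-junction
events; multi-junction rearrangements and heteroduplex traces are out of
scope.

## Quality model

Phred Q gives error probability 10^(−Q/10). The filter takes the longest
contiguous run in which every base is below the cutoff (default
p < 0.05 ⇔ Q ≥ 14), requires ≥40 nt, masks the rest, and — because the
junction position in read coordinates is unknown before alignment —
enforces "high quality around the break site" as a second stage: after
calling, events whose junction is not strictly inside the window are
discarded and counted. Single-run semantics (an isolated low-quality base
splits the window) were chosen over gap-tolerant runs; ties go to the
leftmost run.

## Insertion-origin mapping

Greedy longest-match-first segmentation of the insertion against three
windows: 300 bp upstream of the deletion start, 300 bp downstream of the
deletion end, and the deleted interval itself (`inside_del` — templated
inserts may copy sequence that was subsequently deleted; these are counted
separately). Matches on the minus strand (reverse complement) are allowed
by default. Segments must reach 8 bp (`seg_min`, operationalising "can be
reliably mapped"); an insertion is *templated* when ≥80 % of its bases are
covered (`cov_min`); *patchwork* = ≥2 segments or a repeated stretch (two
segments with identical origin or identical sequence). Ties are broken
deterministically: leftmost insertion position, then left < right <
inside_del window, then + before −, then leftmost origin. Thresholds are
reporting choices; the classifier exposes them as parameters, and fractions
such as the patchwork share can shift by a few points under different
`seg_min`.

## SV filtering and TD junctions

Record-level filters mirror standard practice for short-read SV
verification: ≥5 supporting reads, both orientations present, and
uniqueness within the cohort (another sample with the same SV type and both
breakpoints within 10 bp removes every member of the shared event). The
tolerance is configurable; 10 bp absorbs caller-dependent breakpoint
jitter, including the ±1 bp offset between this package's 0-based VCF span
convention (POS = 0-based start, END = 0-based exclusive end, documented in
`io.py`) and the 1-based anchor convention of standard callers. Support is
read from a configurable INFO field map; records without a recognised
support field default to 0 so they cannot pass the filter unnoticed.
Breakend pairs in duplication orientation on one chromosome are collapsed
to a single TD. The size-spectrum median uses the lower of the two middle
values for even n (stated convention, so summaries are reproducible
integers).

## Synthetic data: what it emulates

The generator produces ground truth for every other module under the study
conditions:

* **Loci**: 2 kb random sequence at GC 0.36 (the *C. elegans* genome is
  AT-rich), a planted G4 motif (four G-tracts of 3–4 G, loops 1–3 nt) at
  the centre, and optionally a planted direct repeat (default 25 bp,
  identical copies 40 bp upstream / 60 bp downstream of the motif —
  the observed flanking homology at eMMEJ-competent loci is ~20–30 bp).
  Rejection sampling guarantees no coincidental flank repeat ≥ the planted
  length, and single-base mismatches are forced immediately outside both
  planted copies so the pair has exact boundaries.
* **TMEJ**: deletion from ≤10 bp upstream of the motif to 50–300 bp
  downstream of it; the drawn MH (uniform over 0–5 bp) is engineered
  exactly by copying m bases across the junction on a private copy of the
  locus and forcing mismatches at both ends of the run. 30 % of products
  carry an insertion; 14 % of those are patchworks of 2–4 flank stretches
  (8–14 bp each, 30 % chance of reusing one); half of templated stretches
  are reverse-complement. Inserts are redrawn when their footprint would
  not be observable as its own label (a last base equal to the junction
  context would rotate under left alignment; a seam-crossing ≥8 bp flank
  match would merge patchwork pieces into one apparent template) — truth
  labels describe the observable footprint.
* **eMMEJ**: deletion between homologous positions of the planted repeat
  copies, retaining exactly one copy, so junction MH = repeat length minus
  planted mismatches.
* **SSA**: a reporter construct with two identical 250 bp repeats around a
  30 bp spacer containing the I-SceI recognition site; the product is the
  single-copy collapse (junction MH = 250 bp).
* **TD**: size drawn log-normal with median 1 kb (the 100 bp–10 kb range
  spans ±3σ; a log-uniform law over the same range was rejected because the
  median of a 300-event cohort then misses the ±20 % self-consistency band
  on ~12 % of seeds), junction MH engineered as for TMEJ, 20 % of junctions
  carrying a templated insert, emitted as both the rearranged sequence and
  an SV record with configurable support fields.
* **Reads**: full-length copies of the product with a Q50 plateau (default
  200 nt) centred on the junction and linearly decaying tails (1.5 Phred
  points per base); optional mid-plateau dips create QC failures on demand.

All generators are bit-reproducible given (seed, config).

### What passing tests do and do not show

The synthetic reads carry no base-calling errors inside the high-quality
window, no chimeric or mixed traces, and exactly one junction per product;
real Sanger data adds miscalls, heteroduplex positions and occasional
multi-junction products that this pipeline deliberately rejects rather
than resolves. Synthetic loci are i.i.d. random sequence — real flanks
contain repeat families that raise the rate of coincidental homology, so
real-data MH and insertion-origin calls inherit more ambiguity than the
synthetic recovery rates (≥95 %) suggest. The SV cohort tests validate the
filter logic, not the upstream callers.

## Problem sizes and numerical conventions

Oracle-agreement checks run at 1,000 random deletion junctions, 500 TD
junctions and 1,000 quality vectors; round trips at 1,000 simulated events
across all pathway labels; repeat-finder/oracle agreement on 100 random
loci (55 bp windows for the all-pairs oracle) plus 100 planted
constructions at full 300 bp windows; generator self-consistency at
n = 1,000 (fractions) and n = 300 (TD median). Proportions are judged
within 3 binomial standard errors of the configured value. The chi-square
test on 2×2 spectra tables is Pearson's without continuity correction
(df = 1), undefined (raised) on zero marginals. Repeat discovery with
mismatches reports maximal ≤k-mismatch windows per alignment diagonal,
trimmed so both endpoints match, with containment suppression on the same
diagonal; default `max_mismatch = 0`.

## Known limitations

* No fallback alignment for reads whose junction lies in the masked tail;
  such reads are dropped (counted), not rescued.
* Insertion mapping is exact-match only; a single miscalled base inside a
  templated insert moves it to "undetermined origin".
* G4 scanning uses the standard motif rule G≥3(N1–7G≥3)≥3 on both strands;
  it does not model thermodynamic stability, and desk-scale performance
  (kilobase loci) was favoured over genome-scale optimisation.
* The BND-to-TD collapse recognises intra-chromosomal duplication-oriented
  pairs only; inter-chromosomal and inversion breakends pass through as
  `OTHER`.
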