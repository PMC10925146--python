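# Methods

## Model and assumptions

A fusion transcript joins exonic sequence of a 5' gene to exonic sequence of
a 3' gene, almost always at annotated exon junctions via canonical
splicing. A long read sequencing such a molecule aligns as two (or more)
segments at distinct genomic loci; the caller's job is to recognize that
split, orient it in the transcript's sense, locate the junction at base
resolution, and quantify support per splicing isoform. The method assumes:

* reads are cDNA molecules that may be sequenced from either strand, so a
  read antisense to both genes carries the same evidence as its sense
  complement (orientation is normalized, never averaged);
* a linear molecule evidences junctions only between *consecutive* alignment
  segments, so a read with n segments contributes n−1 candidate junctions
  (non-adjacent pairs are not emitted);
* true breakpoints cluster at exon boundaries, which motivates both the
  phase-1 proximity gate and the phase-2 snapping step.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| minimum alignment identity | 70 | % | segment retention before pairing |
| exon-boundary distance, strict | 50 | bases | phase-1 gate, both sides |
| exon-boundary distance, relaxed | 1000 | bases | phase-1 gate, one side, ≥ 2 reads |
| minimum expression | 0.1 | FFPM | phase-1 and final filters |
| locus separation | 100 000 | bases | same-contig split-read gate |
| minimum anchor | 25 | bases | aligned bases per junction side |
| intron shrinkage | 1000 | bases | fusion-contig construction |
| junction spacer | 20 | N bases | contig region separator |
| snapping tolerance | 3 | bases | block-end to exon-boundary snap |
| non-consensus read minimum | 2 | reads | non-GT–AG breakpoints |
| minor isoform fraction | 5 | % of dominant | per-pair isoform noise filter |
| fuzzy breakpoint window | ±5 | bases | benchmark fuzzy mode |
| proxy-truth support | 3 | reads | proxy-truth construction |
| promiscuity rule | ≥2 methods, ≥3 samples | — | proxy-truth gene exclusion |

FFPM (fusion fragments per million) is `count × 10⁶ / total`; the product is
taken before the division so that one read in ten million compares equal to
the 0.1 threshold in floating point.

The minimum-anchor and locus-separation values are this package's own
choices: 25 bases suppresses microhomology split artifacts at junctions, and
100 kb matches the neighboring-gene notion used by the benchmark filters, so
same-chromosome segments closer than that are left to the neighbor logic
rather than treated as chimeric.

## Numerical and design choices

* **Coordinates.** Internal intervals are 0-based half-open; reported
  breakpoints are 1-based `contig:position:strand`, the position being the
  last transcribed base of the 5' segment or the first of the 3' segment.
* **Consensus splice set.** Only GT–AG counts as consensus; GC–AG and AT–AC
  are treated as non-consensus (the set is a call-site argument). The donor
  dinucleotide is read immediately 3' of the 5'-gene breakpoint in
  transcriptional orientation, reverse-complemented for minus-strand genes.
* **Exon boundaries are pooled across all transcripts** of a gene for
  distance tests and snapping; no primary transcript is privileged.
* **Intron shrinkage keeps the two flanking 500-base halves** of a long
  intron rather than inserting a fixed spacer, preserving splice-site
  sequence for the dinucleotide check after realignment.
* **The 20-base N spacer** between contig gene regions prevents read-through
  alignment across the synthetic junction; CIGAR deletions ≥ 10 bases also
  break alignment blocks so a spacer crossed by a deletion still separates
  the two gene regions.
* **Snapping** moves each block end independently to the nearest exon
  boundary within tolerance, shifting the read interval by the same offset;
  a snap that would invert a block is skipped. The operation is idempotent.
* **Breakpoint grouping is exact**; near-identical junctions are distinct
  isoforms at calling time, and tolerance belongs to the benchmark's fuzzy
  mode.
* **The dominant isoform** for the 5% noise rule is fixed on the unfiltered
  call set (ties broken by leftmost 5' breakpoint), which makes the final
  per-call filters order-independent.
* **One-to-one matching.** Benchmark scoring consumes each truth entry at
  most once, using a maximum bipartite matching, so TP counts are invariant
  to record order and a double-predicted truth yields one TP plus one FP.
  Duplicate predictions within a method are collapsed first.
* **Sweep thresholds** are the distinct observed support values (ties on F1
  resolve to the smallest threshold).
* **Blocklist order.** The normal-tissue blocklist is applied alongside the
  other final filters, i.e. effectively after the 5% rule; since the rule's
  dominant support is fixed pre-filter, the order does not change the
  retained set.
* **Degenerate inputs.** Empty alignment sets yield empty outputs; a zero or
  negative library size is an error; records lacking identity-derivable
  fields are kept but fail the identity filter; benchmark records missing
  breakpoints are excluded from breakpoint scoring and logged.

## Synthetic data generator

The generator emulates the study conditions end to end: a toy multi-gene
genome (default 10 genes, 3–6 exons of 80–300 bases, introns of 200–3000
bases with GT..AG flanks, alternating strands, one gene per contig), fusion
transcripts joined at exon junctions, reads at 3–8 per transcript with
i.i.d. substitution/indel errors, a 0.5 antisense fraction (double-stranded
cDNA), and an optional 3'-anchored fragmenting mode emulating the coverage
bias of 3'-capture single-cell libraries (the junction-to-3'-end distance is
recorded in truth so the short/long detection asymmetry can be exercised as
a property). Genes sit on separate contigs because the phase-1 scan
deliberately ignores same-contig splits closer than 100 kb; co-located
partners are a dedicated fixture for the neighbor filters, not a default
condition.

By-construction "truth" alignments (genome-space PAF, contig-space blocks)
make the whole pipeline testable without an aligner, for substitution-only
reads; indel-bearing reads shift coordinates and are directed to the
external minimap2 path, which is exercised separately in the tests.

What the generator does **not** model: realistic long-read error profiles
(homopolymer errors, quality scores, chimera artifacts from library
preparation), multi-transcript genes' alternative splicing, genomic
rearrangement context, or expression heterogeneity. Passing tests therefore
demonstrate algorithmic correctness of the detection, quantification and
scoring machinery under controlled error — not end-to-end accuracy on real
sequencing data, which additionally depends on the external aligner's
behavior and annotation quality.

## Problem sizes used by the test suite

The exactness and robustness suites run 50 simulated fusions over 30 genes
(roughly 400 reads) error-free and at a 2% substitution rate; oracle
equivalence checks use 1000 random instances each; all told the default
suite completes in a few seconds on one CPU.

## Known limitations

* Fusions whose partner locus is absent from the annotation cannot be
  reported (gene assignment requires an overlapping gene model).
* Phase 2 evaluates only phase-1 candidate pairs; a fusion invisible to the
  split-read scan cannot be rescued by realignment.
* The identity fallback `(1 − NM/alignment length) × 100` counts indel
  columns as differences, which slightly understates identity for
  indel-rich alignments.
* Breakpoints within two bases of a contig end have undefined splice
  dinucleotides and are reported without a consensus flag.
* The per-cell matrix deduplicates by exact (barcode, UMI) match; sequencing
  errors in barcodes/UMIs are not collapsed.
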