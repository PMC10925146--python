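"""Phase 1: chimeric long-read scan.

Parses long-read alignments (PAF or SAM/BAM with supplementary records),
identifies reads whose alignments split across two distinct genomic loci,
assigns the split segments to an ordered (5', 3') gene pair, and applies the
phase-1 retention rules:

* per-segment minimum alignment identity (default 70%),
* exon-boundary proximity of the chimeric junction — retained if both
  junction-to-boundary distances are within 50 bases, or one is within
  50 bases and the other within 1 kb with at least two supporting reads,
* a minimum expression of 0.1 FFPM (fusion reads per million total reads,
  i.e. at least one fusion read per 10 M reads).

The 5'/3' orientation of each candidate is normalized so that it reflects
the transcriptional sense of the fusion transcript: a read sequenced from
the second cDNA strand (antisense to both genes) yields the same ordered
gene pair as its sense counterpart.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .annotation import BoundaryIndex, Breakpoint, GeneModel

logger = logging.getLogger(__name__)

DEFAULT_MIN_IDENTITY = 70.0  # percent
DEFAULT_MIN_ANCHOR = 25  # bases on each side of the junction
DEFAULT_LOCUS_SEPARATION = 100_000  # same-contig gap declaring distinct loci
DEFAULT_MIN_FFPM = 0.1
MAX_BOUNDARY_DIST_STRICT = 50
MAX_BOUNDARY_DIST_RELAXED = 1000


@dataclass(frozen=True)
class ReadAlignmentSegment:
    """One alignment record of a read, in original-read coordinates."""

    read_id: str
    read_start: int
    read_end: int
    contig: str
    genome_start: int
    genome_end: int
    strand: str
    identity: float | None  # percent, None when not derivable from the record
    role: str = "representative"  # or "supplementary"

    def __post_init__(self):
        if self.read_end <= self.read_start:
            raise ValueError(f"{self.read_id}: empty read interval")
        if self.genome_end <= self.genome_start:
            raise ValueError(f"{self.read_id}: empty genomic interval")
        if self.identity is not None and not (0.0 <= self.identity <= 100.0):
            raise ValueError(f"{self.read_id}: identity {self.identity} out of range")

    @property
    def read_length_aligned(self) -> int:
        return self.read_end - self.read_start


@dataclass
class ChimericCandidate:
    """A single read's evidence for an ordered gene-pair fusion."""

    read_id: str
    segment_5p: ReadAlignmentSegment
    segment_3p: ReadAlignmentSegment
    gene_5p: str
    gene_3p: str
    breakpoint_5p: Breakpoint
    breakpoint_3p: Breakpoint
    dist_5p: int
    dist_3p: int
    tied_genes_5p: tuple[str, ...] = ()
    tied_genes_3p: tuple[str, ...] = ()


@dataclass
class FusionPairCandidate:
    """All phase-1 evidence for one ordered gene pair."""

    gene_pair: tuple[str, str]
    candidates: list[ChimericCandidate] = field(default_factory=list)
    ffpm: float = 0.0

    @property
    def read_ids(self) -> set[str]:
        return {c.read_id for c in self.candidates}

    @property
    def read_count(self) -> int:
        return len(self.read_ids)


# ---------------------------------------------------------------------------
# Alignment parsing
# ---------------------------------------------------------------------------


def parse_alignments(path: str | Path) -> dict[str, list[ReadAlignmentSegment]]:
    """Parse PAF or SAM/BAM alignments into segments grouped by read id.

    Percent identity is matches / alignment-column count × 100 when the
    record carries a match count, else ``(1 − NM / alignment length) × 100``
    from the edit-distance tag; records providing neither keep
    ``identity=None`` and are later removed by the identity filter.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".paf":
        return _parse_paf(path)
    if suffix in (".sam", ".bam", ".cram"):
        return _parse_sam(path)
    raise ValueError(
        f"unknown alignment format {path.name!r}: expected .paf, .sam or .bam"
    )


def _parse_paf(path: Path) -> dict[str, list[ReadAlignmentSegment]]:
    with open(path) as fh:
        return parse_paf_lines(fh, source=str(path))


def parse_paf_lines(
    lines: Iterable[str], source: str = "<paf>"
) -> dict[str, list[ReadAlignmentSegment]]:
    """Parse PAF records from an iterable of lines, grouped by read id."""
    groups: dict[str, list[ReadAlignmentSegment]] = defaultdict(list)
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) < 12:
            raise ValueError(
                f"{source}: malformed PAF line {lineno}: fewer than 12 columns"
            )
        tags = dict(
            (t.split(":", 2)[0], t.split(":", 2)[1:]) for t in f[12:] if ":" in t
        )
        try:
            n_match, aln_len = int(f[9]), int(f[10])
        except ValueError:
            n_match, aln_len = -1, 0
        identity: float | None
        if aln_len > 0 and n_match >= 0:
            identity = 100.0 * n_match / aln_len
        elif "NM" in tags and aln_len > 0:
            identity = 100.0 * (1.0 - int(tags["NM"][1]) / aln_len)
        else:
            identity = None
        role = "representative"
        if "tp" in tags and tags["tp"][1] == "S":
            role = "supplementary"
        seg = ReadAlignmentSegment(
            read_id=f[0],
            read_start=int(f[2]),
            read_end=int(f[3]),
            contig=f[5],
            genome_start=int(f[7]),
            genome_end=int(f[8]),
            strand=f[4],
            identity=identity,
            role=role,
        )
        groups[seg.read_id].append(seg)
    return dict(groups)


def _parse_sam(path: Path) -> dict[str, list[ReadAlignmentSegment]]:
    import pysam

    groups: dict[str, list[ReadAlignmentSegment]] = defaultdict(list)
    save = pysam.set_verbosity(0)
    try:
        with pysam.AlignmentFile(str(path), check_sq=False) as af:
            for rec in af:
                if rec.is_unmapped or rec.is_secondary:
                    continue
                cig = rec.cigartuples or []
                hard5 = cig[0][1] if cig and cig[0][0] == 5 else 0
                hard3 = cig[-1][1] if cig and cig[-1][0] == 5 else 0
                stored_len = rec.query_length
                full_len = stored_len + hard5 + hard3
                qs = hard5 + rec.query_alignment_start
                qe = hard5 + rec.query_alignment_end
                if rec.is_reverse:  # flip to original read orientation
                    qs, qe = full_len - qe, full_len - qs
                aln_cols = sum(n for op, n in cig if op in (0, 1, 2, 7, 8))
                identity: float | None = None
                if rec.has_tag("NM") and aln_cols > 0:
                    identity = 100.0 * (1.0 - rec.get_tag("NM") / aln_cols)
                groups[rec.query_name].append(
                    ReadAlignmentSegment(
                        read_id=rec.query_name,
                        read_start=qs,
                        read_end=qe,
                        contig=rec.reference_name,
                        genome_start=rec.reference_start,
                        genome_end=rec.reference_end,
                        strand="-" if rec.is_reverse else "+",
                        identity=identity,
                        role="supplementary" if rec.is_supplementary else "representative",
                    )
                )
    finally:
        pysam.set_verbosity(save)
    return dict(groups)


# ---------------------------------------------------------------------------
# Chimeric read detection
# ---------------------------------------------------------------------------


def detect_chimeric_reads(
    grouped_segments: Mapping[str, Sequence[ReadAlignmentSegment]],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_anchor: int = DEFAULT_MIN_ANCHOR,
    locus_separation: int = DEFAULT_LOCUS_SEPARATION,
) -> list[tuple[ReadAlignmentSegment, ReadAlignmentSegment]]:
    """Find split reads whose adjacent segments lie at distinct genomic loci.

    Segments below ``min_identity`` (or with unknown identity) are removed
    before pairing.  A read with three or more retained segments yields one
    pair per adjacent segment pair along the read — a linear cDNA molecule
    only evidences junctions between consecutive segments.  The first element
    of each returned pair covers the lower read coordinates (5' on the read).
    """
    pairs: list[tuple[ReadAlignmentSegment, ReadAlignmentSegment]] = []
    for read_id in sorted(grouped_segments):
        segs = [
            s
            for s in grouped_segments[read_id]
            if s.identity is not None
            and s.identity >= min_identity
            and s.read_length_aligned >= min_anchor
        ]
        if len(segs) < 2:
            continue
        segs.sort(key=lambda s: (s.read_start, s.read_end))
        for left, right in zip(segs, segs[1:]):
            if left.contig != right.contig:
                pairs.append((left, right))
                continue
            gap = max(
                left.genome_start - right.genome_end,
                right.genome_start - left.genome_end,
            )
            if gap > locus_separation:
                pairs.append((left, right))
    return pairs


def _junction_coords(
    left: ReadAlignmentSegment, right: ReadAlignmentSegment
) -> tuple[int, int]:
    """0-based genomic coordinates of the junction-adjacent base per segment."""
    jl = left.genome_end - 1 if left.strand == "+" else left.genome_start
    jr = right.genome_start if right.strand == "+" else right.genome_end - 1
    return jl, jr


def assign_genes(
    segment_pair: tuple[ReadAlignmentSegment, ReadAlignmentSegment],
    index: BoundaryIndex,
) -> ChimericCandidate | None:
    """Assign a chimeric segment pair to an ordered (5', 3') gene pair.

    Each segment is assigned the overlapping gene with maximal span overlap
    (ties broken toward the lexicographically smaller gene id, all tied ids
    recorded).  The ordered pair follows the fusion transcript's sense: if
    both segments align antisense to their genes, the read is the reverse
    complement of the transcript and the roles are swapped.  Candidates whose
    two segments have inconsistent strand combinations, map to the same gene,
    or overlap no gene are rejected (returns None, logged).
    """
    left, right = segment_pair
    gl = _best_gene(left, index)
    gr = _best_gene(right, index)
    if gl is None or gr is None:
        logger.debug("%s: segment overlaps no annotated gene", left.read_id)
        return None
    (gene_l, ties_l), (gene_r, ties_r) = gl, gr
    if gene_l.gene_id == gene_r.gene_id:
        logger.debug("%s: both segments within gene %s", left.read_id, gene_l.gene_id)
        return None

    sense_l = left.strand == gene_l.strand
    sense_r = right.strand == gene_r.strand
    jl, jr = _junction_coords(left, right)
    if sense_l and sense_r:
        # Read is the fusion transcript: left segment is the 5' gene.
        seg5, seg3, gene5, gene3 = left, right, gene_l, gene_r
        j5, j3 = jl, jr
        t5, t3 = ties_l, ties_r
    elif not sense_l and not sense_r:
        # Second-strand cDNA read: reverse complement of the transcript.
        seg5, seg3, gene5, gene3 = right, left, gene_r, gene_l
        j5, j3 = jr, jl
        t5, t3 = ties_r, ties_l
    else:
        logger.debug("%s: inconsistent strand combination", left.read_id)
        return None

    return ChimericCandidate(
        read_id=left.read_id,
        segment_5p=seg5,
        segment_3p=seg3,
        gene_5p=gene5.gene_id,
        gene_3p=gene3.gene_id,
        breakpoint_5p=_breakpoint(gene5, j5, five_prime=True),
        breakpoint_3p=_breakpoint(gene3, j3, five_prime=False),
        dist_5p=_boundary_distance(gene5, j5, five_prime=True),
        dist_3p=_boundary_distance(gene3, j3, five_prime=False),
        tied_genes_5p=t5,
        tied_genes_3p=t3,
    )


def _best_gene(
    seg: ReadAlignmentSegment, index: BoundaryIndex
) -> tuple[GeneModel, tuple[str, ...]] | None:
    hits = index.genes_overlapping(seg.contig, seg.genome_start, seg.genome_end)
    if not hits:
        return None
    overlaps = []
    for gene in hits:
        s, e = gene.span
        ov = min(e, seg.genome_end) - max(s, seg.genome_start)
        overlaps.append((ov, gene))
    best_ov = max(ov for ov, _ in overlaps)
    tied = sorted(
        (g for ov, g in overlaps if ov == best_ov), key=lambda g: g.gene_id
    )
    return tied[0], tuple(g.gene_id for g in tied)


def _breakpoint(gene: GeneModel, junction0: int, five_prime: bool) -> Breakpoint:
    # junction0 is the 0-based junction-adjacent base; report 1-based.
    return Breakpoint(gene.contig, junction0 + 1, gene.strand)


def _boundary_distance(gene: GeneModel, junction0: int, five_prime: bool) -> int:
    # Exon boundaries use half-open coordinates: the junction after the last
    # transcribed base of an exon (5' side, + strand) coincides with the exon
    # end; measure from the matching half-open edge of the junction base.
    transcribed_then_boundary = five_prime == (gene.strand == "+")
    pos = junction0 + 1 if transcribed_then_boundary else junction0
    from .annotation import nearest_exon_boundary_distance

    return nearest_exon_boundary_distance(gene, pos)


# ---------------------------------------------------------------------------
# Aggregation and filtering
# ---------------------------------------------------------------------------


def compute_ffpm(fusion_read_count: int, total_reads: int) -> float:
    """Fusion reads per million total reads: count / total × 10^6."""
    if fusion_read_count < 0:
        raise ValueError(f"negative read count {fusion_read_count}")
    if total_reads <= 0:
        raise ValueError(f"total read count must be positive, got {total_reads}")
    # multiply first: 1 read in 10 M must equal the 0.1 threshold exactly
    return fusion_read_count * 1e6 / total_reads


def aggregate_candidates(
    candidates: Iterable[ChimericCandidate], total_reads: int
) -> list[FusionPairCandidate]:
    """Group per-read candidates by ordered gene pair and compute FFPM."""
    by_pair: dict[tuple[str, str], FusionPairCandidate] = {}
    for cand in candidates:
        pair = (cand.gene_5p, cand.gene_3p)
        by_pair.setdefault(pair, FusionPairCandidate(pair)).candidates.append(cand)
    out = []
    for pair in sorted(by_pair):
        fc = by_pair[pair]
        fc.ffpm = compute_ffpm(fc.read_count, total_reads)
        out.append(fc)
    return out


def phase1_filter(
    pairs: Iterable[FusionPairCandidate],
    total_reads: int,
    min_ffpm: float = DEFAULT_MIN_FFPM,
    max_dist_strict: int = MAX_BOUNDARY_DIST_STRICT,
    max_dist_relaxed: int = MAX_BOUNDARY_DIST_RELAXED,
) -> list[FusionPairCandidate]:
    """Apply the phase-1 exon-proximity and expression filters.

    An ordered pair is retained iff (i) some supporting read has both
    junction-to-exon-boundary distances ≤ 50 bases, or (ii) the pair has at
    least two distinct supporting reads and some read has one distance ≤ 50
    and the other ≤ 1000 bases; retained pairs must reach ``min_ffpm``.
    """
    if total_reads <= 0:
        raise ValueError(f"total read count must be positive, got {total_reads}")
    kept = []
    for fc in pairs:
        cond_i = any(
            c.dist_5p <= max_dist_strict and c.dist_3p <= max_dist_strict
            for c in fc.candidates
        )
        cond_ii = fc.read_count >= 2 and any(
            min(c.dist_5p, c.dist_3p) <= max_dist_strict
            and max(c.dist_5p, c.dist_3p) <= max_dist_relaxed
            for c in fc.candidates
        )
        if (cond_i or cond_ii) and fc.ffpm >= min_ffpm:
            kept.append(fc)
    return kept


def run_phase1(
    grouped_segments: Mapping[str, Sequence[ReadAlignmentSegment]],
    index: BoundaryIndex,
    total_reads: int,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_anchor: int = DEFAULT_MIN_ANCHOR,
    locus_separation: int = DEFAULT_LOCUS_SEPARATION,
    min_ffpm: float = DEFAULT_MIN_FFPM,
) -> list[FusionPairCandidate]:
    """End-to-end phase 1: detect, assign, aggregate and filter."""
    segment_pairs = detect_chimeric_reads(
        grouped_segments,
        min_identity=min_identity,
        min_anchor=min_anchor,
        locus_separation=locus_separation,
    )
    candidates = []
    for pair in segment_pairs:
        cand = assign_genes(pair, index)
        if cand is not None:
            candidates.append(cand)
    aggregated = aggregate_candidates(candidates, total_reads)
    return phase1_filter(aggregated, total_reads, min_ffpm=min_ffpm)
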