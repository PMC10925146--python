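"""End-to-end orchestration of the two-phase fusion caller.

Phase 1 scans split alignments for chimeric reads and retains gene-pair
candidates passing the exon-proximity and FFPM pre-filters.  Phase 2 builds
a collinear fusion contig per candidate pair, realigns the candidate reads,
snaps alignment ends to exon boundaries, calls fusion-spanning reads, and
tallies per-isoform breakpoints.  Final filters and (optional) short-read
evidence merging produce the report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .annotation import BoundaryIndex, GeneModel, Genome
from .contig import (
    ContigAligner,
    DEFAULT_SNAP_TOLERANCE,
    FusionContig,
    FusionIsoformCall,
    build_fusion_contig,
    call_fusion_reads,
    realign_candidate_reads,
    snap_to_exon_boundaries,
    tally_breakpoints,
)
from .phase1 import (
    DEFAULT_LOCUS_SEPARATION,
    DEFAULT_MIN_ANCHOR,
    DEFAULT_MIN_FFPM,
    DEFAULT_MIN_IDENTITY,
    FusionPairCandidate,
    ReadAlignmentSegment,
    run_phase1,
)
from .report import Blocklist, apply_final_filters

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    min_identity: float = DEFAULT_MIN_IDENTITY
    min_anchor: int = DEFAULT_MIN_ANCHOR
    locus_separation: int = DEFAULT_LOCUS_SEPARATION
    min_ffpm: float = DEFAULT_MIN_FFPM
    snap_tolerance: int = DEFAULT_SNAP_TOLERANCE


@dataclass
class PipelineResult:
    phase1_pairs: list[FusionPairCandidate]
    contigs: dict[str, FusionContig]
    calls: list[FusionIsoformCall]  # after final filters
    unfiltered_calls: list[FusionIsoformCall] = field(default_factory=list)


def detect_fusions(
    grouped_segments: Mapping[str, Sequence[ReadAlignmentSegment]],
    genome: Genome,
    genes: Mapping[str, GeneModel],
    total_reads: int,
    contig_aligner: ContigAligner | None,
    reads: Mapping[str, str] | None = None,
    blocklist: Blocklist | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run phase 1 + phase 2 + final filters.

    ``reads`` maps read id to sequence and is required when the contig
    aligner performs real alignment; with precomputed contig alignments an
    empty-sequence mapping restricted to candidate reads is synthesized.
    """
    cfg = config or PipelineConfig()
    index = BoundaryIndex(genes)
    phase1_pairs = run_phase1(
        grouped_segments,
        index,
        total_reads,
        min_identity=cfg.min_identity,
        min_anchor=cfg.min_anchor,
        locus_separation=cfg.locus_separation,
        min_ffpm=cfg.min_ffpm,
    )

    contigs: dict[str, FusionContig] = {}
    all_calls: list[FusionIsoformCall] = []
    for pair in phase1_pairs:
        gene_a = genes[pair.gene_pair[0]]
        gene_b = genes[pair.gene_pair[1]]
        contig = build_fusion_contig(gene_a, gene_b, genome)
        contigs[contig.name] = contig
        candidate_reads: Mapping[str, str]
        if reads is not None:
            candidate_reads = {
                rid: reads[rid] for rid in sorted(pair.read_ids) if rid in reads
            }
        else:
            candidate_reads = {rid: "" for rid in sorted(pair.read_ids)}
        alignments = realign_candidate_reads(candidate_reads, contig, contig_aligner)
        snapped = [
            snap_to_exon_boundaries(a, contig, cfg.snap_tolerance)
            for a in alignments
        ]
        fusion_reads = call_fusion_reads(snapped, contig, cfg.min_anchor)
        calls = tally_breakpoints(fusion_reads, contig, total_reads, genome)
        all_calls.extend(calls)

    filtered = apply_final_filters(
        all_calls, blocklist=blocklist, min_ffpm=cfg.min_ffpm
    )
    return PipelineResult(
        phase1_pairs=phase1_pairs,
        contigs=contigs,
        calls=filtered,
        unfiltered_calls=all_calls,
    )


def run_on_simulation(
    sim,
    blocklist: Blocklist | None = None,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Run the full pipeline on a simulation via by-construction alignments.

    Genome-space truth PAF feeds phase 1; phase 2 consumes truth contig
    alignments keyed by fusion contig name.  Requires substitution-only
    reads (indels need the external aligner).
    """
    from .phase1 import parse_paf_lines
    from .simulate import emit_truth_contig_alignments, emit_truth_paf
    from .contig import PrecomputedAlignments

    grouped = parse_paf_lines(emit_truth_paf(sim))
    genes_by_symbol = {g.symbol: g for g in sim.genes.values()}
    contigs = {}
    for t in sim.truth:
        c = build_fusion_contig(
            genes_by_symbol[t.gene_a], genes_by_symbol[t.gene_b], sim.genome
        )
        contigs[c.name] = c
    aligner = PrecomputedAlignments(emit_truth_contig_alignments(sim, contigs))
    return detect_fusions(
        grouped,
        sim.genome,
        sim.genes,
        sim.total_reads,
        contig_aligner=aligner,
        blocklist=blocklist,
        config=config,
    )


def calls_to_records(calls, sample: str = "sim", method: str = "lrfusion"):
    """Convert isoform calls to benchmark records (one per isoform)."""
    from .benchmark import FusionRecord

    return [
        FusionRecord(
            sample=sample,
            gene_a=c.gene_pair[0],
            gene_b=c.gene_pair[1],
            breakpoint_a=c.breakpoint_5p,
            breakpoint_b=c.breakpoint_3p,
            reads=c.read_count,
            method=method,
        )
        for c in calls
    ]
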