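"""Fusion contig construction, coordinate maps, snapping, and breakpoint tally."""

from __future__ import annotations

import pytest

from lrfusion import (
    ContigAlignment,
    GeneModel,
    Genome,
    Minimap2Aligner,
    PrecomputedAlignments,
    Transcript,
    build_fusion_contig,
    call_fusion_reads,
    realign_candidate_reads,
    snap_to_exon_boundaries,
    tally_breakpoints,
)
from lrfusion.annotation import reverse_complement
from lrfusion.contig import SPACER_LENGTH


def _random_genome(rng_seed: int, layout: dict[str, int]) -> Genome:
    import numpy as np

    rng = np.random.default_rng(rng_seed)
    bases = np.array(list("ACGT"))
    return Genome(
        {name: "".join(bases[rng.integers(0, 4, size=n)]) for name, n in layout.items()}
    )


@pytest.fixture(scope="module")
def long_intron_setup():
    genome = _random_genome(5, {"c1": 12_000, "c2": 12_000})
    gene_a = GeneModel(
        "GA", "GA", "c1", "+", [Transcript("GA.t", ((100, 600), (8600, 9100)))]
    )
    gene_b = GeneModel(
        "GB", "GB", "c2", "+", [Transcript("GB.t", ((200, 700), (8700, 9200)))]
    )
    return genome, gene_a, gene_b


class TestBuildFusionContig:
    def test_long_introns_shrunk_to_1kb(self, long_intron_setup):
        genome, gene_a, gene_b = long_intron_setup
        contig = build_fusion_contig(gene_a, gene_b, genome)
        # each gene: 500 + 1000 (shrunken 8000-base intron) + 500
        assert contig.region_a.end - contig.region_a.start == 2000
        assert contig.region_b.end - contig.region_b.start == 2000
        assert len(contig.sequence) == 2000 + SPACER_LENGTH + 2000

    def test_short_intron_preserved(self):
        genome = _random_genome(6, {"c1": 2000, "c2": 2000})
        gene_a = GeneModel(
            "GA", "GA", "c1", "+", [Transcript("GA.t", ((100, 300), (600, 800)))]
        )
        gene_b = GeneModel(
            "GB", "GB", "c2", "+", [Transcript("GB.t", ((100, 400),))]
        )
        contig = build_fusion_contig(gene_a, gene_b, genome)
        assert contig.region_a.end - contig.region_a.start == 200 + 300 + 200

    def test_spacer_is_n(self, long_intron_setup):
        genome, gene_a, gene_b = long_intron_setup
        contig = build_fusion_contig(gene_a, gene_b, genome)
        gap = contig.junction_gap
        assert contig.sequence[gap[0] : gap[1]] == "N" * SPACER_LENGTH

    def test_minus_strand_gene_in_sense_orientation(self):
        genome = _random_genome(7, {"c1": 2000, "c2": 2000})
        gene_a = GeneModel(
            "GA", "GA", "c1", "+", [Transcript("GA.t", ((100, 400),))]
        )
        gene_b = GeneModel(
            "GB", "GB", "c2", "-", [Transcript("GB.t", ((100, 300), (600, 900)))]
        )
        contig = build_fusion_contig(gene_a, gene_b, genome)
        # 5'-most exon of the minus-strand mRNA is the genomically last exon.
        exons = contig.exons_in_transcript_order("B")
        assert len(exons) == 2 and exons[0][0] < exons[1][0]
        first_exon_seq = contig.sequence[exons[0][0] : exons[0][1]]
        assert first_exon_seq == reverse_complement(genome.fetch("c2", 600, 900))

    def test_coordinate_map_round_trip(self, long_intron_setup):
        genome, gene_a, gene_b = long_intron_setup
        contig = build_fusion_contig(gene_a, gene_b, genome)
        for region, gene in ((contig.region_a, gene_a), (contig.region_b, gene_b)):
            for cs, ce in region.exons:
                for pos in (cs, (cs + ce) // 2, ce - 1):
                    _, gpos, _ = contig.contig_to_genome(pos)
                    assert contig.genome_to_contig(gene.gene_id, gpos) == pos

    def test_minus_strand_round_trip_maps_to_original_base(self):
        genome = _random_genome(8, {"c1": 2000, "c2": 2000})
        gene_a = GeneModel("GA", "GA", "c1", "+", [Transcript("t", ((100, 400),))])
        gene_b = GeneModel(
            "GB", "GB", "c2", "-", [Transcript("t", ((100, 300), (600, 900)))]
        )
        contig = build_fusion_contig(gene_a, gene_b, genome)
        for cs, ce in contig.exons_in_transcript_order("B"):
            for pos in range(cs, ce):
                gc, gpos, strand = contig.contig_to_genome(pos)
                assert gc == "c2" and strand == "-"
                assert contig.sequence[pos] == reverse_complement(
                    genome.fetch("c2", gpos, gpos + 1)
                )

    def test_overlapping_transcript_exons_merged(self):
        genome = _random_genome(9, {"c1": 2000, "c2": 2000})
        gene_a = GeneModel(
            "GA", "GA", "c1", "+",
            [Transcript("t1", ((100, 300),)), Transcript("t2", ((200, 500),))],
        )
        gene_b = GeneModel("GB", "GB", "c2", "+", [Transcript("t", ((100, 400),))])
        contig = build_fusion_contig(gene_a, gene_b, genome)
        assert contig.region_a.exons == [(0, 400)]


@pytest.fixture(scope="module")
def simple_contig():
    genome = _random_genome(10, {"c1": 3000, "c2": 3000})
    gene_a = GeneModel(
        "GA", "GA", "c1", "+", [Transcript("t", ((100, 400), (700, 1000)))]
    )
    gene_b = GeneModel(
        "GB", "GB", "c2", "+", [Transcript("t", ((200, 500), (800, 1100)))]
    )
    return build_fusion_contig(gene_a, gene_b, genome), genome


class TestSnapping:
    @pytest.mark.parametrize("offset", range(0, 7))
    def test_boundary_sweep(self, simple_contig, offset):
        contig, _ = simple_contig
        exon_end = contig.region_a.exons[0][1]
        aln = ContigAlignment("r", [(0, exon_end - offset, 0, exon_end - offset)])
        snapped = snap_to_exon_boundaries(aln, contig, tolerance=3)
        expected_end = exon_end if offset <= 3 else exon_end - offset
        assert snapped.blocks[0][3] == expected_end
        # read interval adjusted by the same offset
        assert snapped.blocks[0][1] - snapped.blocks[0][0] == (
            snapped.blocks[0][3] - snapped.blocks[0][2]
        )

    def test_end_on_boundary_unchanged(self, simple_contig):
        contig, _ = simple_contig
        exon_end = contig.region_a.exons[0][1]
        aln = ContigAlignment("r", [(0, exon_end, 0, exon_end)])
        assert snap_to_exon_boundaries(aln, contig).blocks == aln.blocks

    def test_idempotent(self, simple_contig):
        contig, _ = simple_contig
        exon_end = contig.region_a.exons[0][1]
        aln = ContigAlignment("r", [(5, exon_end - 2, 5, exon_end - 2)])
        once = snap_to_exon_boundaries(aln, contig)
        twice = snap_to_exon_boundaries(once, contig)
        assert once.blocks == twice.blocks

    def test_inverting_snap_left_unchanged(self, simple_contig):
        contig, _ = simple_contig
        b = contig.region_a.exons[1][0]  # an internal boundary
        aln = ContigAlignment("r", [(0, 2, b - 1, b + 1)])
        snapped = snap_to_exon_boundaries(aln, contig, tolerance=3)
        assert snapped.blocks == [(0, 2, b - 1, b + 1)]

    def test_monotone_in_tolerance(self, simple_contig):
        # Growing tolerance never decreases boundary-coincident block ends.
        contig, _ = simple_contig
        boundaries = set(contig.exon_boundaries())
        exon_end = contig.region_a.exons[0][1]
        alns = [
            ContigAlignment(f"r{d}", [(0, exon_end - d, 0, exon_end - d)])
            for d in range(6)
        ]
        counts = []
        for tol in range(6):
            snapped = [snap_to_exon_boundaries(a, contig, tol) for a in alns]
            counts.append(
                sum(1 for a in snapped if a.blocks[0][3] in boundaries)
            )
        assert counts == sorted(counts)


class TestCallFusionReads:
    def test_spanning_read_breakpoints_at_exon_junctions(self, simple_contig):
        contig, _ = simple_contig
        a_end = contig.region_a.exons[-1][1]
        b_start = contig.region_b.exons[0][0]
        aln = ContigAlignment(
            "r", [(0, a_end, 0, a_end), (a_end, a_end + 300, b_start, b_start + 300)]
        )
        calls = call_fusion_reads([aln], contig)
        assert len(calls) == 1
        fr = calls[0]
        # last genomic base of gene A exon 2 is 1-based 1000; the first base
        # of gene B's first exon (genomic start 200) is 1-based 201
        assert fr.breakpoint_5p.position == 1000
        assert fr.breakpoint_3p.position == 201

    def test_read_within_one_gene_not_fusion(self, simple_contig):
        contig, _ = simple_contig
        aln = ContigAlignment("r", [(0, 200, 0, 200)])
        assert call_fusion_reads([aln], contig) == []

    def test_short_anchor_rejected(self, simple_contig):
        contig, _ = simple_contig
        a_end = contig.region_a.exons[-1][1]
        b_start = contig.region_b.exons[0][0]
        aln = ContigAlignment(
            "r",
            [(0, a_end, 0, a_end), (a_end, a_end + 10, b_start, b_start + 10)],
        )
        assert call_fusion_reads([aln], contig) == []
        assert len(call_fusion_reads([aln], contig, min_anchor=5)) == 1

    def test_identical_junctions_same_breakpoint_pair(self, simple_contig):
        contig, _ = simple_contig
        a_end = contig.region_a.exons[-1][1]
        b_start = contig.region_b.exons[0][0]
        alns = [
            ContigAlignment(
                f"r{i}",
                [(0, a_end, 0, a_end), (a_end, a_end + 300, b_start, b_start + 300)],
            )
            for i in range(2)
        ]
        calls = call_fusion_reads(alns, contig)
        assert calls[0].breakpoint_5p == calls[1].breakpoint_5p
        assert calls[0].breakpoint_3p == calls[1].breakpoint_3p


class TestTally:
    def test_grouping_counts_and_ffpm(self, simple_contig):
        contig, genome = simple_contig
        a_end = contig.region_a.exons[-1][1]
        a_mid = contig.region_a.exons[0][1]
        b_start = contig.region_b.exons[0][0]
        j1 = [
            ContigAlignment(
                f"a{i}",
                [(0, a_end, 0, a_end), (a_end, a_end + 300, b_start, b_start + 300)],
            )
            for i in range(5)
        ]
        j2 = [
            ContigAlignment(
                f"b{i}",
                [(0, a_mid, 0, a_mid), (a_mid, a_mid + 300, b_start, b_start + 300)],
            )
            for i in range(2)
        ]
        fusion_reads = call_fusion_reads(j1 + j2, contig)
        calls = tally_breakpoints(fusion_reads, contig, 1_000_000, genome)
        assert [c.read_count for c in calls] == [5, 2]
        assert [c.ffpm for c in calls] == [pytest.approx(5.0), pytest.approx(2.0)]
        # conservation: per-isoform counts sum to distinct fusion reads
        assert sum(c.read_count for c in calls) == len(
            {fr.read_id for fr in fusion_reads}
        )


class TestRealign:
    def test_precomputed_passthrough(self, simple_contig):
        contig, _ = simple_contig
        aln = ContigAlignment("r1", [(0, 100, 0, 100)])
        aligner = PrecomputedAlignments({contig.name: [aln]})
        out = realign_candidate_reads({"r1": ""}, contig, aligner)
        assert out == [aln]

    def test_precomputed_restricted_to_candidate_reads(self, simple_contig):
        contig, _ = simple_contig
        alns = [
            ContigAlignment("r1", [(0, 100, 0, 100)]),
            ContigAlignment("r2", [(0, 100, 0, 100)]),
        ]
        aligner = PrecomputedAlignments({contig.name: alns})
        out = realign_candidate_reads({"r2": ""}, contig, aligner)
        assert [a.read_id for a in out] == ["r2"]

    def test_missing_aligner_errors_with_instructions(self, simple_contig):
        contig, _ = simple_contig
        with pytest.raises(ValueError, match="aligner"):
            realign_candidate_reads({}, contig, None)

    def test_minimap2_recovers_exact_blocks_for_error_free_reads(
        self, simple_contig
    ):
        contig, _ = simple_contig
        # Ten error-free reads spliced across the junction: exons 1-2 of A
        # followed by exons 1-2 of B, read directly off the contig sequence.
        ae = contig.region_a.exons
        be = contig.region_b.exons
        seq = "".join(contig.sequence[s:e] for s, e in ae + be)
        reads = {f"r{i}": seq for i in range(10)}
        alns = realign_candidate_reads(reads, contig, Minimap2Aligner())
        assert len(alns) == 10
        snapped = [snap_to_exon_boundaries(a, contig) for a in alns]
        expected_blocks = [(s, e) for s, e in ae + be]
        for aln in snapped:
            assert [(cs, ce) for _, _, cs, ce in aln.blocks] == expected_blocks
        fusion_reads = call_fusion_reads(snapped, contig)
        assert len(fusion_reads) == 10
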