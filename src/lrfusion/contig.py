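"""Phase 2: fusion contig modeling, realignment, snapping and tallying.

Each phase-1 candidate pair is modeled as a collinear two-gene contig: both
genes placed in transcriptional sense orientation, 5' gene first, with
introns longer than 1 kb shrunken to 1 kb (their flanking 500-base halves
are retained, preserving splice-site sequence context).  A 20-base run of
``N`` separates the two gene regions so a contiguous alignment block cannot
read through the synthetic junction.

Candidate reads are realigned to the contig — either by an external
minimap2 invocation or from precomputed/by-construction alignments — their
block ends are snapped to exon boundaries within a 3-base tolerance, reads
spanning both gene regions are called as fusion reads, and breakpoints are
tallied per exact junction pair with FFPM support and splice-dinucleotide
status.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from bisect import bisect_left
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Protocol, Sequence

from .annotation import (
    Breakpoint,
    GeneModel,
    Genome,
    reverse_complement,
    splice_dinucleotides,
)
from .phase1 import DEFAULT_MIN_ANCHOR, compute_ffpm

logger = logging.getLogger(__name__)

MAX_INTRON_LENGTH = 1000  # longer introns are shrunken to this length
SPACER_LENGTH = 20  # Ns between the two gene regions
DEFAULT_SNAP_TOLERANCE = 3  # bases


# ---------------------------------------------------------------------------
# Coordinate-mapped fusion contig
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _MapBlock:
    """One collinear piece of the contig↔genome coordinate map."""

    contig_start: int
    length: int
    genome_contig: str
    genome_start: int  # 0-based start of the genomic interval
    strand: str  # orientation of the gene region on the genome

    def contig_to_genome(self, pos: int) -> int:
        off = pos - self.contig_start
        if self.strand == "+":
            return self.genome_start + off
        return self.genome_start + self.length - 1 - off

    def genome_to_contig(self, gpos: int) -> int:
        off = gpos - self.genome_start
        if self.strand == "+":
            return self.contig_start + off
        return self.contig_start + self.length - 1 - off


@dataclass
class _GeneRegion:
    gene: GeneModel
    start: int  # contig interval of this gene's region
    end: int
    blocks: list[_MapBlock]
    exons: list[tuple[int, int]]  # merged exons in contig coordinates, 5'→3'


class FusionContig:
    """A synthetic collinear two-gene reference with a coordinate map."""

    def __init__(
        self,
        gene_a: GeneModel,
        gene_b: GeneModel,
        sequence: str,
        region_a: _GeneRegion,
        region_b: _GeneRegion,
    ):
        self.gene_a = gene_a
        self.gene_b = gene_b
        self.sequence = sequence
        self.region_a = region_a
        self.region_b = region_b

    @property
    def name(self) -> str:
        return f"{self.gene_a.symbol}--{self.gene_b.symbol}"

    @property
    def junction_gap(self) -> tuple[int, int]:
        """Contig interval of the N spacer separating the gene regions."""
        return self.region_a.end, self.region_b.start

    def region_of(self, pos: int) -> str | None:
        if self.region_a.start <= pos < self.region_a.end:
            return "A"
        if self.region_b.start <= pos < self.region_b.end:
            return "B"
        return None

    def exon_boundaries(self) -> list[int]:
        """Sorted contig coordinates of exon starts/ends of both genes."""
        coords: set[int] = set()
        for region in (self.region_a, self.region_b):
            for s, e in region.exons:
                coords.add(s)
                coords.add(e)
        return sorted(coords)

    def contig_to_genome(self, pos: int) -> tuple[str, int, str]:
        """Map a contig position to (genome contig, 0-based position, strand)."""
        for region in (self.region_a, self.region_b):
            for blk in region.blocks:
                if blk.contig_start <= pos < blk.contig_start + blk.length:
                    return (
                        blk.genome_contig,
                        blk.contig_to_genome(pos),
                        region.gene.strand,
                    )
        raise ValueError(f"contig position {pos} not on a mapped gene block")

    def genome_to_contig(self, gene_id: str, gpos: int) -> int:
        region = self.region_a if gene_id == self.gene_a.gene_id else self.region_b
        for blk in region.blocks:
            if blk.genome_start <= gpos < blk.genome_start + blk.length:
                return blk.genome_to_contig(gpos)
        raise ValueError(f"genomic position {gpos} of {gene_id} not on the contig")

    def exons_in_transcript_order(self, which: str) -> list[tuple[int, int]]:
        region = self.region_a if which == "A" else self.region_b
        return list(region.exons)

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f">{self.name}\n")
            for i in range(0, len(self.sequence), 60):
                fh.write(self.sequence[i : i + 60] + "\n")

    def to_gtf(self, path: str | Path) -> None:
        """Write the contig-space exon annotation of both genes."""
        with open(path, "w") as fh:
            for which, region in (("A", self.region_a), ("B", self.region_b)):
                gene = region.gene
                for s, e in region.exons:
                    attrs = (
                        f'gene_id "{gene.gene_id}"; '
                        f'transcript_id "{gene.gene_id}.contig"; '
                        f'gene_name "{gene.symbol}";'
                    )
                    fh.write(
                        "\t".join(
                            [self.name, "lrfusion", "exon", str(s + 1), str(e),
                             ".", "+", ".", attrs]
                        )
                        + "\n"
                    )


def build_fusion_contig(
    gene_a: GeneModel,
    gene_b: GeneModel,
    genome: Genome,
    max_intron: int = MAX_INTRON_LENGTH,
    spacer: int = SPACER_LENGTH,
) -> FusionContig:
    """Build the collinear two-gene contig with shrunken introns.

    Gene regions are extracted in sense orientation (minus-strand genes are
    reverse-complemented); introns longer than ``max_intron`` are replaced by
    their first and last ``max_intron/2`` bases.  The coordinate map is
    invertible on every retained base.
    """
    seq_a, region_a = _build_gene_region(gene_a, genome, 0, max_intron)
    offset_b = len(seq_a) + spacer
    seq_b, region_b = _build_gene_region(gene_b, genome, offset_b, max_intron)
    sequence = seq_a + "N" * spacer + seq_b
    return FusionContig(gene_a, gene_b, sequence, region_a, region_b)


def _build_gene_region(
    gene: GeneModel, genome: Genome, offset: int, max_intron: int
) -> tuple[str, _GeneRegion]:
    exons = gene.merged_exons()
    half = max_intron // 2
    # Genomic pieces retained on the contig, in genomic order.
    pieces: list[tuple[int, int]] = [exons[0]]
    for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
        intron_len = s2 - e1
        if intron_len > max_intron:
            pieces.append((e1, e1 + half))
            pieces.append((s2 - half, s2))
        elif intron_len > 0:
            pieces.append((e1, s2))
        pieces.append((s2, e2))

    if gene.strand == "-":
        pieces = pieces[::-1]

    blocks: list[_MapBlock] = []
    parts: list[str] = []
    pos = offset
    for gs, ge in pieces:
        piece = genome.fetch(gene.contig, gs, ge)
        if gene.strand == "-":
            piece = reverse_complement(piece)
        blocks.append(
            _MapBlock(
                contig_start=pos,
                length=ge - gs,
                genome_contig=gene.contig,
                genome_start=gs,
                strand=gene.strand,
            )
        )
        parts.append(piece)
        pos += ge - gs

    seq = "".join(parts)
    region = _GeneRegion(
        gene=gene,
        start=offset,
        end=offset + len(seq),
        blocks=blocks,
        exons=[],
    )
    # Merged exons mapped to contig coordinates, in transcript (5'→3') order.
    contig_exons = []
    ordered = exons if gene.strand == "+" else exons[::-1]
    for gs, ge in ordered:
        c1 = _map_genomic(blocks, gs)
        c2 = _map_genomic(blocks, ge - 1)
        lo, hi = min(c1, c2), max(c1, c2)
        contig_exons.append((lo, hi + 1))
    region.exons = contig_exons
    return seq, region


def _map_genomic(blocks: Sequence[_MapBlock], gpos: int) -> int:
    for blk in blocks:
        if blk.genome_start <= gpos < blk.genome_start + blk.length:
            return blk.genome_to_contig(gpos)
    raise ValueError(f"genomic position {gpos} not retained on the contig")


# ---------------------------------------------------------------------------
# Realignment
# ---------------------------------------------------------------------------


@dataclass
class ContigAlignment:
    """A read's alignment to a fusion contig as sorted, disjoint blocks."""

    read_id: str
    blocks: list[tuple[int, int, int, int]]  # (read_start, read_end, c_start, c_end)
    strand: str = "+"
    score: float | None = None

    def __post_init__(self):
        self.blocks = sorted(self.blocks, key=lambda b: b[2])
        for (_, _, _, e1), (_, _, s2, _) in zip(self.blocks, self.blocks[1:]):
            if s2 < e1:
                raise ValueError(f"{self.read_id}: overlapping contig blocks")


class ContigAligner(Protocol):
    def align(
        self, reads: Mapping[str, str], contig: FusionContig
    ) -> list[ContigAlignment]: ...


class PrecomputedAlignments:
    """Aligner interface backed by alignments keyed by contig name."""

    def __init__(self, by_contig: Mapping[str, Sequence[ContigAlignment]]):
        self._by_contig = {k: list(v) for k, v in by_contig.items()}

    def align(
        self, reads: Mapping[str, str], contig: FusionContig
    ) -> list[ContigAlignment]:
        return [a for a in self._by_contig.get(contig.name, []) if a.read_id in reads]


class Minimap2Aligner:
    """External spliced alignment of candidate reads to a fusion contig."""

    def __init__(self, executable: str = "minimap2", preset: str = "splice"):
        self.executable = executable
        self.preset = preset

    def align(
        self, reads: Mapping[str, str], contig: FusionContig
    ) -> list[ContigAlignment]:
        if shutil.which(self.executable) is None:
            raise RuntimeError(
                f"external aligner {self.executable!r} not found on PATH; "
                "supply precomputed contig alignments (PrecomputedAlignments) "
                "or install minimap2"
            )
        with tempfile.TemporaryDirectory() as tmp:
            ref = Path(tmp) / "contig.fa"
            qry = Path(tmp) / "reads.fa"
            contig.to_fasta(ref)
            with open(qry, "w") as fh:
                for rid, seq in reads.items():
                    fh.write(f">{rid}\n{seq}\n")
            proc = subprocess.run(
                [self.executable, "-cx", self.preset, "--secondary=no",
                 str(ref), str(qry)],
                capture_output=True,
                text=True,
                check=True,
            )
        return _paf_to_contig_alignments(proc.stdout, contig.name)


def _paf_to_contig_alignments(paf_text: str, contig_name: str) -> list[ContigAlignment]:
    out = []
    for line in paf_text.splitlines():
        if not line.strip():
            continue
        f = line.split("\t")
        if f[5] != contig_name:
            continue
        cg = next((t[5:] for t in f[12:] if t.startswith("cg:Z:")), None)
        strand = f[4]
        qstart, qend = int(f[2]), int(f[3])
        tstart = int(f[7])
        if cg is None:
            out.append(
                ContigAlignment(f[0], [(qstart, qend, tstart, int(f[8]))], strand)
            )
            continue
        blocks = []
        qpos, tpos = qstart, tstart
        bq, bt = qpos, tpos
        import re

        for num, op in re.findall(r"(\d+)([MIDNSH=X])", cg):
            n = int(num)
            if op in "M=X":
                qpos += n
                tpos += n
            elif op == "I":
                qpos += n
            elif op == "D":
                # large deletions (e.g. spanning the N spacer) break blocks
                if n >= 10 and tpos > bt:
                    blocks.append((bq, qpos, bt, tpos))
                    tpos += n
                    bq, bt = qpos, tpos
                else:
                    tpos += n
            elif op == "N":  # intron: close the current block
                if tpos > bt:
                    blocks.append((bq, qpos, bt, tpos))
                tpos += n
                bq, bt = qpos, tpos
        if tpos > bt:
            blocks.append((bq, qpos, bt, tpos))
        out.append(ContigAlignment(f[0], blocks, strand))
    return out


def realign_candidate_reads(
    reads: Mapping[str, str],
    contig: FusionContig,
    aligner: ContigAligner | None,
) -> list[ContigAlignment]:
    """Realign candidate fusion reads to the fusion contig.

    ``aligner`` is either an external invocation (:class:`Minimap2Aligner`)
    or precomputed alignments (:class:`PrecomputedAlignments`); reads that do
    not align to this contig are dropped.
    """
    if aligner is None:
        raise ValueError(
            "no aligner interface supplied: provide Minimap2Aligner() for "
            "external realignment or PrecomputedAlignments({contig_name: "
            "alignments}) for precomputed input"
        )
    return [a for a in aligner.align(reads, contig) if a.blocks]


# ---------------------------------------------------------------------------
# Snapping and fusion-read calling
# ---------------------------------------------------------------------------


def snap_to_exon_boundaries(
    alignment: ContigAlignment,
    contig: FusionContig,
    tolerance: int = DEFAULT_SNAP_TOLERANCE,
) -> ContigAlignment:
    """Snap block ends within ``tolerance`` bases of an exon boundary onto it.

    Read intervals are adjusted by the same offset so block lengths stay
    consistent; a snap that would invert a block leaves it unchanged (logged).
    Idempotent: a snapped end is at distance zero from its boundary.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    boundaries = contig.exon_boundaries()
    new_blocks = []
    for rs, re_, cs, ce in alignment.blocks:
        ns = _nearest(boundaries, cs, tolerance)
        ne = _nearest(boundaries, ce, tolerance)
        ds, de = ns - cs, ne - ce
        if ne - ns <= 0:
            logger.debug(
                "%s: snapping block [%d,%d) would invert it; left unchanged",
                alignment.read_id, cs, ce,
            )
            new_blocks.append((rs, re_, cs, ce))
            continue
        if alignment.strand == "+":
            new_blocks.append((rs + ds, re_ + de, ns, ne))
        else:
            # On a reverse-strand alignment the read runs against the contig:
            # moving the block start trims/extends the read end and vice versa.
            new_blocks.append((rs - de, re_ - ds, ns, ne))
    return replace(alignment, blocks=new_blocks)


def _nearest(boundaries: Sequence[int], pos: int, tolerance: int) -> int:
    i = bisect_left(boundaries, pos)
    best, best_d = pos, tolerance + 1
    for j in (i - 1, i):
        if 0 <= j < len(boundaries):
            d = abs(boundaries[j] - pos)
            if d < best_d or (d == best_d and boundaries[j] < best):
                best, best_d = boundaries[j], d
    return best if best_d <= tolerance else pos


@dataclass
class FusionRead:
    """A read whose alignment spans both genes, with its junction pair."""

    read_id: str
    breakpoint_5p: Breakpoint
    breakpoint_3p: Breakpoint
    contig_break_a: int  # last covered contig base in gene A region
    contig_break_b: int  # first covered contig base in gene B region


def call_fusion_reads(
    alignments: Iterable[ContigAlignment],
    contig: FusionContig,
    min_anchor: int = DEFAULT_MIN_ANCHOR,
) -> list[FusionRead]:
    """Identify reads whose (snapped) alignments bridge both gene regions.

    A read supports the fusion iff its blocks cover at least ``min_anchor``
    aligned bases in each gene region.  Its breakpoint pair is the last
    covered contig base in gene A and the first covered contig base in gene
    B, translated back to 1-based genome coordinates with the gene strand.
    """
    calls = []
    for aln in alignments:
        cov_a = cov_b = 0
        last_a = first_b = None
        for _, _, cs, ce in aln.blocks:
            a_lo, a_hi = max(cs, contig.region_a.start), min(ce, contig.region_a.end)
            if a_hi > a_lo:
                cov_a += a_hi - a_lo
                last_a = a_hi - 1 if last_a is None else max(last_a, a_hi - 1)
            b_lo, b_hi = max(cs, contig.region_b.start), min(ce, contig.region_b.end)
            if b_hi > b_lo:
                cov_b += b_hi - b_lo
                first_b = b_lo if first_b is None else min(first_b, b_lo)
        if cov_a < min_anchor or cov_b < min_anchor:
            continue
        assert last_a is not None and first_b is not None
        gc_a, gp_a, st_a = contig.contig_to_genome(last_a)
        gc_b, gp_b, st_b = contig.contig_to_genome(first_b)
        calls.append(
            FusionRead(
                read_id=aln.read_id,
                breakpoint_5p=Breakpoint(gc_a, gp_a + 1, st_a),
                breakpoint_3p=Breakpoint(gc_b, gp_b + 1, st_b),
                contig_break_a=last_a,
                contig_break_b=first_b,
            )
        )
    return calls


# ---------------------------------------------------------------------------
# Breakpoint tally
# ---------------------------------------------------------------------------


@dataclass
class FusionIsoformCall:
    """One fusion splicing isoform: gene pair, breakpoint pair, support."""

    gene_pair: tuple[str, str]  # symbols, 5' gene first
    breakpoint_5p: Breakpoint
    breakpoint_3p: Breakpoint
    read_ids: tuple[str, ...]
    ffpm: float
    splice_donor: str = ""
    splice_acceptor: str = ""
    consensus_splice: bool = False
    short_read_count: int = 0
    short_read_ffpm: float = 0.0
    annotations: str = ""

    @property
    def read_count(self) -> int:
        return len(set(self.read_ids))

    @property
    def name(self) -> str:
        return f"{self.gene_pair[0]}--{self.gene_pair[1]}"


def tally_breakpoints(
    fusion_reads: Iterable[FusionRead],
    contig: FusionContig,
    total_reads: int,
    genome: Genome | None = None,
) -> list[FusionIsoformCall]:
    """Group fusion reads by exact breakpoint pair into isoform calls.

    Near-identical junctions are deliberately not merged here; tolerance is
    the benchmark's fuzzy mode's concern.  When ``genome`` is supplied the
    splice dinucleotides flanking each junction are recorded.
    """
    groups: dict[tuple[Breakpoint, Breakpoint], list[str]] = {}
    for fr in fusion_reads:
        groups.setdefault((fr.breakpoint_5p, fr.breakpoint_3p), []).append(fr.read_id)
    calls = []
    pair = (contig.gene_a.symbol, contig.gene_b.symbol)
    for (bp5, bp3), read_ids in sorted(groups.items()):
        donor = acceptor = ""
        consensus = False
        if genome is not None:
            try:
                donor, acceptor, consensus = splice_dinucleotides(genome, bp5, bp3)
            except ValueError:
                logger.debug("%s: breakpoint too close to contig end", pair)
        distinct = sorted(set(read_ids))
        calls.append(
            FusionIsoformCall(
                gene_pair=pair,
                breakpoint_5p=bp5,
                breakpoint_3p=bp3,
                read_ids=tuple(distinct),
                ffpm=compute_ffpm(len(distinct), total_reads),
                splice_donor=donor,
                splice_acceptor=acceptor,
                consensus_splice=consensus,
            )
        )
    calls.sort(key=lambda c: (-c.read_count, c.breakpoint_5p, c.breakpoint_3p))
    return calls
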