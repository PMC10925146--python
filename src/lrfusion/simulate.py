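"""Synthetic toy genomes, fusion transcripts, reads and truth alignments.

This generator makes every stage of the fusion caller testable without an
external aligner or any downloaded reference:

* a toy multi-gene genome with exon/intron structure on both strands
  (introns carry GT..AG flanks so exon-junction fusion breakpoints present
  consensus splice dinucleotides, as in real genes),
* fusion transcripts joining a 5' transcript prefix to a 3' transcript
  suffix at exon junctions, with a genomic-breakpoint truth table,
* long reads with configurable substitution/indel error, an antisense
  fraction (second-strand cDNA), and an optional 3'-anchored fragmenting
  mode emulating 3'-capture single-cell coverage bias,
* by-construction ("truth") alignments: genome-space PAF for the phase-1
  scan and fusion-contig-space alignments for phase 2.

Everything is deterministic for a fixed seed.  By default every gene sits
on its own contig: the phase-1 scan treats same-contig loci closer than
100 kb as a single locus, so co-located partners belong in dedicated
neighbor-filter fixtures rather than the default conditions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .annotation import (
    Breakpoint,
    GeneModel,
    Genome,
    Transcript,
    reverse_complement,
    write_annotation,
)
from .contig import ContigAlignment, FusionContig

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study conditions for the synthetic data generator."""

    seed: int = 0
    gene_count: int = 10
    exons_per_gene: tuple[int, int] = (3, 6)
    exon_length: tuple[int, int] = (80, 300)
    intron_length: tuple[int, int] = (200, 3000)
    intergenic_flank: int = 500
    fusion_count: int = 3
    reads_per_transcript: tuple[int, int] = (3, 8)
    substitution_rate: float = 0.0
    insertion_rate: float = 0.0
    deletion_rate: float = 0.0
    antisense_fraction: float = 0.5
    three_prime_fraction: float = 0.0  # fraction of reads fragmented from the 3' end
    min_fragment_length: int = 150

    def __post_init__(self):
        for name in ("substitution_rate", "insertion_rate", "deletion_rate"):
            r = getattr(self, name)
            if not (0.0 <= r < 1.0):
                raise ValueError(f"{name} must be in [0, 1), got {r}")
        for name in ("exon_length", "intron_length", "exons_per_gene",
                     "reads_per_transcript"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"infeasible range for {name}: ({lo}, {hi})")
        if not (0.0 <= self.antisense_fraction <= 1.0):
            raise ValueError("antisense_fraction must be in [0, 1]")


@dataclass
class TruthRecord:
    """Ground truth for one simulated fusion transcript."""

    fusion_name: str  # "SYMA--SYMB", ordered 5'->3'
    gene_a: str  # symbols
    gene_b: str
    breakpoint_a: Breakpoint
    breakpoint_b: Breakpoint
    transcript_a: str
    transcript_b: str
    n_exons_a: int  # exons of transcript A in the fusion (prefix length)
    first_exon_b: int  # 0-based index of the first retained exon of B
    sequence: str = ""
    read_ids: list[str] = field(default_factory=list)

    @property
    def breakpoint_distance_to_3p_end(self) -> int:
        """Spliced distance from the junction to the transcript 3' end."""
        return len(self.sequence) - self.sequence_break

    sequence_break: int = 0  # junction offset within the fusion sequence


@dataclass
class SimulatedRead:
    """One simulated read plus the provenance needed for truth alignments."""

    read_id: str
    sequence: str
    source: str  # fusion name or gene symbol
    is_fusion: bool
    antisense: bool
    fragment_start: int  # transcript-coordinate interval covered
    fragment_end: int
    substitutions: tuple[int, ...] = ()  # transcript coordinates of substituted bases
    has_indels: bool = False


@dataclass
class Simulation:
    """Bundle of one simulated study: genome, annotation, reads, truth."""

    config: SimConfig
    genome: Genome
    genes: dict[str, GeneModel]
    truth: list[TruthRecord]
    reads: list[SimulatedRead]
    gene_transcripts: dict[str, str] = field(default_factory=dict)  # spliced seqs

    @property
    def total_reads(self) -> int:
        return len(self.reads)

    def truth_by_read(self) -> dict[str, TruthRecord]:
        by_name = {t.fusion_name: t for t in self.truth}
        return {
            r.read_id: by_name[r.source] for r in self.reads if r.is_fusion
        }

    def truth_records(self, sample: str = "sim"):
        """Truth set in the benchmark module's record dialect."""
        from .benchmark import FusionRecord

        return [
            FusionRecord(
                sample=sample,
                gene_a=t.gene_a,
                gene_b=t.gene_b,
                breakpoint_a=t.breakpoint_a,
                breakpoint_b=t.breakpoint_b,
                reads=len(t.read_ids),
                method="truth",
            )
            for t in self.truth
        ]

    def write_truth_table(self, path: str | Path, sample: str = "sim") -> None:
        """Write the benchmark-dialect truth TSV."""
        lines = ["sample\tgeneA\tgeneB\tbreakpointA\tbreakpointB\treads\tmethod"]
        for t in self.truth:
            lines.append(
                "\t".join(
                    [
                        sample,
                        t.gene_a,
                        t.gene_b,
                        str(t.breakpoint_a),
                        str(t.breakpoint_b),
                        str(len(t.read_ids)),
                        "truth",
                    ]
                )
            )
        Path(path).write_text("".join(l + "\n" for l in lines))

    def write_reads_fastq(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for r in self.reads:
                fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")

    def write_genome(self, fasta_path: str | Path, gtf_path: str | Path) -> None:
        self.genome.to_fasta(fasta_path)
        write_annotation(
            sorted(self.genes.values(), key=lambda g: g.gene_id), gtf_path
        )


# ---------------------------------------------------------------------------
# Toy genome
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def make_toy_genome(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[Genome, dict[str, GeneModel]]:
    """Generate a toy genome and annotation, one gene per contig.

    Gene structure is drawn in sense orientation — random exons separated by
    introns whose first two bases are GT and last two AG — then placed on
    the forward strand directly (+ genes) or reverse-complemented (− genes).
    Strands alternate so both are always represented.  Deterministic for a
    fixed config seed.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    sequences: dict[str, str] = {}
    genes: dict[str, GeneModel] = {}
    for i in range(config.gene_count):
        symbol = f"GENE{i:02d}"
        gene_id = f"SIM{i:04d}"
        contig = f"chr{i + 1}"
        strand = "+" if i % 2 == 0 else "-"
        n_exons = int(rng.integers(config.exons_per_gene[0],
                                   config.exons_per_gene[1] + 1))
        exon_lens = rng.integers(
            config.exon_length[0], config.exon_length[1] + 1, size=n_exons
        )
        intron_lens = rng.integers(
            max(config.intron_length[0], 4), config.intron_length[1] + 1,
            size=n_exons - 1,
        )
        # Sense-orientation gene sequence with GT..AG intron flanks.
        parts = []
        sense_exons: list[tuple[int, int]] = []  # sense-region coordinates
        pos = 0
        for j in range(n_exons):
            exon_seq = _random_seq(rng, int(exon_lens[j]))
            parts.append(exon_seq)
            sense_exons.append((pos, pos + len(exon_seq)))
            pos += len(exon_seq)
            if j < n_exons - 1:
                ilen = int(intron_lens[j])
                intron = "GT" + _random_seq(rng, ilen - 4) + "AG"
                parts.append(intron)
                pos += ilen
        sense_region = "".join(parts)

        flank5 = _random_seq(rng, config.intergenic_flank)
        flank3 = _random_seq(rng, config.intergenic_flank)
        if strand == "+":
            contig_seq = flank5 + sense_region + flank3
            offset = len(flank5)
            genomic_exons = [(offset + s, offset + e) for s, e in sense_exons]
        else:
            contig_seq = flank5 + reverse_complement(sense_region) + flank3
            offset = len(flank5)
            L = len(sense_region)
            genomic_exons = sorted(
                (offset + L - e, offset + L - s) for s, e in sense_exons
            )
        sequences[contig] = contig_seq
        genes[gene_id] = GeneModel(
            gene_id=gene_id,
            symbol=symbol,
            contig=contig,
            strand=strand,
            transcripts=[Transcript(f"{gene_id}.t1", tuple(genomic_exons))],
        )
    return Genome(sequences), genes


# ---------------------------------------------------------------------------
# Transcript splicing helpers
# ---------------------------------------------------------------------------


def spliced_sequence(gene: GeneModel, genome: Genome,
                     transcript: Transcript | None = None) -> str:
    """Spliced (sense-orientation) transcript sequence."""
    tx = transcript or gene.transcripts[0]
    parts = [genome.fetch(gene.contig, s, e) for s, e in tx.exons]
    seq = "".join(parts)
    return seq if gene.strand == "+" else reverse_complement(seq)


def _exons_in_transcript_order(gene: GeneModel,
                               tx: Transcript) -> list[tuple[int, int]]:
    return list(tx.exons) if gene.strand == "+" else list(tx.exons)[::-1]


def _exon_sense_seq(gene: GeneModel, genome: Genome, exon: tuple[int, int]) -> str:
    seq = genome.fetch(gene.contig, exon[0], exon[1])
    return seq if gene.strand == "+" else reverse_complement(seq)


# ---------------------------------------------------------------------------
# Fusion transcripts
# ---------------------------------------------------------------------------


def make_fusion_transcripts(
    genome: Genome,
    genes: Mapping[str, GeneModel],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[TruthRecord]:
    """Join 5' transcript prefixes to 3' transcript suffixes at exon junctions.

    Each fusion takes exons 1..k (k < n) of a donor transcript and exons
    j..n (j ≥ 2) of an acceptor transcript; the sequence is exactly the
    concatenation of the corresponding spliced exon sequences.  Breakpoints
    are recorded as 1-based genomic coordinates: the last transcribed base
    of donor exon k and the first transcribed base of acceptor exon j.
    Genes with a single exon cannot host an internal junction; draws are
    retried a bounded number of times.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    eligible = [g for g in genes.values() if len(g.transcripts[0].exons) >= 2]
    if len(eligible) < 2:
        raise ValueError("need at least two multi-exon genes to build fusions")
    truth: list[TruthRecord] = []
    used_pairs: set[tuple[str, str]] = set()
    max_tries = 50 * config.fusion_count + 100
    tries = 0
    while len(truth) < config.fusion_count:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not draw {config.fusion_count} distinct fusion pairs"
            )
        ia, ib = rng.choice(len(eligible), size=2, replace=False)
        gene_a, gene_b = eligible[int(ia)], eligible[int(ib)]
        if (gene_a.gene_id, gene_b.gene_id) in used_pairs:
            continue
        used_pairs.add((gene_a.gene_id, gene_b.gene_id))
        tx_a, tx_b = gene_a.transcripts[0], gene_b.transcripts[0]
        ex_a = _exons_in_transcript_order(gene_a, tx_a)
        ex_b = _exons_in_transcript_order(gene_b, tx_b)
        k = int(rng.integers(1, len(ex_a)))  # keep exons [0, k) of A
        j = int(rng.integers(1, len(ex_b)))  # keep exons [j, n) of B

        seq_a = "".join(_exon_sense_seq(gene_a, genome, e) for e in ex_a[:k])
        seq_b = "".join(_exon_sense_seq(gene_b, genome, e) for e in ex_b[j:])

        last_exon_a = ex_a[k - 1]
        first_exon_b = ex_b[j]
        # 1-based genomic coordinate of the junction-adjacent base.
        bp_a = (
            last_exon_a[1]
            if gene_a.strand == "+"
            else last_exon_a[0] + 1
        )
        bp_b = (
            first_exon_b[0] + 1
            if gene_b.strand == "+"
            else first_exon_b[1]
        )
        rec = TruthRecord(
            fusion_name=f"{gene_a.symbol}--{gene_b.symbol}",
            gene_a=gene_a.symbol,
            gene_b=gene_b.symbol,
            breakpoint_a=Breakpoint(gene_a.contig, bp_a, gene_a.strand),
            breakpoint_b=Breakpoint(gene_b.contig, bp_b, gene_b.strand),
            transcript_a=tx_a.transcript_id,
            transcript_b=tx_b.transcript_id,
            n_exons_a=k,
            first_exon_b=j,
            sequence=seq_a + seq_b,
            sequence_break=len(seq_a),
        )
        truth.append(rec)
    return truth


def write_fusion_fasta(truth: Sequence[TruthRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for t in truth:
            fh.write(f">{t.fusion_name}\n{t.sequence}\n")


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


def _apply_errors(
    seq: str, config: SimConfig, rng: np.random.Generator, frag_start: int
) -> tuple[str, tuple[int, ...], bool]:
    """i.i.d. per-base substitutions and indels; returns transcript-space subs."""
    subs: list[int] = []
    has_indel = False
    if config.substitution_rate > 0:
        arr = np.frombuffer(seq.encode(), dtype="S1").astype("U1")
        hits = np.flatnonzero(rng.random(len(arr)) < config.substitution_rate)
        for i in hits:
            orig = arr[i]
            choices = [b for b in "ACGT" if b != orig]
            arr[i] = choices[int(rng.integers(0, 3))]
        subs = [frag_start + int(i) for i in hits]
        seq = "".join(arr)
    if config.insertion_rate > 0 or config.deletion_rate > 0:
        out = []
        for ch in seq:
            r = rng.random()
            if r < config.deletion_rate:
                has_indel = True
                continue
            out.append(ch)
            if r < config.deletion_rate + config.insertion_rate:
                has_indel = True
                out.append(str(_BASES[rng.integers(0, 4)]))
        seq = "".join(out)
    return seq, tuple(subs), has_indel


def simulate_long_reads(
    truth: Sequence[TruthRecord],
    genes: Mapping[str, GeneModel],
    genome: Genome,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[SimulatedRead]:
    """Simulate reads from fusion transcripts and every normal gene transcript.

    Each transcript yields a uniform number of reads in
    ``reads_per_transcript``; a read is full-length or (at the configured
    fraction) a 3'-anchored fragment; antisense reads are reverse
    complements.  Substitutions/indels are i.i.d. per base.  Read names
    carry no truth — provenance lives in the returned objects only.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    sources: list[tuple[str, str, bool]] = []  # (name, sequence, is_fusion)
    for t in truth:
        sources.append((t.fusion_name, t.sequence, True))
    for gene in sorted(genes.values(), key=lambda g: g.gene_id):
        sources.append((gene.symbol, spliced_sequence(gene, genome), False))

    reads: list[SimulatedRead] = []
    counter = 0
    truth_by_name = {t.fusion_name: t for t in truth}
    for name, seq, is_fusion in sources:
        n_reads = int(
            rng.integers(config.reads_per_transcript[0],
                         config.reads_per_transcript[1] + 1)
        )
        for _ in range(n_reads):
            frag_start, frag_end = 0, len(seq)
            if (
                config.three_prime_fraction > 0
                and rng.random() < config.three_prime_fraction
                and len(seq) > config.min_fragment_length
            ):
                frag_len = int(
                    rng.integers(config.min_fragment_length, len(seq) + 1)
                )
                frag_start = len(seq) - frag_len
            fragment = seq[frag_start:frag_end]
            errored, subs, has_indel = _apply_errors(
                fragment, config, rng, frag_start
            )
            antisense = rng.random() < config.antisense_fraction
            read_seq = reverse_complement(errored) if antisense else errored
            read_id = f"read{counter:06d}"
            counter += 1
            reads.append(
                SimulatedRead(
                    read_id=read_id,
                    sequence=read_seq,
                    source=name,
                    is_fusion=is_fusion,
                    antisense=antisense,
                    fragment_start=frag_start,
                    fragment_end=frag_end,
                    substitutions=subs,
                    has_indels=has_indel,
                )
            )
            if is_fusion:
                t = truth_by_name[name]
                # A fragment evidences the fusion only if it spans the junction.
                if frag_start < t.sequence_break < frag_end:
                    t.read_ids.append(read_id)
    return reads


def simulate(config: SimConfig) -> Simulation:
    """Run the full generator: genome, fusions, reads, truth."""
    rng = np.random.default_rng(config.seed)
    genome, genes = make_toy_genome(config, rng)
    truth = make_fusion_transcripts(genome, genes, config, rng)
    reads = simulate_long_reads(truth, genes, genome, config, rng)
    sim = Simulation(
        config=config, genome=genome, genes=genes, truth=truth, reads=reads
    )
    for gene in genes.values():
        sim.gene_transcripts[gene.symbol] = spliced_sequence(gene, genome)
    return sim


# ---------------------------------------------------------------------------
# Truth alignments (by construction)
# ---------------------------------------------------------------------------


def _transcript_maps(gene: GeneModel, tx: Transcript) -> list[tuple[int, int, int]]:
    """(transcript_start, genomic_start, length) per exon, transcript order."""
    blocks = []
    tpos = 0
    for s, e in _exons_in_transcript_order(gene, tx):
        blocks.append((tpos, s, e - s))
        tpos += e - s
    return blocks


def _genomic_span(
    gene: GeneModel, tx: Transcript, t_lo: int, t_hi: int
) -> tuple[int, int]:
    """Genomic min/max span covered by transcript interval [t_lo, t_hi)."""
    lo = hi = None
    for tstart, gstart, length in _transcript_maps(gene, tx):
        a, b = max(t_lo, tstart), min(t_hi, tstart + length)
        if b <= a:
            continue
        if gene.strand == "+":
            g1, g2 = gstart + (a - tstart), gstart + (b - tstart)
        else:
            # transcript runs against the genome on minus-strand genes
            g2 = gstart + length - (a - tstart)
            g1 = gstart + length - (b - tstart)
        lo = g1 if lo is None else min(lo, g1)
        hi = g2 if hi is None else max(hi, g2)
    if lo is None:
        raise ValueError("empty transcript interval")
    return lo, hi


def emit_truth_paf(
    sim: Simulation, path: str | Path | None = None
) -> list[str]:
    """Genome-space PAF rows computed by construction from the truth map.

    Fusion reads spanning the junction yield two rows (one per gene side);
    other reads yield one.  Identity reflects the realized substitutions in
    each segment.  Only substitution-bearing (not indel-bearing) reads are
    supported: indels shift coordinates, which requires the external-aligner
    path.
    """
    truth_by_name = {t.fusion_name: t for t in sim.truth}
    genes_by_symbol = {g.symbol: g for g in sim.genes.values()}
    lines: list[str] = []
    for read in sim.reads:
        if read.has_indels:
            raise ValueError(
                f"{read.read_id}: indel-bearing reads cannot use truth "
                "alignments; realign with the external aligner instead"
            )
        read_len = len(read.sequence)
        if read.is_fusion:
            t = truth_by_name[read.source]
            brk = t.sequence_break
            parts = []
            if read.fragment_start < brk:
                parts.append(("A", read.fragment_start, min(read.fragment_end, brk)))
            if read.fragment_end > brk:
                parts.append(("B", max(read.fragment_start, brk), read.fragment_end))
        else:
            parts = [("A", read.fragment_start, read.fragment_end)]
        for side, t_lo, t_hi in parts:
            if read.is_fusion:
                t = truth_by_name[read.source]
                if side == "A":
                    gene = genes_by_symbol[t.gene_a]
                    tx = gene.transcripts[0]
                    s_lo, s_hi = t_lo, t_hi  # donor part: transcript coords match
                else:
                    gene = genes_by_symbol[t.gene_b]
                    tx = gene.transcripts[0]
                    # Offset into the acceptor transcript: the fusion keeps
                    # exons [first_exon_b:], i.e. drops a 5' prefix.
                    dropped = sum(
                        e - s
                        for s, e in _exons_in_transcript_order(gene, tx)[
                            : t.first_exon_b
                        ]
                    )
                    s_lo, s_hi = t_lo - t.sequence_break + dropped, \
                        t_hi - t.sequence_break + dropped
            else:
                gene = genes_by_symbol[read.source]
                tx = gene.transcripts[0]
                s_lo, s_hi = t_lo, t_hi
            g_lo, g_hi = _genomic_span(gene, tx, s_lo, s_hi)
            # Read-space interval of this part (original read orientation).
            r_lo = t_lo - read.fragment_start
            r_hi = t_hi - read.fragment_start
            if read.antisense:
                r_lo, r_hi = read_len - r_hi, read_len - r_lo
            strand = gene.strand if not read.antisense else (
                "-" if gene.strand == "+" else "+"
            )
            seg_len = t_hi - t_lo
            n_sub = sum(1 for p in read.substitutions if t_lo <= p < t_hi)
            lines.append(
                "\t".join(
                    str(x)
                    for x in [
                        read.read_id,
                        read_len,
                        r_lo,
                        r_hi,
                        strand,
                        gene.contig,
                        sim.genome.length(gene.contig),
                        g_lo,
                        g_hi,
                        seg_len - n_sub,
                        seg_len,
                        60,
                    ]
                )
            )
    if path is not None:
        Path(path).write_text("".join(l + "\n" for l in lines))
    return lines


def emit_truth_contig_alignments(
    sim: Simulation, contigs: Mapping[str, FusionContig]
) -> dict[str, list[ContigAlignment]]:
    """Fusion-contig-space alignments computed by construction.

    For each fusion read and its pair's contig, every covered exon piece is
    mapped through the contig's coordinate map into one alignment block.
    Substitution-only reads keep exact coordinates; indel-bearing reads are
    rejected (use the external aligner).
    """
    truth_by_name = {t.fusion_name: t for t in sim.truth}
    genes_by_symbol = {g.symbol: g for g in sim.genes.values()}
    out: dict[str, list[ContigAlignment]] = {name: [] for name in contigs}
    for read in sim.reads:
        if not read.is_fusion or read.source not in contigs:
            continue
        if read.has_indels:
            raise ValueError(
                f"{read.read_id}: indel-bearing reads cannot use truth "
                "alignments; realign with the external aligner instead"
            )
        t = truth_by_name[read.source]
        contig = contigs[read.source]
        gene_a = genes_by_symbol[t.gene_a]
        gene_b = genes_by_symbol[t.gene_b]
        read_len = len(read.sequence)
        blocks: list[tuple[int, int, int, int]] = []

        def _add_blocks(gene: GeneModel, tx: Transcript, s_lo: int, s_hi: int,
                        t_offset: int) -> None:
            for tstart, gstart, length in _transcript_maps(gene, tx):
                a, b = max(s_lo, tstart), min(s_hi, tstart + length)
                if b <= a:
                    continue
                if gene.strand == "+":
                    g1, g2 = gstart + (a - tstart), gstart + (b - tstart)
                else:
                    g2 = gstart + length - (a - tstart)
                    g1 = gstart + length - (b - tstart)
                c1 = contig.genome_to_contig(gene.gene_id, g1)
                c2 = contig.genome_to_contig(gene.gene_id, g2 - 1)
                c_lo, c_hi = min(c1, c2), max(c1, c2) + 1
                # transcript interval [a, b) sits at fusion-sequence coords
                f_lo = a + t_offset
                f_hi = b + t_offset
                r_lo = f_lo - read.fragment_start
                r_hi = f_hi - read.fragment_start
                if read.antisense:
                    r_lo, r_hi = read_len - r_hi, read_len - r_lo
                blocks.append((r_lo, r_hi, c_lo, c_hi))

        brk = t.sequence_break
        if read.fragment_start < brk:
            _add_blocks(
                gene_a, gene_a.transcripts[0],
                read.fragment_start, min(read.fragment_end, brk), 0,
            )
        if read.fragment_end > brk:
            tx_b = gene_b.transcripts[0]
            dropped = sum(
                e - s
                for s, e in _exons_in_transcript_order(gene_b, tx_b)[: t.first_exon_b]
            )
            _add_blocks(
                gene_b, tx_b,
                max(read.fragment_start, brk) - brk + dropped,
                read.fragment_end - brk + dropped,
                brk - dropped,
            )
        out[read.source].append(
            ContigAlignment(
                read_id=read.read_id,
                blocks=blocks,
                strand="-" if read.antisense else "+",
            )
        )
    return out
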