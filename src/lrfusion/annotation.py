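"""Genome and gene-annotation model.

Loads a reference genome (FASTA) and a gene annotation (GTF, GENCODE/Ensembl
dialect) into lightweight in-memory models, and provides the three primitives
the fusion caller relies on:

* interval lookup of genes overlapping a genomic region,
* minimum distance from a genomic position to any annotated exon boundary of
  a gene (pooled across all of its transcripts), and
* extraction of the splice dinucleotides flanking a candidate fusion
  breakpoint pair, with a consensus (GT–AG) flag.

Coordinate conventions
----------------------
All internal intervals are 0-based, half-open ``[start, end)``.  Reported
breakpoints are 1-based ``contig:position:strand`` where the position is the
last transcribed base of the 5' gene segment or the first transcribed base of
the 3' gene segment, matching GTF/IGV conventions.
"""

from __future__ import annotations

import bisect
import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

_RC = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Donor/acceptor dinucleotide pairs treated as consensus splice sites.
#: Only the canonical GT–AG pair is included by default; GC–AG and AT–AC are
#: scored as non-consensus (the set is configurable at call sites).
CONSENSUS_DINUCLEOTIDES: frozenset[tuple[str, str]] = frozenset({("GT", "AG")})


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------


class Genome:
    """Random-access nucleotide sequences keyed by contig name.

    Backed either by an in-memory mapping (toy genomes, simulations) or by a
    ``pyfaidx``-indexed FASTA file on disk.
    """

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs = {name: str(seq).upper() for name, seq in sequences.items()}

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Genome":
        import pyfaidx

        fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
        return cls({name: str(fa[name][:]) for name in fa.keys()})

    def __contains__(self, contig: str) -> bool:
        return contig in self._seqs

    @property
    def contigs(self) -> list[str]:
        return list(self._seqs)

    def length(self, contig: str) -> int:
        return len(self._seqs[contig])

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Return the sequence of ``[start, end)`` on ``contig`` (0-based)."""
        if contig not in self._seqs:
            raise KeyError(f"unknown contig {contig!r}")
        seq = self._seqs[contig]
        if start < 0 or end > len(seq) or start > end:
            raise ValueError(
                f"interval [{start}, {end}) out of range for contig "
                f"{contig!r} of length {len(seq)}"
            )
        return seq[start:end]

    def to_fasta(self, path: str | Path, width: int = 60) -> None:
        with open(path, "w") as fh:
            for name, seq in self._seqs.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Transcript:
    """A transcript: ordered, non-overlapping exon intervals on the genome."""

    transcript_id: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self):
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        exons = tuple(sorted(tuple(e) for e in self.exons))
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValueError(
                    f"transcript {self.transcript_id}: overlapping exons "
                    f"[{s1},{e1}) and [{s2},{e2})"
                )
        object.__setattr__(self, "exons", exons)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass
class GeneModel:
    """An annotated gene: stranded exon structure pooled over transcripts."""

    gene_id: str
    symbol: str
    contig: str
    strand: str
    transcripts: list[Transcript] = field(default_factory=list)

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def span(self) -> tuple[int, int]:
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")
        return (
            min(t.span[0] for t in self.transcripts),
            max(t.span[1] for t in self.transcripts),
        )

    def exon_boundaries(self) -> list[int]:
        """Sorted distinct exon start/end coordinates over all transcripts."""
        coords: set[int] = set()
        for t in self.transcripts:
            for s, e in t.exons:
                coords.add(s)
                coords.add(e)
        if not coords:
            raise ValueError(f"gene {self.gene_id} has no exons")
        return sorted(coords)

    def merged_exons(self) -> list[tuple[int, int]]:
        """Union of all transcript exons as maximal disjoint intervals."""
        ivs = sorted(e for t in self.transcripts for e in t.exons)
        if not ivs:
            raise ValueError(f"gene {self.gene_id} has no exons")
        merged = [list(ivs[0])]
        for s, e in ivs[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        return [(s, e) for s, e in merged]


def nearest_exon_boundary_distance(gene: GeneModel, position: int) -> int:
    """Minimum |boundary - position| over all exon starts/ends of the gene.

    Boundaries are pooled across every transcript of the gene; positions and
    boundaries share the 0-based half-open convention.
    """
    bounds = gene.exon_boundaries()
    i = bisect.bisect_left(bounds, position)
    best = None
    for j in (i - 1, i):
        if 0 <= j < len(bounds):
            d = abs(bounds[j] - position)
            best = d if best is None else min(best, d)
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# GTF I/O
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _parse_attributes(text: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(text))


def load_annotation(gtf_path: str | Path) -> dict[str, GeneModel]:
    """Load gene models from a GTF file.

    Only ``exon`` features are consulted; each must carry ``gene_id`` and
    ``transcript_id`` attributes (``gene_name`` is used as the symbol when
    present).  GTF 1-based inclusive coordinates are converted to internal
    0-based half-open intervals.

    Raises
    ------
    ValueError
        On a structurally malformed line, naming its line number.  Exon
        records lacking ``transcript_id`` are rejected and logged, not fatal.
    """
    genes: dict[str, dict] = {}
    with open(gtf_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"{gtf_path}: malformed GTF line {lineno}: expected 9 "
                    f"tab-separated fields, got {len(fields)}"
                )
            contig, _src, feature, start, end, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(
                    f"{gtf_path}: malformed GTF line {lineno}: non-integer "
                    f"coordinates {start!r}..{end!r}"
                ) from exc
            att = _parse_attributes(attrs)
            gene_id = att.get("gene_id")
            tx_id = att.get("transcript_id")
            if not gene_id:
                raise ValueError(
                    f"{gtf_path}: malformed GTF line {lineno}: exon without gene_id"
                )
            if not tx_id:
                logger.warning(
                    "%s line %d: exon of gene %s lacks transcript_id; record skipped",
                    gtf_path, lineno, gene_id,
                )
                continue
            rec = genes.setdefault(
                gene_id,
                {
                    "symbol": att.get("gene_name", gene_id),
                    "contig": contig,
                    "strand": strand,
                    "tx": {},
                },
            )
            if rec["contig"] != contig or rec["strand"] != strand:
                raise ValueError(
                    f"{gtf_path}: line {lineno}: gene {gene_id} spans multiple "
                    f"contigs or strands"
                )
            # GTF is 1-based inclusive; internal is 0-based half-open.
            rec["tx"].setdefault(tx_id, []).append((start_i - 1, end_i))

    out: dict[str, GeneModel] = {}
    for gene_id, rec in genes.items():
        transcripts = [
            Transcript(tx_id, tuple(sorted(exons)))
            for tx_id, exons in rec["tx"].items()
        ]
        out[gene_id] = GeneModel(
            gene_id=gene_id,
            symbol=rec["symbol"],
            contig=rec["contig"],
            strand=rec["strand"],
            transcripts=transcripts,
        )
    return out


def write_annotation(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as GTF exon records (round-trips with load_annotation)."""
    with open(path, "w") as fh:
        for gene in genes:
            for tx in gene.transcripts:
                for s, e in tx.exons:
                    attrs = (
                        f'gene_id "{gene.gene_id}"; '
                        f'transcript_id "{tx.transcript_id}"; '
                        f'gene_name "{gene.symbol}";'
                    )
                    fh.write(
                        "\t".join(
                            [
                                gene.contig,
                                "lrfusion",
                                "exon",
                                str(s + 1),
                                str(e),
                                ".",
                                gene.strand,
                                ".",
                                attrs,
                            ]
                        )
                        + "\n"
                    )


# ---------------------------------------------------------------------------
# Boundary index
# ---------------------------------------------------------------------------


class BoundaryIndex:
    """Interval index of gene spans plus per-gene exon-boundary sets.

    Supports the phase-1 gene assignment (which gene does an alignment
    segment overlap, and how far is its junction from an exon boundary).
    """

    def __init__(self, genes: Mapping[str, GeneModel]):
        self.genes = dict(genes)
        self._trees: dict[str, IntervalTree] = {}
        for gene in self.genes.values():
            s, e = gene.span
            self._trees.setdefault(gene.contig, IntervalTree()).addi(
                s, e, gene.gene_id
            )

    def genes_overlapping(self, contig: str, start: int, end: int) -> list[GeneModel]:
        tree = self._trees.get(contig)
        if tree is None:
            return []
        hits = tree.overlap(start, end)
        return sorted((self.genes[iv.data] for iv in hits), key=lambda g: g.gene_id)

    def boundary_distance(self, gene_id: str, position: int) -> int:
        return nearest_exon_boundary_distance(self.genes[gene_id], position)

    def to_tsv(self, path: str | Path) -> None:
        """Serialize the boundary set as (contig, coordinate, gene_id) rows."""
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["contig", "coordinate", "gene_id"])
            for gene in sorted(self.genes.values(), key=lambda g: g.gene_id):
                for coord in gene.exon_boundaries():
                    w.writerow([gene.contig, coord, gene.gene_id])


# ---------------------------------------------------------------------------
# Breakpoints and splice dinucleotides
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class Breakpoint:
    """A fusion breakpoint: 1-based genomic position with gene strand."""

    contig: str
    position: int  # 1-based: last (5' side) or first (3' side) transcribed base
    strand: str

    def __str__(self) -> str:
        return f"{self.contig}:{self.position}:{self.strand}"

    @classmethod
    def parse(cls, text: str) -> "Breakpoint":
        contig, pos, strand = text.rsplit(":", 2)
        return cls(contig, int(pos), strand)


def splice_dinucleotides(
    genome: Genome,
    breakpoint_5p: Breakpoint,
    breakpoint_3p: Breakpoint,
    consensus: frozenset[tuple[str, str]] = CONSENSUS_DINUCLEOTIDES,
) -> tuple[str, str, bool]:
    """Extract donor/acceptor dinucleotides flanking a breakpoint pair.

    The donor is the two bases immediately 3' of the 5'-gene breakpoint in
    that gene's transcriptional orientation (reverse-complemented for minus
    strand genes); the acceptor is the two bases immediately 5' of the
    3'-gene breakpoint likewise.  Returns ``(donor, acceptor, is_consensus)``
    where consensus means the pair is in ``consensus`` (GT–AG by default).
    """
    donor = _flank(genome, breakpoint_5p, downstream=True)
    acceptor = _flank(genome, breakpoint_3p, downstream=False)
    return donor, acceptor, (donor, acceptor) in consensus


def _flank(genome: Genome, bp: Breakpoint, downstream: bool) -> str:
    pos0 = bp.position - 1  # 0-based index of the breakpoint base
    length = genome.length(bp.contig)
    # Walk two bases away from the transcribed segment: downstream of a donor,
    # upstream of an acceptor, in transcriptional orientation.
    forward = (bp.strand == "+") == downstream
    if forward:
        start, end = pos0 + 1, pos0 + 3
    else:
        start, end = pos0 - 2, pos0
    if start < 0 or end > length:
        raise ValueError(
            f"breakpoint {bp} is within 2 bases of the end of contig "
            f"{bp.contig} (length {length})"
        )
    seq = genome.fetch(bp.contig, start, end)
    return seq if bp.strand == "+" else reverse_complement(seq)
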