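"""Final fusion filters, short-read evidence merging, and report output.

Filters applied to phase-2 isoform calls:

* minimum fusion expression of 0.1 FFPM,
* at least 2 supporting reads when the breakpoint lacks consensus (GT–AG)
  splice dinucleotides,
* isoforms with read support below 5% of their gene pair's dominant isoform
  are discarded as noise (the dominant isoform is determined on the
  unfiltered call set, which makes the per-call filters order-independent),
* gene pairs present in a normal-tissue blocklist are removed (unordered
  symbol matching, as normal-tissue catalogs list unordered pairs).

When short-read fusion evidence is available (a FusionInspector-style
table), isoforms are retained if *either* the long-read or the short-read
FFPM reaches 0.1, each computed against its own library size.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotation import Breakpoint
from .contig import FusionIsoformCall
from .phase1 import DEFAULT_MIN_FFPM, compute_ffpm

logger = logging.getLogger(__name__)

DEFAULT_MIN_READS_NONCONSENSUS = 2
DEFAULT_MINOR_ISOFORM_FRACTION = 0.05

REPORT_COLUMNS = [
    "fusion_name",
    "breakpoint_A",
    "breakpoint_B",
    "long_read_count",
    "long_FFPM",
    "short_read_count",
    "short_FFPM",
    "splice_dinucleotides",
    "annotations",
    "supporting_reads",
]


class Blocklist:
    """Unordered gene-symbol pairs known to fuse in normal tissues."""

    def __init__(self, pairs: Iterable[tuple[str, str]] = ()):
        self._pairs = {frozenset(p) for p in pairs}

    @classmethod
    def from_tsv(cls, path: str | Path) -> "Blocklist":
        """Read a two-column (plus optional annotation) TSV of symbol pairs."""
        pairs = []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                fields = line.rstrip("\n").split("\t")
                if len(fields) < 2:
                    raise ValueError(f"{path}: blocklist line needs two columns")
                pairs.append((fields[0], fields[1]))
        return cls(pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return frozenset(pair) in self._pairs

    def __len__(self) -> int:
        return len(self._pairs)


def apply_final_filters(
    calls: Sequence[FusionIsoformCall],
    blocklist: Blocklist | None = None,
    min_ffpm: float = DEFAULT_MIN_FFPM,
    min_reads_nonconsensus: int = DEFAULT_MIN_READS_NONCONSENSUS,
    minor_isoform_fraction: float = DEFAULT_MINOR_ISOFORM_FRACTION,
) -> list[FusionIsoformCall]:
    """Apply the final per-call filters; see the module docstring.

    The dominant isoform of each gene pair is the maximal read-count call in
    the *input* set (ties broken by the leftmost 5' breakpoint), so the three
    per-call predicates commute.
    """
    dominant: dict[tuple[str, str], int] = {}
    for call in sorted(calls, key=lambda c: (-c.read_count, c.breakpoint_5p)):
        dominant.setdefault(call.gene_pair, call.read_count)

    kept = []
    for call in calls:
        if call.ffpm < min_ffpm:
            continue
        if not call.consensus_splice and call.read_count < min_reads_nonconsensus:
            continue
        if call.read_count < minor_isoform_fraction * dominant[call.gene_pair]:
            continue
        if blocklist is not None and call.gene_pair in blocklist:
            continue
        kept.append(call)
    return kept


def load_short_read_evidence(path: str | Path) -> pd.DataFrame:
    """Read a short-read fusion evidence table.

    Expected columns: geneA, geneB, breakpointA, breakpointB, count and
    optionally ffpm (computed from a supplied fragment total otherwise).
    """
    df = pd.read_csv(path, sep="\t", dtype={"geneA": str, "geneB": str})
    required = {"geneA", "geneB", "breakpointA", "breakpointB", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: short-read table missing columns {sorted(missing)}")
    return df


def merge_short_read_evidence(
    long_calls: Sequence[FusionIsoformCall],
    short_table: pd.DataFrame,
    total_short_fragments: int,
    candidate_pairs: Iterable[tuple[str, str]] | None = None,
    min_ffpm: float = DEFAULT_MIN_FFPM,
) -> list[FusionIsoformCall]:
    """Merge long- and short-read evidence into the final isoform set.

    The result is the union of isoforms; an isoform is retained iff its
    long-read FFPM or its short-read FFPM reaches ``min_ffpm``.  Isoforms
    present only in the short table appear with a long-read count of zero;
    those whose gene pair was never a long-read candidate are kept but
    flagged ``short-only pair`` in the annotations column (and logged).
    """
    if candidate_pairs is None:
        candidate_pairs = {c.gene_pair for c in long_calls}
    else:
        candidate_pairs = set(candidate_pairs)

    by_key: dict[tuple, FusionIsoformCall] = {}
    for call in long_calls:
        key = (call.gene_pair, str(call.breakpoint_5p), str(call.breakpoint_3p))
        by_key[key] = call

    for row in short_table.to_dict("records"):
        pair = (str(row["geneA"]), str(row["geneB"]))
        key = (pair, str(row["breakpointA"]), str(row["breakpointB"]))
        count = int(row["count"])
        ffpm = (
            float(row["ffpm"])
            if "ffpm" in row and not pd.isna(row["ffpm"])
            else compute_ffpm(count, total_short_fragments)
        )
        if key in by_key:
            by_key[key] = replace(
                by_key[key], short_read_count=count, short_read_ffpm=ffpm
            )
        else:
            annotations = ""
            if pair not in candidate_pairs:
                annotations = "short-only pair"
                logger.warning(
                    "short-read evidence for non-candidate pair %s--%s", *pair
                )
            by_key[key] = FusionIsoformCall(
                gene_pair=pair,
                breakpoint_5p=Breakpoint.parse(str(row["breakpointA"])),
                breakpoint_3p=Breakpoint.parse(str(row["breakpointB"])),
                read_ids=(),
                ffpm=0.0,
                short_read_count=count,
                short_read_ffpm=ffpm,
                annotations=annotations,
            )

    merged = [
        c
        for c in by_key.values()
        if c.ffpm >= min_ffpm or c.short_read_ffpm >= min_ffpm
    ]
    merged.sort(key=lambda c: (-c.read_count, c.name, c.breakpoint_5p, c.breakpoint_3p))
    return merged


def report_rows(calls: Sequence[FusionIsoformCall]) -> pd.DataFrame:
    """Tabulate isoform calls in the report's deterministic column order."""
    rows = []
    for c in calls:
        rows.append(
            {
                "fusion_name": c.name,
                "breakpoint_A": str(c.breakpoint_5p),
                "breakpoint_B": str(c.breakpoint_3p),
                "long_read_count": c.read_count,
                "long_FFPM": round(c.ffpm, 4),
                "short_read_count": c.short_read_count,
                "short_FFPM": round(c.short_read_ffpm, 4),
                "splice_dinucleotides": (
                    f"{c.splice_donor}-{c.splice_acceptor}"
                    if c.splice_donor
                    else "."
                ),
                "annotations": c.annotations or ".",
                "supporting_reads": ",".join(c.read_ids),
            }
        )
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    df = df.sort_values(
        ["long_read_count", "fusion_name", "breakpoint_A", "breakpoint_B"],
        ascending=[False, True, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return df


def write_report(calls: Sequence[FusionIsoformCall], path: str | Path) -> None:
    """Write the final fusion report TSV (byte-deterministic for fixed input)."""
    df = report_rows(calls)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
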