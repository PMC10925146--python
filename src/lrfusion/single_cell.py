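"""Per-cell fusion reporting for barcoded single-cell long reads.

Cell barcodes and UMIs are carried in the read names (encoded upstream of
alignment as ``barcode^UMI^original_name`` by default; both delimiter and
field order are configurable here to avoid dialect lock-in).  From the final
fusion report's supporting read lists, this module tallies per-(cell,
isoform) molecule counts, collapsing reads that share a (barcode, UMI) pair
into a single molecule (exact-match deduplication — no edit-distance
collapsing).  Reads lacking the encoding are flagged untagged: they still
count toward bulk totals but are excluded from per-cell output.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import scipy.io
import scipy.sparse

from .contig import FusionIsoformCall

logger = logging.getLogger(__name__)

DEFAULT_DELIMITER = "^"


@dataclass(frozen=True)
class CellReadTag:
    """Cell barcode + UMI extracted from an encoded read name."""

    barcode: str
    umi: str
    read_name: str


def encode_cell_tag(
    barcode: str, umi: str, read_name: str, delimiter: str = DEFAULT_DELIMITER
) -> str:
    """Encode barcode and UMI into a read name (inverse of parse_cell_tag)."""
    for part, label in ((barcode, "barcode"), (umi, "UMI")):
        if not part:
            raise ValueError(f"empty {label}")
        if delimiter in part:
            raise ValueError(f"{label} {part!r} contains delimiter {delimiter!r}")
    return f"{barcode}{delimiter}{umi}{delimiter}{read_name}"


def parse_cell_tag(
    read_name: str, delimiter: str = DEFAULT_DELIMITER
) -> CellReadTag | None:
    """Split an encoded read name into (barcode, UMI, remainder).

    The remainder may itself contain the delimiter.  Returns None for
    untagged names (fewer than two delimiters, or empty barcode/UMI).
    """
    parts = read_name.split(delimiter, 2)
    if len(parts) < 3 or not parts[0] or not parts[1]:
        return None
    return CellReadTag(barcode=parts[0], umi=parts[1], read_name=parts[2])


class CellFusionMatrix:
    """Cells × fusion isoforms matrix of deduplicated molecule counts."""

    def __init__(
        self,
        cells: Sequence[str],
        isoforms: Sequence[str],
        counts: scipy.sparse.csr_matrix,
    ):
        self.cells = list(cells)
        self.isoforms = list(isoforms)
        self.counts = counts

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts.toarray(), index=self.cells, columns=self.isoforms
        )

    def to_long_tsv(self, path: str | Path) -> None:
        """Write long-form rows: cell, fusion, breakpoints, molecule count."""
        rows = []
        coo = self.counts.tocoo()
        for i, j, v in zip(coo.row, coo.col, coo.data):
            name, bp_a, bp_b = self.isoforms[j].split("|")
            rows.append(
                {
                    "cell": self.cells[i],
                    "fusion": name,
                    "breakpoint_A": bp_a,
                    "breakpoint_B": bp_b,
                    "count": int(v),
                }
            )
        df = pd.DataFrame(
            rows, columns=["cell", "fusion", "breakpoint_A", "breakpoint_B", "count"]
        ).sort_values(["cell", "fusion", "breakpoint_A", "breakpoint_B"])
        df.to_csv(path, sep="\t", index=False, lineterminator="\n")

    def to_mtx(self, prefix: str | Path) -> None:
        """Write MatrixMarket counts plus row (cell) / column (isoform) sidecars."""
        prefix = Path(prefix)
        scipy.io.mmwrite(str(prefix.with_suffix(".mtx")), self.counts)
        prefix.with_suffix(".rows.tsv").write_text(
            "".join(c + "\n" for c in self.cells)
        )
        prefix.with_suffix(".cols.tsv").write_text(
            "".join(i + "\n" for i in self.isoforms)
        )


def per_cell_fusion_matrix(
    calls: Iterable[FusionIsoformCall],
    delimiter: str = DEFAULT_DELIMITER,
) -> CellFusionMatrix:
    """Build the per-cell molecule-count matrix from fusion isoform calls.

    For each (cell, isoform), distinct (barcode, UMI) pairs among the
    isoform's supporting reads are counted; reads sharing barcode and UMI
    collapse to one molecule.  Invariant to read order.
    """
    molecules: dict[str, set[tuple[str, str]]] = {}
    isoform_ids: list[str] = []
    for call in calls:
        iso = f"{call.name}|{call.breakpoint_5p}|{call.breakpoint_3p}"
        isoform_ids.append(iso)
        seen = molecules.setdefault(iso, set())
        n_untagged = 0
        for read_name in call.read_ids:
            tag = parse_cell_tag(read_name, delimiter)
            if tag is None:
                n_untagged += 1
                continue
            seen.add((tag.barcode, tag.umi))
        if n_untagged:
            logger.info(
                "%s: %d untagged read(s) excluded from per-cell output",
                iso, n_untagged,
            )

    cells = sorted({bc for pairs in molecules.values() for bc, _ in pairs})
    isoforms = sorted(set(isoform_ids))
    cell_ix = {c: i for i, c in enumerate(cells)}
    iso_ix = {s: j for j, s in enumerate(isoforms)}
    mat = scipy.sparse.dok_matrix((len(cells), len(isoforms)), dtype=int)
    for iso, pairs in molecules.items():
        per_cell: dict[str, int] = {}
        for bc, _umi in pairs:
            per_cell[bc] = per_cell.get(bc, 0) + 1
        for bc, n in per_cell.items():
            mat[cell_ix[bc], iso_ix[iso]] = n
    return CellFusionMatrix(cells, isoforms, mat.tocsr())
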