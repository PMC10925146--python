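"""Benchmarking of fusion predictions against truth sets.

Gene-pair matching runs in two modes: *strict* (the predicted 5'→3' gene
order must match the truth) and *allow-reverse* (either order accepted).
Symbols are compared through an equivalence map admitting paralog symbols
and genes with overlapping genomic coordinates as proxies.  Breakpoint
matching likewise runs *exact* or *fuzzy* (each coordinate within a ±5-base
window); the two breakpoints of every record are sorted before comparison.

Matching is one-to-one: each truth entry is consumed at most once, so a
truth fusion matched by two predictions of the same method scores one TP
and one FP (duplicate predictions within a method are collapsed first).
The TP assignment is a maximum bipartite matching, so the TP count never
depends on record order.

Scores follow precision = TP/(TP+FP), recall = TP/(TP+FN) and
F1 = 2·precision·recall/(precision+recall), each 0 when its denominator is
0.  ``max_f1_over_min_reads`` sweeps a minimum-read-support threshold over
the distinct observed support values and reports the maximum F1.

For real data lacking an absolute truth, ``build_proxy_truth_set``
constructs an operational truth from multi-method agreement after artifact
filters (minimum support, gene-category and normal-tissue blocklists, the
100 kb neighboring-gene filter, and promiscuous-gene exclusion).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .annotation import Breakpoint, GeneModel

logger = logging.getLogger(__name__)

DEFAULT_FUZZY_WINDOW = 5  # bases
DEFAULT_MIN_READS = 3
DEFAULT_NEIGHBOR_DISTANCE = 100_000  # bases
DEFAULT_PROMISCUITY_METHODS = 2
DEFAULT_PROMISCUITY_SAMPLES = 3


@dataclass(frozen=True)
class FusionRecord:
    """One predicted or truth fusion for one sample."""

    sample: str
    gene_a: str
    gene_b: str
    breakpoint_a: Breakpoint | None = None
    breakpoint_b: Breakpoint | None = None
    reads: int = 0
    method: str = ""

    def __post_init__(self):
        if self.reads < 0:
            raise ValueError("read support must be non-negative")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)

    @property
    def sorted_breakpoints(self) -> tuple[tuple[str, int], tuple[str, int]] | None:
        if self.breakpoint_a is None or self.breakpoint_b is None:
            return None
        pts = sorted(
            [
                (self.breakpoint_a.contig, self.breakpoint_a.position),
                (self.breakpoint_b.contig, self.breakpoint_b.position),
            ]
        )
        return (pts[0], pts[1])


def read_fusion_table(path: str | Path) -> list[FusionRecord]:
    """Load a prediction or truth TSV.

    Columns: sample, geneA, geneB, optional breakpointA/breakpointB
    (contig:pos:strand), optional reads, optional method.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    records = []
    for row in df.to_dict("records"):
        records.append(
            FusionRecord(
                sample=row.get("sample", ""),
                gene_a=row["geneA"],
                gene_b=row["geneB"],
                breakpoint_a=(
                    Breakpoint.parse(row["breakpointA"])
                    if row.get("breakpointA")
                    else None
                ),
                breakpoint_b=(
                    Breakpoint.parse(row["breakpointB"])
                    if row.get("breakpointB")
                    else None
                ),
                reads=int(float(row["reads"])) if row.get("reads") else 0,
                method=row.get("method", ""),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Equivalence map
# ---------------------------------------------------------------------------


class EquivalenceMap:
    """Symbol → accepted proxy symbols (self, paralogs, overlapping genes)."""

    def __init__(self, mapping: Mapping[str, set[str]] | None = None):
        self._map: dict[str, set[str]] = {}
        if mapping:
            for sym, proxies in mapping.items():
                for p in proxies:
                    self.add(sym, p)

    def add(self, a: str, b: str) -> None:
        self._map.setdefault(a, {a}).add(b)
        self._map.setdefault(b, {b}).add(a)

    def proxies(self, symbol: str) -> set[str]:
        return self._map.get(symbol, {symbol})

    def equivalent(self, a: str, b: str) -> bool:
        return a == b or b in self._map.get(a, ())

    @classmethod
    def identity(cls) -> "EquivalenceMap":
        return cls()

    @classmethod
    def from_paralog_tsv(cls, path: str | Path) -> "EquivalenceMap":
        """Two-column TSV of symbol pairs accepted as mutual proxies."""
        em = cls()
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                a, b = line.rstrip("\n").split("\t")[:2]
                em.add(a, b)
        return em

    def add_overlapping_genes(self, genes: Iterable[GeneModel]) -> "EquivalenceMap":
        """Accept symbols of genes with overlapping genomic spans as proxies."""
        by_contig: dict[str, list[GeneModel]] = {}
        for g in genes:
            by_contig.setdefault(g.contig, []).append(g)
        for contig_genes in by_contig.values():
            contig_genes.sort(key=lambda g: g.span)
            for g1, g2 in itertools.combinations(contig_genes, 2):
                s1, e1 = g1.span
                s2, e2 = g2.span
                if min(e1, e2) > max(s1, s2):
                    self.add(g1.symbol, g2.symbol)
        return self


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------


@dataclass
class MatchResult:
    tp_records: list[FusionRecord] = field(default_factory=list)
    fp_records: list[FusionRecord] = field(default_factory=list)
    fn_records: list[FusionRecord] = field(default_factory=list)

    @property
    def tp(self) -> int:
        return len(self.tp_records)

    @property
    def fp(self) -> int:
        return len(self.fp_records)

    @property
    def fn(self) -> int:
        return len(self.fn_records)


def _pair_matches(
    pred: FusionRecord,
    truth: FusionRecord,
    mode: str,
    equivalence: EquivalenceMap,
) -> bool:
    eq = equivalence.equivalent
    forward = eq(pred.gene_a, truth.gene_a) and eq(pred.gene_b, truth.gene_b)
    if mode == "strict":
        return forward
    if mode == "allow_reverse":
        return forward or (
            eq(pred.gene_b, truth.gene_a) and eq(pred.gene_a, truth.gene_b)
        )
    raise ValueError(f"unknown matching mode {mode!r}")


def _one_to_one(
    predictions: Sequence[FusionRecord],
    truth: Sequence[FusionRecord],
    edge_fn,
) -> MatchResult:
    """Maximum bipartite matching between predictions and truth entries."""
    g = nx.Graph()
    pred_nodes = [("p", i) for i in range(len(predictions))]
    truth_nodes = [("t", j) for j in range(len(truth))]
    g.add_nodes_from(pred_nodes, bipartite=0)
    g.add_nodes_from(truth_nodes, bipartite=1)
    for i, p in enumerate(predictions):
        for j, t in enumerate(truth):
            if p.sample == t.sample and edge_fn(p, t):
                g.add_edge(("p", i), ("t", j))
    matching = nx.bipartite.hopcroft_karp_matching(g, top_nodes=pred_nodes)
    result = MatchResult()
    matched_truth: set[int] = set()
    for i, p in enumerate(predictions):
        partner = matching.get(("p", i))
        if partner is not None:
            result.tp_records.append(p)
            matched_truth.add(partner[1])
        else:
            result.fp_records.append(p)
    for j, t in enumerate(truth):
        if j not in matched_truth:
            result.fn_records.append(t)
    return result


def collapse_duplicates(records: Sequence[FusionRecord]) -> list[FusionRecord]:
    """Collapse records sharing (sample, ordered pair, breakpoints); keep max reads."""
    best: dict[tuple, FusionRecord] = {}
    for r in records:
        key = (r.sample, r.pair, r.sorted_breakpoints)
        if key not in best or r.reads > best[key].reads:
            best[key] = r
    return list(best.values())


def match_fusion_pairs(
    predictions: Sequence[FusionRecord],
    truth: Sequence[FusionRecord],
    mode: str = "strict",
    equivalence: EquivalenceMap | None = None,
) -> MatchResult:
    """Score predicted gene pairs against the truth set.

    ``mode='strict'`` requires the predicted 5'→3' order; ``'allow_reverse'``
    also accepts the reversed order.  Symbols compare through ``equivalence``
    (identity when omitted).  One-to-one: each truth entry matches at most
    one prediction; unmatched predictions are FP, unmatched truths FN.
    """
    equivalence = equivalence or EquivalenceMap.identity()
    preds = _collapse_pairs(predictions)
    return _one_to_one(
        preds, list(truth), lambda p, t: _pair_matches(p, t, mode, equivalence)
    )


def _collapse_pairs(records: Sequence[FusionRecord]) -> list[FusionRecord]:
    best: dict[tuple, FusionRecord] = {}
    for r in records:
        key = (r.sample, r.pair)
        if key not in best or r.reads > best[key].reads:
            best[key] = r
    return list(best.values())


def _breakpoints_match(
    pred: FusionRecord, truth: FusionRecord, mode: str, window: int
) -> bool:
    bp_p, bp_t = pred.sorted_breakpoints, truth.sorted_breakpoints
    assert bp_p is not None and bp_t is not None
    for (cp, pp), (ct, pt) in zip(bp_p, bp_t):
        if cp != ct:
            return False
        if mode == "exact":
            if pp != pt:
                return False
        elif mode == "fuzzy":
            if abs(pp - pt) > window:
                return False
        else:
            raise ValueError(f"unknown breakpoint mode {mode!r}")
    return True


def match_breakpoints(
    predictions: Sequence[FusionRecord],
    truth: Sequence[FusionRecord],
    mode: str = "exact",
    window: int = DEFAULT_FUZZY_WINDOW,
) -> MatchResult:
    """Score breakpoint pairs; gene ordering is ignored (breakpoints sorted).

    ``'exact'`` requires identical sorted coordinates; ``'fuzzy'`` allows each
    coordinate within ±``window`` bases.  Records missing a breakpoint are
    excluded (logged).
    """
    preds = [p for p in predictions if p.sorted_breakpoints is not None]
    truths = [t for t in truth if t.sorted_breakpoints is not None]
    if len(preds) < len(predictions) or len(truths) < len(truth):
        logger.warning(
            "excluded %d prediction(s) and %d truth record(s) without breakpoints",
            len(predictions) - len(preds), len(truth) - len(truths),
        )
    preds = collapse_duplicates(preds)
    return _one_to_one(
        preds, truths, lambda p, t: _breakpoints_match(p, t, mode, window)
    )


# ---------------------------------------------------------------------------
# Scores
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BenchmarkCounts:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float


def precision_recall_f1(tp: int, fp: int, fn: int) -> BenchmarkCounts:
    """precision = TP/(TP+FP); recall = TP/(TP+FN); F1 = harmonic mean."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall
        else 0.0
    )
    return BenchmarkCounts(tp, fp, fn, precision, recall, f1)


def score_predictions(
    predictions: Sequence[FusionRecord],
    truth: Sequence[FusionRecord],
    pair_mode: str = "strict",
    breakpoint_mode: str | None = None,
    window: int = DEFAULT_FUZZY_WINDOW,
    equivalence: EquivalenceMap | None = None,
) -> BenchmarkCounts:
    """Gene-pair scoring, optionally refined by breakpoint agreement.

    With ``breakpoint_mode`` set, a prediction counts as TP only if its gene
    pair matched *and* its breakpoints match its truth partner under the
    chosen mode (evaluated among the pair-matched records only, ignoring
    gene order).
    """
    equivalence = equivalence or EquivalenceMap.identity()
    if breakpoint_mode is None:
        res = match_fusion_pairs(predictions, truth, pair_mode, equivalence)
        return precision_recall_f1(res.tp, res.fp, res.fn)
    preds = _collapse_pairs(
        [p for p in predictions if p.sorted_breakpoints is not None]
    )
    truths = [t for t in truth if t.sorted_breakpoints is not None]
    res = _one_to_one(
        preds,
        truths,
        lambda p, t: _pair_matches(p, t, pair_mode, equivalence)
        and _breakpoints_match(p, t, breakpoint_mode, window),
    )
    return precision_recall_f1(res.tp, res.fp, res.fn)


def max_f1_over_min_reads(
    predictions: Sequence[FusionRecord],
    truth: Sequence[FusionRecord],
    pair_mode: str = "strict",
    breakpoint_mode: str | None = None,
    window: int = DEFAULT_FUZZY_WINDOW,
    equivalence: EquivalenceMap | None = None,
) -> tuple[int, float, pd.DataFrame]:
    """Sweep minimum read support and report the maximum F1.

    Thresholds are the sorted distinct support values among the predictions;
    at each threshold t, predictions with support ≥ t are scored.  Ties on
    F1 resolve to the smallest threshold.  Returns
    (best threshold, best F1, sweep table).
    """
    thresholds = sorted({p.reads for p in predictions}) or [0]
    rows = []
    best_t, best_f1 = thresholds[0], -1.0
    for t in thresholds:
        subset = [p for p in predictions if p.reads >= t]
        counts = score_predictions(
            subset, truth, pair_mode, breakpoint_mode, window, equivalence
        )
        rows.append(
            {
                "min_reads": t,
                "TP": counts.tp,
                "FP": counts.fp,
                "FN": counts.fn,
                "precision": counts.precision,
                "recall": counts.recall,
                "F1": counts.f1,
            }
        )
        if counts.f1 > best_f1:
            best_t, best_f1 = t, counts.f1
    sweep = pd.DataFrame(rows)
    return best_t, max(best_f1, 0.0), sweep


# ---------------------------------------------------------------------------
# Proxy truth construction
# ---------------------------------------------------------------------------


@dataclass
class ProxyTruthResult:
    truth: list[FusionRecord]
    fp_by_method: dict[str, list[FusionRecord]]
    flagged: list[FusionRecord]  # kept despite a missing gene coordinate


def build_proxy_truth_set(
    predictions: Sequence[FusionRecord],
    min_reads: int = DEFAULT_MIN_READS,
    neighbor_distance: int = DEFAULT_NEIGHBOR_DISTANCE,
    promiscuity_methods: int = DEFAULT_PROMISCUITY_METHODS,
    promiscuity_samples: int = DEFAULT_PROMISCUITY_SAMPLES,
    category_symbols: Iterable[str] = (),
    blocklist_pairs: Iterable[tuple[str, str]] = (),
    gene_coordinates: Mapping[str, tuple[str, int, int]] | None = None,
) -> ProxyTruthResult:
    """Operational truth from multi-method agreement on real samples.

    Pipeline order: minimum-support filter; removal of fusions touching a
    filtered gene category (mitochondrial/HLA/IG symbol lists pooled in
    ``category_symbols``) or a normal-tissue blocklist pair; removal of
    same-chromosome pairs closer than ``neighbor_distance``; exclusion of
    promiscuous genes (reported by ≥ ``promiscuity_methods`` methods in
    ≥ ``promiscuity_samples`` samples); then per (sample, unordered pair),
    entries predicted by at least two methods form the truth set, and
    surviving uniquely-predicted fusions are FPs for their method.
    Pairs with a gene missing from ``gene_coordinates`` skip the neighbor
    test but are flagged.
    """
    category = set(category_symbols)
    blocked = {frozenset(p) for p in blocklist_pairs}
    coords = gene_coordinates or {}

    survivors: list[FusionRecord] = []
    flagged: list[FusionRecord] = []
    for rec in predictions:
        if rec.reads < min_reads:
            continue
        if rec.gene_a in category or rec.gene_b in category:
            continue
        if frozenset(rec.pair) in blocked:
            continue
        ca, cb = coords.get(rec.gene_a), coords.get(rec.gene_b)
        if ca is None or cb is None:
            if coords:
                flagged.append(rec)
        elif ca[0] == cb[0]:
            gap = max(ca[1], cb[1]) - min(ca[2], cb[2])
            if gap < neighbor_distance:
                continue
        survivors.append(rec)

    # Promiscuous genes: reported by >= promiscuity_methods methods in
    # >= promiscuity_samples distinct samples.
    gene_hits: dict[str, dict[str, set[str]]] = {}
    for rec in survivors:
        for sym in rec.pair:
            gene_hits.setdefault(sym, {}).setdefault(rec.sample, set()).add(rec.method)
    promiscuous = {
        sym
        for sym, by_sample in gene_hits.items()
        if sum(
            1 for methods in by_sample.values() if len(methods) >= promiscuity_methods
        )
        >= promiscuity_samples
    }
    survivors = [
        r
        for r in survivors
        if r.gene_a not in promiscuous and r.gene_b not in promiscuous
    ]

    by_fusion: dict[tuple, list[FusionRecord]] = {}
    for rec in survivors:
        by_fusion.setdefault((rec.sample, frozenset(rec.pair)), []).append(rec)

    truth: list[FusionRecord] = []
    fp_by_method: dict[str, list[FusionRecord]] = {}
    for key in sorted(by_fusion, key=lambda k: (k[0], sorted(k[1]))):
        recs = by_fusion[key]
        methods = {r.method for r in recs}
        if len(methods) >= 2:
            truth.append(recs[0])
        else:
            for r in recs:
                fp_by_method.setdefault(r.method, []).append(r)
    return ProxyTruthResult(truth=truth, fp_by_method=fp_by_method, flagged=flagged)
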