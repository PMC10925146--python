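"""Benchmark scoring: matching modes, score formulas, sweeps, proxy truth."""

from __future__ import annotations

import random

import pytest

from lrfusion import (
    Breakpoint,
    EquivalenceMap,
    FusionRecord,
    GeneModel,
    Transcript,
    build_proxy_truth_set,
    match_breakpoints,
    match_fusion_pairs,
    max_f1_over_min_reads,
    precision_recall_f1,
    score_predictions,
)


def _rec(a, b, sample="s1", bp=None, reads=0, method="m1"):
    bpa = Breakpoint("chr1", bp[0], "+") if bp else None
    bpb = Breakpoint("chr2", bp[1], "+") if bp else None
    return FusionRecord(sample, a, b, bpa, bpb, reads, method)


def brute_force_max_matching(preds, truths, edge_fn):
    """Independent oracle: exhaustive search for the maximum one-to-one matching."""

    def best(i, used):
        if i == len(preds):
            return 0
        score = best(i + 1, used)  # leave prediction i unmatched
        for j, t in enumerate(truths):
            if j not in used and preds[i].sample == t.sample and edge_fn(preds[i], t):
                score = max(score, 1 + best(i + 1, used | {j}))
        return score

    return best(0, frozenset())


class TestMatchFusionPairs:
    def test_reversed_pair_strict_vs_allow_reverse(self):
        preds = [_rec("GB", "GA")]
        truth = [_rec("GA", "GB")]
        strict = match_fusion_pairs(preds, truth, "strict")
        assert (strict.tp, strict.fp, strict.fn) == (0, 1, 1)
        rev = match_fusion_pairs(preds, truth, "allow_reverse")
        assert (rev.tp, rev.fp, rev.fn) == (1, 0, 0)

    def test_identical_pairs_match_in_both_modes(self):
        preds = [_rec("GA", "GB")]
        truth = [_rec("GA", "GB")]
        for mode in ("strict", "allow_reverse"):
            res = match_fusion_pairs(preds, truth, mode)
            assert (res.tp, res.fp, res.fn) == (1, 0, 0)

    def test_overlapping_gene_symbol_accepted_as_proxy(self):
        genes = [
            GeneModel("G1", "SYMA", "chr1", "+", [Transcript("t", ((100, 500),))]),
            GeneModel("G2", "SYMA-AS", "chr1", "-", [Transcript("t", ((300, 800),))]),
            GeneModel("G3", "SYMB", "chr2", "+", [Transcript("t", ((0, 100),))]),
        ]
        equiv = EquivalenceMap().add_overlapping_genes(genes)
        preds = [_rec("SYMA-AS", "SYMB")]
        truth = [_rec("SYMA", "SYMB")]
        res = match_fusion_pairs(preds, truth, "strict", equiv)
        assert res.tp == 1

    def test_paralog_map_symmetric_and_reflexive(self):
        em = EquivalenceMap()
        em.add("A1", "A2")
        assert em.equivalent("A1", "A2") and em.equivalent("A2", "A1")
        assert em.equivalent("A1", "A1") and em.equivalent("ZZ", "ZZ")

    def test_truth_entry_consumed_once(self):
        # two same-method predictions hitting one truth: 1 TP + 1 FP
        preds = [
            _rec("GA", "GB", bp=(100, 200), reads=5),
            _rec("GA", "GBalt", bp=(100, 300), reads=3),
        ]
        equiv = EquivalenceMap()
        equiv.add("GB", "GBalt")
        truth = [_rec("GA", "GB")]
        res = match_fusion_pairs(preds, truth, "strict", equiv)
        assert (res.tp, res.fp, res.fn) == (1, 1, 0)

    def test_duplicate_predictions_collapsed(self):
        preds = [_rec("GA", "GB", reads=3), _rec("GA", "GB", reads=7)]
        res = match_fusion_pairs(preds, [_rec("GA", "GB")], "strict")
        assert (res.tp, res.fp) == (1, 0)

    def test_strict_tp_subset_of_allow_reverse(self):
        rng = random.Random(3)
        genes = [f"G{i}" for i in range(6)]
        preds = [
            _rec(*rng.sample(genes, 2), reads=rng.randint(1, 5))
            for _ in range(15)
        ]
        truth = [_rec(*rng.sample(genes, 2)) for _ in range(8)]
        strict = match_fusion_pairs(preds, truth, "strict")
        rev = match_fusion_pairs(preds, truth, "allow_reverse")
        assert strict.tp <= rev.tp

    def test_matches_brute_force_oracle(self):
        rng = random.Random(99)
        genes = [f"G{i}" for i in range(5)]
        for _ in range(200):
            preds = [
                _rec(*rng.sample(genes, 2)) for _ in range(rng.randint(0, 8))
            ]
            truth = [
                _rec(*rng.sample(genes, 2)) for _ in range(rng.randint(0, 8))
            ]
            mode = rng.choice(["strict", "allow_reverse"])
            res = match_fusion_pairs(preds, truth, mode)
            from lrfusion.benchmark import _collapse_pairs, _pair_matches

            collapsed = _collapse_pairs(preds)
            oracle = brute_force_max_matching(
                collapsed,
                truth,
                lambda p, t: _pair_matches(p, t, mode, EquivalenceMap()),
            )
            assert res.tp == oracle
            assert res.fp == len(collapsed) - oracle
            assert res.fn == len(truth) - oracle

    def test_invariant_under_record_order(self):
        rng = random.Random(5)
        genes = [f"G{i}" for i in range(5)]
        preds = [_rec(*rng.sample(genes, 2)) for _ in range(10)]
        truth = [_rec(*rng.sample(genes, 2)) for _ in range(6)]
        r1 = match_fusion_pairs(preds, truth, "strict")
        r2 = match_fusion_pairs(preds[::-1], truth[::-1], "strict")
        assert (r1.tp, r1.fp, r1.fn) == (r2.tp, r2.fp, r2.fn)


class TestMatchBreakpoints:
    def test_fuzzy_window_boundary(self):
        truth = [_rec("GA", "GB", bp=(1000, 2000))]
        at_window = [_rec("GA", "GB", bp=(1005, 2000))]
        beyond = [_rec("GA", "GB", bp=(1006, 2000))]
        assert match_breakpoints(at_window, truth, "fuzzy", 5).tp == 1
        assert match_breakpoints(beyond, truth, "fuzzy", 5).tp == 0
        assert match_breakpoints(at_window, truth, "exact").tp == 0

    def test_identical_breakpoints_match_both_modes(self):
        truth = [_rec("GA", "GB", bp=(1000, 2000))]
        preds = [_rec("GA", "GB", bp=(1000, 2000))]
        assert match_breakpoints(preds, truth, "exact").tp == 1
        assert match_breakpoints(preds, truth, "fuzzy").tp == 1

    def test_swapped_breakpoints_sorted_before_comparison(self):
        truth = [_rec("GA", "GB", bp=(1000, 2000))]
        pred = FusionRecord(
            "s1", "GA", "GB",
            Breakpoint("chr2", 2000, "+"), Breakpoint("chr1", 1000, "+"),
        )
        assert match_breakpoints([pred], truth, "exact").tp == 1

    def test_records_without_breakpoints_excluded(self):
        truth = [_rec("GA", "GB", bp=(1000, 2000))]
        preds = [_rec("GA", "GB")]  # no breakpoints
        res = match_breakpoints(preds, truth, "exact")
        assert (res.tp, res.fp, res.fn) == (0, 0, 1)

    def test_exact_tp_subset_of_fuzzy(self):
        rng = random.Random(8)
        truth = [_rec("GA", "GB", bp=(rng.randint(0, 50), 100)) for _ in range(10)]
        preds = [_rec("GA", "GB", bp=(rng.randint(0, 50), 100)) for _ in range(10)]
        exact = match_breakpoints(preds, truth, "exact")
        for window in (0, 1, 3, 10):
            fuzzy = match_breakpoints(preds, truth, "fuzzy", window)
            assert exact.tp <= fuzzy.tp


class TestScores:
    def test_direct_formula(self):
        c = precision_recall_f1(8, 2, 2)
        assert (c.precision, c.recall, c.f1) == (0.8, 0.8, pytest.approx(0.8))

    def test_zero_cases(self):
        c = precision_recall_f1(0, 0, 5)
        assert (c.precision, c.recall, c.f1) == (0.0, 0.0, 0.0)
        z = precision_recall_f1(0, 0, 0)
        assert z.f1 == 0.0

    def test_f1_equals_p_when_p_equals_r(self):
        for tp, fpn in [(1, 1), (3, 2), (10, 5)]:
            c = precision_recall_f1(tp, fpn, fpn)
            assert c.f1 == pytest.approx(c.precision)

    def test_negative_counts_error(self):
        with pytest.raises(ValueError):
            precision_recall_f1(-1, 0, 0)

    def test_bounds_and_f1_le_max(self):
        rng = random.Random(2)
        for _ in range(100):
            c = precision_recall_f1(
                rng.randint(0, 20), rng.randint(0, 20), rng.randint(0, 20)
            )
            assert 0 <= c.precision <= 1 and 0 <= c.recall <= 1 and 0 <= c.f1 <= 1
            assert c.f1 <= max(c.precision, c.recall) + 1e-12


class TestMaxF1Sweep:
    def test_threshold_separates_fp_from_tp(self):
        truth = [_rec(f"G{i}", f"H{i}") for i in range(5)]
        preds = [_rec(f"G{i}", f"H{i}", reads=3 + i) for i in range(5)] + [
            _rec(f"X{i}", f"Y{i}", reads=1) for i in range(5)
        ]
        best_t, best_f1, sweep = max_f1_over_min_reads(preds, truth)
        assert best_f1 == pytest.approx(1.0)
        assert 2 <= best_t <= 3

    def test_single_correct_prediction(self):
        best_t, best_f1, _ = max_f1_over_min_reads(
            [_rec("GA", "GB", reads=4)], [_rec("GA", "GB")]
        )
        assert best_f1 == pytest.approx(1.0)

    def test_sweep_rows_equal_direct_scoring(self):
        rng = random.Random(4)
        genes = [f"G{i}" for i in range(6)]
        truth = [_rec(*rng.sample(genes, 2)) for _ in range(5)]
        preds = [
            _rec(*rng.sample(genes, 2), reads=rng.randint(1, 6)) for _ in range(12)
        ]
        _, _, sweep = max_f1_over_min_reads(preds, truth)
        for row in sweep.to_dict("records"):
            t = row["min_reads"]
            direct = score_predictions(
                [p for p in preds if p.reads >= t], truth
            )
            assert row["F1"] == pytest.approx(direct.f1)

    def test_empty_predictions(self):
        best_t, best_f1, sweep = max_f1_over_min_reads([], [_rec("GA", "GB")])
        assert best_f1 == 0.0 and (sweep["F1"] == 0.0).all()


class TestProxyTruth:
    def _preds(self):
        out = []
        # agreed fusion: two methods, enough reads
        out.append(_rec("GA", "GB", reads=4, method="m1"))
        out.append(_rec("GB", "GA", reads=6, method="m2"))
        # unique survivor -> FP for its method
        out.append(_rec("GC", "GD", reads=5, method="m1"))
        # low support
        out.append(_rec("GE", "GF", reads=2, method="m1"))
        return out

    def test_two_method_agreement_defines_truth(self):
        res = build_proxy_truth_set(self._preds())
        truths = {frozenset(t.pair) for t in res.truth}
        assert frozenset({"GA", "GB"}) in truths

    def test_unique_prediction_is_fp(self):
        res = build_proxy_truth_set(self._preds())
        assert [r.pair for r in res.fp_by_method["m1"]] == [("GC", "GD")]

    def test_min_read_support_filter(self):
        res = build_proxy_truth_set(self._preds())
        assert all(
            frozenset({"GE", "GF"}) != frozenset(t.pair) for t in res.truth
        )

    def test_neighbor_distance_excludes_close_pairs(self):
        coords = {
            "GA": ("chr1", 0, 10_000),
            "GB": ("chr1", 60_000, 70_000),  # 50 kb gap: excluded
            "GC": ("chr1", 200_000, 210_000),
            "GD": ("chr1", 400_000, 410_000),  # 190 kb gap: kept
        }
        preds = [
            _rec("GA", "GB", reads=5, method="m1"),
            _rec("GA", "GB", reads=5, method="m2"),
            _rec("GC", "GD", reads=5, method="m1"),
            _rec("GC", "GD", reads=5, method="m2"),
        ]
        res = build_proxy_truth_set(preds, gene_coordinates=coords)
        pairs = {frozenset(t.pair) for t in res.truth}
        assert pairs == {frozenset({"GC", "GD"})}

    def test_category_symbols_excluded(self):
        preds = [
            _rec("MT-CO1", "GB", reads=5, method="m1"),
            _rec("MT-CO1", "GB", reads=5, method="m2"),
        ]
        res = build_proxy_truth_set(preds, category_symbols=["MT-CO1"])
        assert res.truth == []

    def test_promiscuous_gene_excluded(self):
        preds = []
        for s in ("s1", "s2", "s3"):
            preds.append(_rec("PROM", "GB", sample=s, reads=5, method="m1"))
            preds.append(_rec("PROM", "GB", sample=s, reads=5, method="m2"))
        preds.append(_rec("GX", "GY", sample="s1", reads=5, method="m1"))
        preds.append(_rec("GX", "GY", sample="s1", reads=5, method="m2"))
        res = build_proxy_truth_set(preds)
        pairs = {frozenset(t.pair) for t in res.truth}
        assert frozenset({"PROM", "GB"}) not in pairs
        assert frozenset({"GX", "GY"}) in pairs

    def test_promiscuity_needs_three_samples(self):
        preds = []
        for s in ("s1", "s2"):  # only two samples
            preds.append(_rec("PROM", "GB", sample=s, reads=5, method="m1"))
            preds.append(_rec("PROM", "GB", sample=s, reads=5, method="m2"))
        res = build_proxy_truth_set(preds)
        assert {frozenset(t.pair) for t in res.truth} == {frozenset({"PROM", "GB"})}

    def test_missing_coordinate_kept_and_flagged(self):
        coords = {"GA": ("chr1", 0, 10_000)}  # GB missing
        preds = [
            _rec("GA", "GB", reads=5, method="m1"),
            _rec("GA", "GB", reads=5, method="m2"),
        ]
        res = build_proxy_truth_set(preds, gene_coordinates=coords)
        assert {frozenset(t.pair) for t in res.truth} == {frozenset({"GA", "GB"})}
        assert len(res.flagged) == 2
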