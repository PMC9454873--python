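import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import _oracles as oracle
from lidcnet import evaluation
from lidcnet.io import GoldStandard


def make_table(n: int) -> pd.DataFrame:
    """Ranked table of n proteins, already in final order."""
    return pd.DataFrame({
        "protein": [f"P{i:03d}" for i in range(n)],
        "lid": np.linspace(2, 0, n),
        "idc": 0,
        "rank": range(1, n + 1),
        "lidc": np.linspace(2, 0, n),
    })


class TestSelection:
    def test_top_k_extremes(self):
        t = make_table(5)
        assert evaluation.select_top_k(t, 5) == set(t["protein"])
        assert evaluation.select_top_k(t, 1) == {"P000"}

    def test_k_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            evaluation.select_top_k(make_table(5), 6)

    @given(st.integers(2, 30), st.integers(1, 29))
    def test_nested_selection(self, n, k):
        if k >= n:
            return
        t = make_table(n)
        assert evaluation.select_top_k(t, k) < evaluation.select_top_k(t, k + 1)

    def test_fraction_one_selects_all(self):
        t = make_table(7)
        assert evaluation.select_top_fraction(t, 1.0) == set(t["protein"])

    def test_fraction_point_two_of_ten(self):
        assert len(evaluation.select_top_fraction(make_table(10), 0.2)) == 2

    @pytest.mark.parametrize("rounding,expected", [
        ("ceil", 3), ("floor", 2), ("round", 2)])
    def test_rounding_modes(self, rounding, expected):
        # 0.2 * 11 = 2.2
        t = make_table(11)
        assert len(evaluation.select_top_fraction(t, 0.2, rounding=rounding)) \
            == expected

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            evaluation.select_top_fraction(make_table(5), 0.0)


class TestClassificationMetrics:
    def test_perfect_prediction(self):
        gold = GoldStandard(essential=frozenset({"a", "b"}))
        r = evaluation.classification_metrics({"a", "b"}, gold,
                                              {"a", "b", "c", "d"})
        assert r.precision == r.recall == r.fscore == 1.0
        assert (r.tp, r.fp, r.fn, r.tn) == (2, 0, 0, 2)

    def test_disjoint_prediction(self):
        gold = GoldStandard(essential=frozenset({"a"}))
        r = evaluation.classification_metrics({"b"}, gold, {"a", "b", "c"})
        assert r.precision == r.recall == r.fscore == 0.0

    def test_worked_confusion_table(self):
        # universe of 20, 8 essential, 10 predicted of which 6 essential
        universe = {f"u{i}" for i in range(20)}
        essential = frozenset(f"u{i}" for i in range(8))
        predicted = {f"u{i}" for i in range(6)} | {f"u{i}" for i in range(10, 14)}
        r = evaluation.classification_metrics(
            predicted, GoldStandard(essential=essential), universe)
        assert r.precision == pytest.approx(0.6)
        assert r.recall == pytest.approx(0.75)
        assert r.fscore == pytest.approx(2 * 0.6 * 0.75 / 1.35)

    def test_full_recall_denominator_switch(self):
        gold = GoldStandard(essential=frozenset({"a", "b", "z"}))  # z not in universe
        r_uni = evaluation.classification_metrics({"a"}, gold, {"a", "b", "c"})
        r_full = evaluation.classification_metrics(
            {"a"}, gold, {"a", "b", "c"}, recall_denominator="full")
        assert r_uni.recall == pytest.approx(1 / 2)
        assert r_full.recall == pytest.approx(1 / 3)

    def test_strict_gold_excludes_unlisted(self):
        gold = GoldStandard(essential=frozenset({"a"}),
                            nonessential=frozenset({"b"}))
        r = evaluation.classification_metrics({"a", "c"}, gold,
                                              {"a", "b", "c"}, strict_gold=True)
        assert r.universe_size == 2 and r.tp == 1 and r.fp == 0

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            evaluation.classification_metrics(
                set(), GoldStandard(essential=frozenset()), set())

    def test_prediction_outside_universe_rejected(self):
        with pytest.raises(ValueError):
            evaluation.classification_metrics(
                {"x"}, GoldStandard(essential=frozenset()), {"a"})

    @given(st.integers(0, 6), st.integers(0, 6), st.integers(0, 6))
    def test_fscore_is_harmonic_mean_of_emitted_counts(self, n_tp, n_fp, n_fn):
        ess = {f"e{i}" for i in range(n_tp + n_fn)}
        pred = {f"e{i}" for i in range(n_tp)} | {f"x{i}" for i in range(n_fp)}
        universe = ess | pred | {"pad"}
        r = evaluation.classification_metrics(
            pred, GoldStandard(essential=frozenset(ess)), universe)
        p = r.tp / (r.tp + r.fp) if r.tp + r.fp else 0.0
        q = r.tp / (r.tp + r.fn) if r.tp + r.fn else 0.0
        f = 2 * p * q / (p + q) if p + q else 0.0
        assert r.fscore == pytest.approx(f)

    def test_recall_nondecreasing_in_k(self):
        t = make_table(20)
        gold = GoldStandard(essential=frozenset({"P001", "P005", "P015"}))
        universe = set(t["protein"])
        recalls = [evaluation.classification_metrics(
            evaluation.select_top_k(t, k), gold, universe).recall
            for k in range(1, 21)]
        assert all(b >= a for a, b in zip(recalls, recalls[1:]))


class TestJackknife:
    def test_no_essentials_all_zero(self):
        t = make_table(8)
        curve = evaluation.jackknife_curve(
            t, GoldStandard(essential=frozenset({"zzz"})), 8)
        assert curve.tolist() == [0] * 8

    def test_all_essential_is_identity(self):
        t = make_table(6)
        curve = evaluation.jackknife_curve(
            t, GoldStandard(essential=frozenset(t["protein"])), 6)
        assert curve.tolist() == [1, 2, 3, 4, 5, 6]

    def test_matches_bruteforce_and_is_stepwise(self):
        rng = np.random.default_rng(42)
        t = make_table(30)
        gold = frozenset(rng.choice(t["protein"], size=10, replace=False))
        curve = evaluation.jackknife_curve(
            t, GoldStandard(essential=gold), 30)
        assert curve.tolist() == oracle.jackknife(list(t["protein"]), gold, 30)
        steps = np.diff(np.concatenate([[0], curve]))
        assert set(steps.tolist()) <= {0, 1}

    def test_invariant_to_nonessential_relabeling(self):
        t = make_table(10)
        gold = GoldStandard(essential=frozenset({"P002", "P007"}))
        relabeled = t.copy()
        relabeled["protein"] = [
            p if p in gold.essential else f"Q{p}" for p in t["protein"]]
        a = evaluation.jackknife_curve(t, gold, 10)
        b = evaluation.jackknife_curve(relabeled, gold, 10)
        assert a.tolist() == b.tolist()

    def test_excess_max_rank_clamped(self):
        t = make_table(5)
        curve = evaluation.jackknife_curve(
            t, GoldStandard(essential=frozenset({"P000"})), 99)
        assert len(curve) == 5
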