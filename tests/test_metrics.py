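"""Metric suite: confusion counts, exact percentages, chi-square."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from ausculta.metrics import (
    ChiSquareResult,
    ConfusionCounts,
    chi_square_2x2,
    compare_raters,
    confusion,
    f1_from_printed,
    macro_mean,
    majority_vote,
    metrics,
    report_table,
    round_half_up,
    write_report,
)
from ausculta.phenomena import CLASSES


def random_labels(rng, ids):
    return pd.DataFrame(
        {c: rng.random(len(ids)) < 0.3 for c in CLASSES}, index=ids
    )


class TestRounding:
    @pytest.mark.parametrize("x,expected", [
        (62.525, 62.5), (54.175, 54.2), (0.05, 0.1), (8.35, 8.4),
        (63.45, 63.5), (3.975, 4.0), (47.175, 47.2),
    ])
    def test_half_up_one_decimal(self, x, expected):
        assert round_half_up(Fraction(str(x))) == expected


class TestConfusion:
    def test_perfect_rater_has_no_errors(self, rng):
        ids = [f"r{i}" for i in range(20)]
        ref = random_labels(rng, ids)
        c = confusion(ref, ref.copy(), "wheeze")
        assert c.fp == c.fn == 0
        assert c.total == 20

    def test_complement_rater_has_no_correct(self, rng):
        ids = [f"r{i}" for i in range(20)]
        ref = random_labels(rng, ids)
        c = confusion(ref, ~ref, "rhonchus")
        assert c.tp == c.tn == 0

    def test_id_mismatch_listed(self, rng):
        ref = random_labels(rng, ["a", "b", "c"])
        rat = random_labels(rng, ["a", "b", "d"])
        with pytest.raises(ValueError, match="mismatch.*'c'|mismatch"):
            confusion(ref, rat, "wheeze")

    def test_matches_bruteforce_tally_on_random_pairs(self, rng):
        ids = [f"r{i}" for i in range(500)]
        ref = random_labels(rng, ids)
        rat = random_labels(rng, ids)
        for cls in CLASSES:
            c = confusion(ref, rat, cls)
            tp = fp = tn = fn = 0
            for i in ids:
                r, p = bool(ref.loc[i, cls]), bool(rat.loc[i, cls])
                tp += r and p
                fp += (not r) and p
                tn += (not r) and (not p)
                fn += r and (not p)
            assert (c.tp, c.fp, c.tn, c.fn) == (tp, fp, tn, fn)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fp=0, tn=0, fn=0)


class TestMetricSet:
    @pytest.mark.parametrize("recall,precision,f1", [
        (56.1, 34.6, 42.8),   # published doctors / coarse crackles row
        (83.9, 52.5, 64.6),   # published detector / fine crackles row
    ])
    def test_f1_is_harmonic_mean_of_printed_pair(self, recall, precision, f1):
        assert f1_from_printed(recall, precision) == f1

    def test_perfect_counts_give_all_100(self):
        m = metrics(ConfusionCounts(tp=10, fp=0, tn=5, fn=0))
        assert m.as_pct_dict() == {
            "recall": 100.0, "precision": 100.0, "specificity": 100.0, "f1": 100.0
        }

    def test_undefined_denominators_flagged_not_zero(self):
        m = metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=0))
        assert m.recall is None and m.precision is None
        assert "recall" in m.undefined and "precision" in m.undefined
        assert m.specificity == 1

    def test_zero_precision_and_recall_give_f1_zero(self):
        m = metrics(ConfusionCounts(tp=0, fp=3, tn=5, fn=2))
        assert m.f1 == 0

    def test_matches_bruteforce_rationals_on_random_tables(self, rng):
        """Exact-rational agreement with an independent implementation on
        1,000 random confusion tables."""
        for _ in range(1000):
            tp, fp, tn, fn = (int(v) for v in rng.integers(0, 40, size=4))
            m = metrics(ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn))
            if tp + fn:
                assert m.recall == Fraction(tp, tp + fn)
            else:
                assert m.recall is None
            if tp + fp:
                assert m.precision == Fraction(tp, tp + fp)
            if tn + fp:
                assert m.specificity == Fraction(tn, tn + fp)
            if tp + fn and tp + fp:
                p, r = Fraction(tp, tp + fp), Fraction(tp, tp + fn)
                expected = Fraction(0) if p == r == 0 else 2 * p * r / (p + r)
                assert m.f1 == expected


class TestMacroMean:
    def test_published_recall_row(self):
        vals = [{"recall": v, "precision": 1, "specificity": 1, "f1": 1}
                for v in (56.1, 72.3, 58.1, 67.3)]
        assert macro_mean(vals)["recall"] == 63.5

    def test_published_f1_row(self):
        vals = [{"recall": 1, "precision": 1, "specificity": 1, "f1": v}
                for v in (47.1, 64.6, 66.4, 72.0)]
        assert macro_mean(vals)["f1"] == 62.5

    def test_identical_values_are_fixed_point(self):
        vals = [{"recall": 77.7, "precision": 5.0, "specificity": 1.0, "f1": 0.1}] * 3
        assert macro_mean(vals) == {"recall": 77.7, "precision": 5.0,
                                    "specificity": 1.0, "f1": 0.1}

    def test_undefined_propagates(self):
        vals = [{"recall": 50.0, "precision": None, "specificity": 1.0, "f1": 1.0}]
        assert macro_mean(vals)["precision"] is None


class TestChiSquare:
    def test_identical_raters_give_null_result(self, rng):
        ids = [f"r{i}" for i in range(30)]
        ref = random_labels(rng, ids)
        rat = random_labels(rng, ids)
        res = compare_raters(rat, rat.copy(), ref, "wheeze")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert not res.reject

    def test_statistic_matches_direct_formula(self):
        """Sum((O-E)^2/E) computed independently for [[30,70],[60,40]]."""
        obs = np.array([[30, 70], [60, 40]], dtype=float)
        row, col, n = obs.sum(1), obs.sum(0), obs.sum()
        expected = np.outer(row, col) / n
        oracle = ((obs - expected) ** 2 / expected).sum()
        res = chi_square_2x2(obs)
        assert res.statistic == pytest.approx(oracle)
        assert res.dof == 1
        assert res.p_value == pytest.approx(1 - chi2.cdf(oracle, 1))

    def test_reject_iff_p_below_alpha(self):
        strong = chi_square_2x2(np.array([[90, 10], [10, 90]]))
        weak = chi_square_2x2(np.array([[50, 50], [52, 48]]))
        assert strong.reject and strong.p_value < 0.05
        assert not weak.reject and weak.p_value >= 0.05

    def test_symmetry_under_rater_swap(self, rng):
        ids = [f"r{i}" for i in range(40)]
        ref, a, b = (random_labels(rng, ids) for _ in range(3))
        r1 = compare_raters(a, b, ref, "fine_crackle")
        r2 = compare_raters(b, a, ref, "fine_crackle")
        assert r1.statistic == pytest.approx(r2.statistic)

    def test_small_expected_count_warns(self):
        res = chi_square_2x2(np.array([[1, 200], [0, 300]]))
        assert res.warning is not None

    def test_continuity_correction_reported(self):
        res = chi_square_2x2(np.array([[30, 70], [60, 40]]), continuity_correction=True)
        assert res.continuity_correction
        assert res.statistic < chi_square_2x2(np.array([[30, 70], [60, 40]])).statistic


class TestReportTable:
    def test_perfect_rater_all_cells_100(self, rng):
        ids = [f"r{i}" for i in range(15)]
        ref = random_labels(rng, ids)
        table = report_table(ref, {"perfect": ref.copy()})
        assert (table.loc[:, (slice(None), "perfect")].to_numpy() == 100.0).all()

    def test_cells_equal_metrics_composition(self, rng):
        ids = [f"r{i}" for i in range(60)]
        ref = random_labels(rng, ids)
        rat = random_labels(rng, ids)
        table = report_table(ref, {"r": rat})
        for cls, row in [("wheeze", "Wheezes"), ("rhonchus", "Rhonchi")]:
            m = metrics(confusion(ref, rat, cls))
            for name in ("recall", "precision", "specificity", "f1"):
                expected = m.as_pct_dict()[name]
                got = table.loc[row, (name, "r")]
                assert (got == expected) or (expected is None and pd.isna(got))

    def test_write_report_outputs(self, tmp_path, rng):
        ids = [f"r{i}" for i in range(10)]
        ref = random_labels(rng, ids)
        table = report_table(ref, {"x": ref.copy()})
        write_report(table, tmp_path)
        assert (tmp_path / "report.csv").exists()
        assert "Mean" in (tmp_path / "report.txt").read_text()


def test_majority_vote_ties_positive(rng):
    ids = ["a", "b"]
    t1 = pd.DataFrame({c: [True, False] for c in CLASSES}, index=ids)
    t2 = pd.DataFrame({c: [False, False] for c in CLASSES}, index=ids)
    pooled = majority_vote([t1, t2])
    assert pooled.loc["a", "wheeze"] == True  # 1 of 2 -> tie -> positive
    assert pooled.loc["b", "wheeze"] == False
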