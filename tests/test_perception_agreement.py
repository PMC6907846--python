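"""Forced-choice accuracy, contingency statistics and agreement coefficients."""

import numpy as np
import pytest

from emgsmile import (
    ContingencyTable2x2,
    JudgmentRecord,
    accuracy_summary,
    build_table,
    chi_square_2x2,
    cohens_kappa,
    fleiss_kappa,
    judged_label_table,
    load_ethnicity_table,
    load_judgment_table,
    ttest_vs_chance,
)
from emgsmile.io_core import EmptyInputError
from emgsmile.perception_agreement import round_percent


def _records_from_correctness(table, ethnicity_mode=False):
    """Expand a correctness table into individual judgment records."""
    records = []
    k = 0
    for i, row_label in enumerate(table.row_labels):
        wrong, right = table.counts[i]
        if ethnicity_mode:
            pe, pr = ("A", "A") if row_label == "match" else ("A", "B")
            true_types = ["posed"]  # irrelevant to the ethnicity table
        else:
            pe = pr = ""
            true_types = [row_label]
        for correct, n in ((False, wrong), (True, right)):
            for _ in range(int(n)):
                true_type = true_types[0]
                judged = true_type if correct else ("spontaneous" if true_type == "posed" else "posed")
                records.append(JudgmentRecord(f"perc{k % 73}", f"stim{k % 54}", "prod",
                                              true_type, judged, 50.0, pe, pr))
                k += 1
    return records


class TestAccuracySummary:
    def test_published_counts_round_to_57_and_58_percent(self):
        records = _records_from_correctness(load_judgment_table())
        summary = accuracy_summary(records)
        assert round_percent(summary["by_true_type"]["posed"]) == 57
        assert round_percent(summary["by_true_type"]["spontaneous"]) == 58
        assert summary["n"] == 3942

    def test_all_correct(self):
        records = [JudgmentRecord("a", "s", "p", "posed", "posed")] * 3
        s = accuracy_summary(records)
        assert s["overall"] == 1.0 and s["by_true_type"]["posed"] == 1.0

    def test_empty_rejected(self):
        with pytest.raises(EmptyInputError):
            accuracy_summary([])

    def test_random_judges_concentrate_at_half(self, rng):
        types = np.array(["posed", "spontaneous"])
        records = [
            JudgmentRecord(f"perc{i % 50}", f"s{j}", "p", t, rng.choice(types))
            for i in range(50) for j, t in enumerate(rng.choice(types, size=54))
        ]
        s = accuracy_summary(records)
        accs = np.array(list(s["per_perceiver"].values()))
        se = 0.5 / np.sqrt(len(records))
        assert abs(s["overall"] - 0.5) < 3 * se
        assert 0.3 < accs.mean() < 0.7


class TestBuildTable:
    def test_reconstructs_judged_label_counts(self):
        records = _records_from_correctness(load_judgment_table())
        table = build_table(records, "true_type", "judged_type")
        by = {
            (r, c): table.counts[i, j]
            for i, r in enumerate(table.row_labels)
            for j, c in enumerate(table.col_labels)
        }
        assert by[("posed", "posed")] == 1201
        assert by[("posed", "spontaneous")] == 902
        assert by[("spontaneous", "posed")] == 770
        assert by[("spontaneous", "spontaneous")] == 1069

    def test_ethnic_match_by_correctness(self):
        records = _records_from_correctness(load_ethnicity_table(), ethnicity_mode=True)
        table = build_table(records, "ethnic_match", "correct")
        by = {
            (r, c): table.counts[i, j]
            for i, r in enumerate(table.row_labels)
            for j, c in enumerate(table.col_labels)
        }
        assert by[("mismatch", "correct")] == 1081
        assert by[("mismatch", "incorrect")] == 845
        assert by[("match", "correct")] == 1189
        assert by[("match", "incorrect")] == 827

    def test_single_record(self):
        with pytest.raises(ValueError, match="binary"):
            build_table([JudgmentRecord("a", "s", "p", "posed", "posed")], "true_type", "judged_type")

    def test_non_binary_factor_rejected(self):
        records = [
            JudgmentRecord("a", "s", "p", "posed", "posed", 50, e, e)
            for e in ("x", "y", "z")
        ]
        with pytest.raises(ValueError, match="binary"):
            build_table(records, "perceiver_ethnicity", "producer_ethnicity")


class TestChiSquare:
    def test_flat_table_is_independent(self):
        table = ContingencyTable2x2(np.array([[50, 50], [50, 50]]), ("a", "b"), ("x", "y"))
        chi2, df, p = chi_square_2x2(table)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)
        assert df == 1

    def test_invariant_under_row_and_column_swaps(self):
        counts = np.array([[1201, 902], [770, 1069]])
        base = chi_square_2x2(ContingencyTable2x2(counts, ("r1", "r2"), ("c1", "c2")))[0]
        for swapped in (counts[::-1], counts[:, ::-1], counts[::-1, ::-1], counts.T):
            chi2 = chi_square_2x2(ContingencyTable2x2(swapped, ("r1", "r2"), ("c1", "c2")))[0]
            assert chi2 == pytest.approx(base)

    def test_corrected_below_uncorrected(self):
        table = judged_label_table(load_judgment_table())
        corrected = chi_square_2x2(table, continuity_correction=True)[0]
        uncorrected = chi_square_2x2(table, continuity_correction=False)[0]
        assert corrected < uncorrected

    def test_zero_margin_rejected(self):
        table = ContingencyTable2x2(np.array([[0, 0], [5, 5]]), ("a", "b"), ("x", "y"))
        with pytest.raises(ValueError, match="margin"):
            chi_square_2x2(table)


class TestCohensKappa:
    def test_perfect_agreement(self):
        a = ["x", "y", "x", "z", "y"]
        assert cohens_kappa(a, list(a)) == pytest.approx(1.0)

    def test_worked_example(self):
        # agreement table [[20,5],[10,15]]: p_o = 0.7, p_e = 0.5 -> kappa 0.4
        a = ["p"] * 25 + ["s"] * 25
        b = ["p"] * 20 + ["s"] * 5 + ["p"] * 10 + ["s"] * 15
        assert cohens_kappa(a, b) == pytest.approx(0.40)

    def test_independent_raters_near_zero(self, rng):
        a = rng.choice(["p", "s"], size=10_000)
        b = rng.choice(["p", "s"], size=10_000)
        assert abs(cohens_kappa(a, b)) < 0.03

    def test_constant_identical_raters(self):
        assert cohens_kappa(["p", "p"], ["p", "p"]) == 1.0

    def test_constant_disagreeing_raters_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            cohens_kappa(["p", "p"], ["s", "s"])

    def test_kappa_never_exceeds_one(self, rng):
        for _ in range(20):
            a = rng.choice(["p", "s"], size=50)
            b = np.where(rng.random(50) < 0.8, a, rng.choice(["p", "s"], size=50))
            assert cohens_kappa(a, b) <= 1.0 + 1e-12


class TestFleissKappa:
    def test_unanimous(self):
        ratings = [["a", "a", "a"], ["b", "b", "b"], ["a", "a", "a"]]
        assert fleiss_kappa(ratings) == pytest.approx(1.0)

    def test_independent_raters_near_zero(self, rng):
        ratings = rng.choice(["p", "s"], size=(10_000, 3))
        assert abs(fleiss_kappa(ratings)) < 0.03

    def test_matches_brute_force_formula(self):
        ratings = [
            ["a", "a", "b"],
            ["b", "b", "b"],
            ["a", "b", "b"],
            ["a", "a", "a"],
        ]
        # brute force: P_i = (sum_j n_ij^2 - n) / (n(n-1)); p_j from pooled counts
        counts = np.array([[2, 1], [0, 3], [1, 2], [3, 0]], dtype=float)
        n = 3
        p_i = ((counts**2).sum(axis=1) - n) / (n * (n - 1))
        p_j = counts.sum(axis=0) / counts.sum()
        expected = (p_i.mean() - (p_j**2).sum()) / (1 - (p_j**2).sum())
        assert fleiss_kappa(ratings) == pytest.approx(expected)

    def test_missing_rating_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            fleiss_kappa([["a", "b", None], ["a", "a", "b"]])


class TestTTestVsChance:
    def test_all_at_chance(self):
        t, df, p, d = ttest_vs_chance([0.5] * 10)
        assert (t, p, d) == (0.0, 1.0, 0.0)
        assert df == 9

    def test_closed_form_hand_case(self):
        accs = [0.6] * 9 + [0.5]
        t, df, p, d = ttest_vs_chance(accs)
        mean, sd = np.mean(accs), np.std(accs, ddof=1)
        assert t == pytest.approx((mean - 0.5) / (sd / np.sqrt(10)))
        assert d == pytest.approx((mean - 0.5) / sd)
        assert df == 9

    def test_zero_variance_above_chance(self):
        t, df, p, d = ttest_vs_chance([0.7] * 5)
        assert np.isinf(t) and t > 0 and p == 0.0

    def test_rejection_rate_near_alpha_for_chance_judges(self):
        from emgsmile.io_core import child_rng

        rng = child_rng(0, "chance-judges")
        reps, n_judges, n_trials = 400, 20, 54
        hits = 0
        for _ in range(reps):
            accs = rng.binomial(n_trials, 0.5, size=n_judges) / n_trials
            hits += ttest_vs_chance(accs)[2] < 0.05
        assert hits / reps == pytest.approx(0.05, abs=0.03)
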