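"""Reader-study metrics and Fleiss' kappa against hand-derived references."""

import numpy as np
import pandas as pd
import pytest

from cyclect import reader_eval

# Published panel: (sensitivity, specificity) per expert on 100+100 slices
PANEL_RATES = [(0.80, 0.62), (0.92, 0.13), (0.82, 0.23)]


@pytest.fixture(scope="module")
def panel():
    return [reader_eval.confusion_from_rates(s, sp, 100, 100) for s, sp in PANEL_RATES]


class TestConfusionFromRates:
    def test_reconstructed_counts(self):
        c = reader_eval.confusion_from_rates(0.8, 0.62, 100, 100)
        assert (c.tp, c.fn, c.tn, c.fp) == (80, 20, 62, 38)

    def test_perfect_rater_no_errors(self):
        c = reader_eval.confusion_from_rates(1.0, 1.0, 50, 50)
        assert c.fp == 0 and c.fn == 0

    def test_non_integral_product_rejected(self):
        with pytest.raises(ValueError, match="not an integer"):
            reader_eval.confusion_from_rates(0.805, 0.5, 100, 100)

    def test_rate_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            reader_eval.confusion_from_rates(1.2, 0.5, 10, 10)


class TestReaderMetrics:
    @pytest.mark.parametrize(
        "rates,auc,accuracy",
        [
            ((0.80, 0.62), 0.71, 0.71),
            ((0.92, 0.13), 0.525, 0.525),
            ((0.82, 0.23), 0.525, 0.525),
        ],
    )
    def test_panel_operating_points(self, rates, auc, accuracy):
        c = reader_eval.confusion_from_rates(*rates, 100, 100)
        m = reader_eval.reader_metrics(c)
        assert m["auc"] == pytest.approx(auc)
        assert m["accuracy"] == pytest.approx(accuracy)

    def test_perfect_rater(self):
        m = reader_eval.reader_metrics(reader_eval.ReaderConfusion(10, 0, 10, 0))
        assert m["accuracy"] == m["auc"] == 1.0
        assert m["fpr"] == 0.0

    def test_uninformative_rater_auc_half(self):
        c = reader_eval.confusion_from_rates(0.7, 0.3, 10, 10)
        assert reader_eval.reader_metrics(c)["auc"] == pytest.approx(0.5)


class TestPanelSummary:
    def test_published_panel_means(self, panel):
        s = reader_eval.panel_summary(panel)
        assert s["mean_accuracy"] == pytest.approx(0.587, abs=5e-4)
        assert s["accuracy_min"] == pytest.approx(0.525)
        assert s["accuracy_max"] == pytest.approx(0.71)
        assert s["mean_fpr_on_synthetic"] == pytest.approx(0.67, abs=5e-3)

    def test_single_perfect_reader(self):
        s = reader_eval.panel_summary([reader_eval.ReaderConfusion(5, 0, 5, 0)])
        assert s["mean_accuracy"] == 1.0
        assert s["mean_fpr_on_synthetic"] == 0.0


class TestFleissKappa:
    def test_perfect_agreement_balanced_margins(self):
        r = reader_eval.RatingMatrix(np.array([[2, 0], [0, 2]]), 2)
        out = reader_eval.fleiss_kappa(r)
        assert out == {"kappa": 1.0, "p_bar": 1.0, "p_bar_e": 0.5}

    def test_hand_derived_partial_disagreement(self):
        r = reader_eval.RatingMatrix(np.array([[2, 0], [1, 1]]), 2)
        out = reader_eval.fleiss_kappa(r)
        assert out["p_bar"] == pytest.approx(0.5)
        assert out["p_bar_e"] == pytest.approx(0.625)
        assert out["kappa"] == pytest.approx(-1.0 / 3.0)

    def test_maximal_disagreement(self):
        r = reader_eval.RatingMatrix(np.array([[1, 1], [1, 1]]), 2)
        out = reader_eval.fleiss_kappa(r)
        assert out["kappa"] == pytest.approx(-1.0)

    def test_single_category_undefined(self):
        with pytest.raises(ZeroDivisionError):
            reader_eval.fleiss_kappa(reader_eval.RatingMatrix(np.array([[3, 0], [3, 0]]), 3))

    def test_category_and_item_permutation_invariance(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(2, 6))
            big_n = int(rng.integers(2, 12))
            k = int(rng.integers(2, 5))
            counts = rng.multinomial(n, np.ones(k) / k, size=big_n)
            r = reader_eval.RatingMatrix(counts, n)
            try:
                base = reader_eval.fleiss_kappa(r)["kappa"]
            except ZeroDivisionError:
                continue
            perm_c = counts[:, rng.permutation(k)]
            perm_i = counts[rng.permutation(big_n)]
            assert reader_eval.fleiss_kappa(reader_eval.RatingMatrix(perm_c, n))["kappa"] == pytest.approx(base)
            assert reader_eval.fleiss_kappa(reader_eval.RatingMatrix(perm_i, n))["kappa"] == pytest.approx(base)

    def test_concentrated_rows_give_kappa_one(self):
        counts = np.array([[3, 0], [0, 3], [3, 0], [0, 3], [3, 0]])
        assert reader_eval.fleiss_kappa(reader_eval.RatingMatrix(counts, 3))["kappa"] == pytest.approx(1.0)

    def test_matches_statsmodels_reference(self):
        """Independent cross-check on random rating matrices."""
        from statsmodels.stats.inter_rater import fleiss_kappa as sm_fleiss

        rng = np.random.default_rng(3)
        for _ in range(20):
            counts = rng.multinomial(4, [0.5, 0.3, 0.2], size=10)
            r = reader_eval.RatingMatrix(counts, 4)
            ours = reader_eval.fleiss_kappa(r)["kappa"]
            theirs = sm_fleiss(counts, method="fleiss")
            assert ours == pytest.approx(theirs, abs=1e-12)


class TestRatingTables:
    def test_long_table_pivot_round_trip(self):
        table, realized = reader_eval.simulate_ratings(PANEL_RATES, 20, 20, seed=4)
        matrix = reader_eval.ratings_from_long(table)
        assert matrix.counts.shape == (40, 2)
        assert matrix.n_raters == 3
        assert matrix.counts.sum() == 120

    def test_simulated_confusions_consistent_with_table(self):
        table, realized = reader_eval.simulate_ratings([(1.0, 1.0)], 5, 7, seed=0)
        c = realized[0]
        assert (c.tp, c.fn, c.tn, c.fp) == (5, 0, 7, 0)
        assert (table["category"] == "real").sum() == 5

    def test_unbalanced_rater_counts_rejected(self):
        table = pd.DataFrame(
            {
                "item_id": ["a", "a", "b"],
                "reader_id": ["r1", "r2", "r1"],
                "category": ["real", "real", "synthetic"],
            }
        )
        with pytest.raises(ValueError, match="same number"):
            reader_eval.ratings_from_long(table)
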