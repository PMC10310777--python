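"""Feature filtering, drift statistics, ROC and bootstrap comparison."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cyclect import drift_eval


@pytest.fixture()
def toy_table(rng):
    f1 = rng.normal(0, 1, 20)
    return pd.DataFrame(
        {
            "f1": f1,
            "f2": f1 + rng.normal(0, 0.05, 20),  # corr ~0.99 with f1
            "f3": rng.normal(0, 1, 20),
        }
    )


class TestDropCorrelated:
    def test_identical_columns_keep_exactly_one(self, rng):
        x = rng.normal(0, 1, 30)
        table = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(0, 1, 30)})
        out = drift_eval.drop_correlated(table, 0.9)
        assert len([c for c in out.columns if c in ("a", "b")]) == 1
        assert "c" in out.columns

    def test_near_duplicate_removed_independent_kept(self, toy_table):
        out = drift_eval.drop_correlated(toy_table, 0.9)
        assert out.shape[1] == 2
        assert "f3" in out.columns

    def test_threshold_one_keeps_everything(self, toy_table):
        assert drift_eval.drop_correlated(toy_table, 1.0).shape[1] == 3

    def test_zero_variance_removed_with_warning(self, toy_table):
        toy_table["const"] = 1.0
        with pytest.warns(UserWarning, match="zero-variance"):
            out = drift_eval.drop_correlated(toy_table, 0.9)
        assert "const" not in out.columns

    def test_postcondition_no_surviving_pair_above_threshold(self, rng):
        base = rng.normal(0, 1, (50, 3))
        mix = base @ rng.normal(0, 1, (3, 10))  # strongly collinear panel
        table = pd.DataFrame(mix, columns=[f"g{i}" for i in range(10)])
        out = drift_eval.drop_correlated(table, 0.9)
        corr = out.corr().abs().to_numpy()
        np.fill_diagonal(corr, 0.0)
        assert corr.max() <= 0.9 + 1e-12

    def test_deterministic_under_column_name_ties(self, rng):
        x = rng.normal(0, 1, 40)
        table = pd.DataFrame({"b": x, "a": x.copy()})
        out1 = drift_eval.drop_correlated(table, 0.5)
        out2 = drift_eval.drop_correlated(table, 0.5)
        assert list(out1.columns) == list(out2.columns) == ["a"]


def _kendall_tau_brute(x, y):
    """O(n^2) concordant/discordant pair count with tie correction (tau-b)."""
    n = len(x)
    conc = disc = tx = ty = 0
    for i, j in itertools.combinations(range(n), 2):
        dx, dy = x[i] - x[j], y[i] - y[j]
        if dx == 0 and dy == 0:
            tx += 1
            ty += 1
        elif dx == 0:
            tx += 1
        elif dy == 0:
            ty += 1
        elif dx * dy > 0:
            conc += 1
        else:
            disc += 1
    n0 = n * (n - 1) / 2
    return (conc - disc) / np.sqrt((n0 - tx) * (n0 - ty))


class TestKendallSelect:
    def test_label_equal_feature_kept(self):
        y = np.array([0, 1, 0, 1, 1, 0, 1, 0])
        table = pd.DataFrame({"same": y.astype(float), "anti": -y.astype(float)})
        out = drift_eval.kendall_select(table, y, 0.2)
        assert set(out.columns) == {"same", "anti"}  # |tau| = 1 both ways

    def test_independent_feature_dropped_and_matches_brute_force(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, 200)
        y = rng.integers(0, 2, 200)
        from scipy.stats import kendalltau

        tau = kendalltau(x, y, variant="b").statistic
        assert tau == pytest.approx(_kendall_tau_brute(x, y.astype(float)), abs=1e-12)
        assert abs(tau) < 0.15
        out = drift_eval.kendall_select(pd.DataFrame({"x": x}), y, 0.2)
        assert out.shape[1] == 0

    def test_invariant_under_monotone_transform(self, rng):
        x = rng.normal(0, 1, 60)
        y = (x + rng.normal(0, 1, 60) > 0).astype(int)
        t1 = drift_eval.kendall_select(pd.DataFrame({"x": x}), y, 0.0)
        t2 = drift_eval.kendall_select(pd.DataFrame({"x": np.exp(3 * x)}), y, 0.0)
        assert t1.shape[1] == t2.shape[1] == 1

    def test_constant_labels_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            drift_eval.kendall_select(pd.DataFrame({"x": [1.0, 2.0]}), [1, 1], 0.2)


class TestAbsPctDiff:
    def test_no_change_gives_zero(self, rng):
        pre = pd.DataFrame(rng.normal(5, 1, (4, 3)), columns=list("abc"))
        out = drift_eval.abs_pct_diff(pre, pre.copy())
        assert float(out.drift.max().max()) == 0.0
        assert int(out.excluded.sum()) == 0

    def test_five_hundred_percent_case(self):
        pre = pd.DataFrame({"f": [2.0]})
        post = pd.DataFrame({"f": [12.0]})
        assert float(drift_eval.abs_pct_diff(pre, post).drift.iloc[0, 0]) == pytest.approx(500.0)

    def test_zero_denominator_excluded_and_tallied(self):
        pre = pd.DataFrame({"f": [0.0, 2.0]})
        post = pd.DataFrame({"f": [1.0, 3.0]})
        out = drift_eval.abs_pct_diff(pre, post)
        assert np.isnan(out.drift.iloc[0, 0])
        assert out.excluded["f"] == 1

    def test_misaligned_tables_rejected(self):
        pre = pd.DataFrame({"f": [1.0]}, index=["s1"])
        post = pd.DataFrame({"f": [1.0]}, index=["s2"])
        with pytest.raises(ValueError, match="misaligned"):
            drift_eval.abs_pct_diff(pre, post)


class TestRocAuc:
    def test_perfect_separation(self):
        assert drift_eval.roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties_give_half(self):
        assert drift_eval.roc_auc([0.5] * 6, [0, 0, 0, 1, 1, 1]) == 0.5

    def test_hand_case_matches_pair_enumeration(self):
        scores = [0.1, 0.4, 0.35, 0.8]
        labels = [0, 0, 1, 1]
        pos = [s for s, l in zip(scores, labels) if l == 1]
        neg = [s for s, l in zip(scores, labels) if l == 0]
        brute = np.mean([(p > n) + 0.5 * (p == n) for p in pos for n in neg])
        assert brute == pytest.approx(0.75)
        assert drift_eval.roc_auc(scores, labels) == pytest.approx(0.75)

    def test_negation_complements(self, rng):
        s = rng.normal(0, 1, 40)
        y = rng.integers(0, 2, 40)
        if len(np.unique(y)) == 2:
            assert drift_eval.roc_auc(s, y) + drift_eval.roc_auc(-s, y) == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            drift_eval.roc_auc([0.1, 0.2], [1, 1])


class TestBootstrapCompare:
    def test_identical_scores_null_result(self, rng):
        y = np.r_[np.ones(20), np.zeros(20)]
        s = rng.normal(0, 1, 40)
        out = drift_eval.bootstrap_auc_compare(s, s.copy(), y, n_boot=200, seed=0)
        assert out["delta_auc"] == 0.0
        assert out["p_value"] == pytest.approx(1.0)

    def test_opposite_scores_significant(self):
        rng = np.random.default_rng(1)
        y = np.r_[np.ones(50), np.zeros(50)]
        s1 = y + 0.1 * rng.normal(0, 1, 100)  # near-perfect
        out = drift_eval.bootstrap_auc_compare(s1, -s1, y, n_boot=500, seed=2)
        assert out["p_value"] < 0.01

    def test_seeded_determinism(self, rng):
        y = np.r_[np.ones(15), np.zeros(15)]
        s1 = rng.normal(0, 1, 30)
        s2 = rng.normal(0, 1, 30)
        o1 = drift_eval.bootstrap_auc_compare(s1, s2, y, n_boot=300, seed=9)
        o2 = drift_eval.bootstrap_auc_compare(s1, s2, y, n_boot=300, seed=9)
        assert o1 == o2

    def test_small_n_boot_warns(self, rng):
        y = np.r_[np.ones(10), np.zeros(10)]
        s = rng.normal(0, 1, 20)
        with pytest.warns(UserWarning, match="small"):
            drift_eval.bootstrap_auc_compare(s, s, y, n_boot=50, seed=0)


class TestFirstOrderFeatures:
    def test_region_statistics(self, rng):
        values = rng.normal(100, 10, (6, 6, 6))
        mask = np.zeros((6, 6, 6), dtype=bool)
        mask[2:4] = True
        out = drift_eval.first_order_features(values, {"roi": mask})
        assert out["roi_mean"] == pytest.approx(values[mask].mean())
        assert set(out) == {"roi_mean", "roi_sd", "roi_p10", "roi_median", "roi_p90", "roi_energy"}

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            drift_eval.first_order_features(np.ones((3, 3, 3)), {"roi": np.zeros((3, 3, 3), bool)})
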