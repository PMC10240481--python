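"""Classification, ranking, significance, and coverage-grid metrics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from litriage import (
    ContingencyCounts,
    PredictionSimulatorConfig,
    ProbabilityMatrix,
    UNKNOWN,
    bootstrap_ci,
    confusion,
    contingency,
    evaluate_level,
    f1,
    fp_rate,
    kvote_grid,
    mcnemar,
    micro_macro,
    pr_curve,
    precision,
    ranking_metrics,
    recall,
    roc_auc,
    simulate_predictions,
)
from litriage.metrics import per_label_counts


class TestContingency:
    @pytest.mark.parametrize(
        "y_true,y_pred,label,expected",
        [
            (["A", "A", "B"], ["A", "B", "B"], "A", (1, 0, 1, 1)),
            (["A", "B", "B"], ["A", "B", "B"], "A", (1, 0, 0, 2)),  # perfect
            (["A", "B", "B"], ["A", "A", "A"], "A", (1, 2, 0, 0)),  # all predicted A
        ],
    )
    def test_counts(self, y_true, y_pred, label, expected):
        c = contingency(y_true, y_pred, label)
        assert (c.tp, c.fp, c.fn, c.tn) == expected
        assert c.n == len(y_true)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            contingency(["A"], ["A", "B"], "A")


class TestFormulaMetrics:
    def test_printed_formulas(self):
        c = ContingencyCounts(tp=3, fp=1, fn=2, tn=4)
        assert precision(c) == pytest.approx(3 / 4)
        assert recall(c) == pytest.approx(3 / 5)
        assert f1(c) == pytest.approx(2 * 0.75 * 0.6 / (0.75 + 0.6))
        assert fp_rate(c) == pytest.approx(1 / 5)

    def test_f1_fixed_point(self):
        # when precision == recall == p, the harmonic mean is p itself
        c = ContingencyCounts(tp=3, fp=1, fn=1, tn=5)
        assert precision(c) == recall(c) == f1(c) == pytest.approx(0.75)

    def test_zero_denominator_convention(self):
        never_predicted = ContingencyCounts(tp=0, fp=0, fn=4, tn=6)
        assert precision(never_predicted) == 0.0
        assert f1(never_predicted) == 0.0
        no_positives = ContingencyCounts(tp=0, fp=2, fn=0, tn=8)
        assert recall(no_positives) == 0.0
        assert f1(no_positives) == 0.0


class TestMicroMacro:
    def test_micro_equals_accuracy_multiclass(self):
        rng = np.random.default_rng(3)
        labels = ["A", "B", "C", "D"]
        y_true = rng.choice(labels, 200)
        y_pred = rng.choice(labels, 200)
        agg = micro_macro(per_label_counts(y_true, y_pred, labels))
        acc = float(np.mean(y_true == y_pred))
        assert agg["micro_precision"] == agg["micro_recall"] == agg["micro_f1"]
        assert agg["micro_f1"] == pytest.approx(acc)

    def test_macro_is_unweighted_mean(self):
        counts = {
            "A": ContingencyCounts(tp=4, fp=1, fn=1, tn=4),  # F1 = 0.8
            "B": ContingencyCounts(tp=1, fp=2, fn=1, tn=6),  # F1 = 0.4
        }
        agg = micro_macro(counts)
        assert agg["macro_f1"] == pytest.approx(0.6)

    def test_dominant_label_moves_micro_not_macro(self):
        # 90 docs of A predicted perfectly, 10 of B always missed:
        # micro tracks the dominant label, macro punishes the rare one
        y_true = ["A"] * 90 + ["B"] * 10
        y_pred = ["A"] * 100
        agg = micro_macro(per_label_counts(y_true, y_pred, ["A", "B"]))
        assert agg["micro_f1"] >= 0.9
        assert agg["macro_f1"] < 0.5
        assert agg["macro_f1"] < agg["micro_f1"]


class TestConfusion:
    def test_shapes_and_totals(self, tax):
        leaves = list(tax.leaf_order)
        rng = np.random.default_rng(5)
        y_true = rng.choice(leaves, 50)
        y_pred = rng.choice(leaves, 50)
        m = confusion(y_true, y_pred, tax, "sub-subclass")
        assert m.shape == (22, 22)
        assert m.to_numpy().sum() == 50
        row_sums = m.sum(axis=1)
        for leaf in leaves:
            assert row_sums[leaf] == np.sum(y_true == leaf)

    def test_perfect_prediction_is_diagonal(self, tax):
        y = ["EPI", "BASIC", "OTHER", "EPI"]
        m = confusion(y, y, tax, "subclass")
        assert (m.to_numpy() == np.diag(np.diag(m.to_numpy()))).all()

    def test_constant_prediction_single_column(self, tax):
        y_true = ["EPI", "BASIC", "OTHER"]
        m = confusion(y_true, ["EPI"] * 3, tax, "subclass")
        assert m["EPI"].sum() == 3 and m.to_numpy().sum() == 3


def _binary_matrix(tax, p_original):
    """Rows with the given rolled-up ORIGINAL probability."""
    values = np.zeros((len(p_original), 22))
    i_orig = tax.leaf_order.index("EPI: Case report")
    i_non = tax.leaf_order.index("OTHER: Other")
    for i, p in enumerate(p_original):
        values[i, i_orig] = p
        values[i, i_non] = 1 - p
    return ProbabilityMatrix([f"d{i}" for i in range(len(p_original))], list(tax.leaf_order), values)


class TestRocAuc:
    def test_perfect_separation(self, tax):
        y_true = ["EPI: Case report"] * 5 + ["OTHER: Other"] * 5
        probs = _binary_matrix(tax, [0.9] * 5 + [0.1] * 5)
        macro, per = roc_auc(y_true, probs, tax, "class")
        assert macro == 1.0

    def test_reversal_symmetry(self, tax):
        rng = np.random.default_rng(6)
        y_true = list(rng.choice(["EPI: Case report", "OTHER: Other"], 60))
        scores = rng.random(60)
        auc_fwd, _ = roc_auc(y_true, _binary_matrix(tax, scores), tax, "class")
        auc_rev, _ = roc_auc(y_true, _binary_matrix(tax, 1 - scores), tax, "class")
        assert auc_fwd == pytest.approx(1 - auc_rev, abs=1e-12)

    def test_uninformative_scores_near_half(self, tax):
        rng = np.random.default_rng(11)
        y_true = list(rng.choice(["EPI: Case report", "OTHER: Other"], 2000))
        probs = _binary_matrix(tax, rng.random(2000))
        macro, _ = roc_auc(y_true, probs, tax, "class")
        assert macro == pytest.approx(0.5, abs=0.05)

    def test_matches_mann_whitney_u(self, tax):
        # AUC == U / (n_pos * n_neg): the rank-sum formulation is the oracle
        rng = np.random.default_rng(8)
        y = rng.choice([True, False], 80)
        s = rng.random(80)
        y_true = ["EPI: Case report" if t else "OTHER: Other" for t in y]
        _, per = roc_auc(y_true, _binary_matrix(tax, s), tax, "class")
        u = stats.mannwhitneyu(s[y], s[~y], alternative="two-sided").statistic
        assert per["ORIGINAL"] == pytest.approx(u / (y.sum() * (~y).sum()), abs=1e-12)

    def test_absent_label_skipped_with_warning(self, tax):
        y_true = ["EPI: Case report"] * 10  # NON-ORIGINAL never occurs
        probs = _binary_matrix(tax, np.linspace(0.2, 0.9, 10))
        with pytest.warns(UserWarning, match="skipped"):
            with pytest.raises(ValueError):
                roc_auc(y_true, probs, tax, "class")


class TestBootstrap:
    def test_constant_metric_degenerate_interval(self):
        res = bootstrap_ci(lambda x: 1.0, np.arange(30), n_boot=100, seed=0)
        assert res.point == res.lower == res.upper == 1.0

    def test_interval_brackets_point(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=200)
        res = bootstrap_ci(np.mean, x, n_boot=500, seed=2)
        assert res.lower <= res.point <= res.upper

    def test_bit_reproducible_from_seed(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=100), rng.normal(size=100)
        metric = lambda a, b: float(np.corrcoef(a, b)[0, 1])
        r1 = bootstrap_ci(metric, x, y, n_boot=300, seed=42)
        r2 = bootstrap_ci(metric, x, y, n_boot=300, seed=42)
        assert (r1.lower, r1.upper) == (r2.lower, r2.upper)

    def test_more_resamples_reduce_percentile_jitter(self):
        rng = np.random.default_rng(3)
        x = rng.exponential(size=150)
        uppers_small, uppers_large = [], []
        for seed in range(20):
            uppers_small.append(bootstrap_ci(np.mean, x, n_boot=100, seed=seed).upper)
            uppers_large.append(bootstrap_ci(np.mean, x, n_boot=800, seed=seed).upper)
        assert np.std(uppers_large) < np.std(uppers_small)

    def test_undefined_resamples_redrawn_and_counted(self):
        # metric defined only when both classes appear in the resample
        y = np.array([True] * 2 + [False] * 28)

        def rate_ratio(v):
            if v.all() or not v.any():
                raise ValueError("one-class resample")
            return float(v.mean())

        res = bootstrap_ci(rate_ratio, y, n_boot=200, seed=5)
        assert res.n_redrawn > 0
        assert np.isfinite(res.lower) and np.isfinite(res.upper)

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci(np.mean, np.array([]))


class TestMcNemar:
    def test_symmetric_discordance_p_near_one(self):
        a = [True] * 5 + [False] * 5 + [True] * 10
        b = [False] * 5 + [True] * 5 + [True] * 10
        res = mcnemar(a, b)
        assert res.b == res.c == 5
        assert res.p_value >= 0.99

    def test_one_sided_discordance_exact(self):
        # b=10, c=0: exact two-sided p = 2 * (1/2)^10
        a = [True] * 10 + [True] * 5
        b = [False] * 10 + [True] * 5
        res = mcnemar(a, b)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(2 * 0.5**10, abs=1e-12)

    def test_chi2_continuity_correction(self):
        a = np.concatenate([np.ones(40), np.zeros(20), np.ones(40)]).astype(bool)
        b = np.concatenate([np.zeros(40), np.ones(20), np.ones(40)]).astype(bool)
        res = mcnemar(a, b)
        assert res.method == "chi2"
        assert res.statistic == pytest.approx(361 / 60)
        assert res.p_value == pytest.approx(float(stats.chi2.sf(361 / 60, 1)), abs=1e-12)

    def test_no_discordance(self):
        res = mcnemar([True, False], [True, False])
        assert res.statistic == 0.0 and res.p_value == 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_agrees_with_statsmodels(self, seed):
        sm = pytest.importorskip("statsmodels.stats.contingency_tables")
        rng = np.random.default_rng(seed)
        a = rng.random(120) < 0.7
        b = rng.random(120) < 0.6
        res = mcnemar(a, b)
        table = [
            [int(np.sum(a & b)), int(np.sum(a & ~b))],
            [int(np.sum(~a & b)), int(np.sum(~a & ~b))],
        ]
        ref = sm.mcnemar(table, exact=(res.method == "exact"), correction=True)
        assert res.p_value == pytest.approx(float(ref.pvalue), abs=1e-9)


class TestRanking:
    def _random_probs(self, tax, n=100, seed=7):
        rng = np.random.default_rng(seed)
        values = rng.dirichlet(np.full(22, 0.4), size=n)
        y_true = list(rng.choice(tax.leaf_order, n))
        m = ProbabilityMatrix([f"d{i}" for i in range(n)], list(tax.leaf_order), values)
        return y_true, m

    def test_top1_identity(self, tax):
        y_true, m = self._random_probs(tax)
        row = ranking_metrics(y_true, m, [1]).at(1)
        assert row["precision_at_k"] == row["recall_at_k"] == row["map_at_k"]

    def test_recall_at_all_leaves_is_one(self, tax):
        y_true, m = self._random_probs(tax)
        assert ranking_metrics(y_true, m, [22]).at(22)["recall_at_k"] == 1.0

    def test_rank_two_fixture(self, tax):
        # truth always retrieved at rank 2 -> P@3 = 1/3, R@3 = 1, MAP@3 = 1/2
        values = np.zeros((4, 22))
        values[:, 0] = 0.6
        values[:, 5] = 0.4
        m = ProbabilityMatrix([f"d{i}" for i in range(4)], list(tax.leaf_order), values)
        y_true = [tax.leaf_order[5]] * 4
        row = ranking_metrics(y_true, m, [3]).at(3)
        assert row["precision_at_k"] == pytest.approx(1 / 3)
        assert row["recall_at_k"] == 1.0
        assert row["map_at_k"] == pytest.approx(1 / 2)

    def test_recall_monotone_and_precision_bound(self, tax):
        y_true, m = self._random_probs(tax, seed=9)
        table = ranking_metrics(y_true, m, list(range(1, 23))).table
        recalls = table["recall_at_k"].to_numpy()
        assert (np.diff(recalls) >= 0).all()
        assert (table["precision_at_k"] * table.index <= 1 + 1e-12).all()

    def test_rescaling_scores_invariant(self, tax):
        y_true, m = self._random_probs(tax, seed=10)
        frame = m.to_frame()
        base = ranking_metrics(y_true, frame, [1, 3]).table
        scaled = ranking_metrics(y_true, frame * 7.3, [1, 3]).table
        pd.testing.assert_frame_equal(base, scaled)

    def test_k_out_of_range(self, tax):
        y_true, m = self._random_probs(tax)
        with pytest.raises(ValueError):
            ranking_metrics(y_true, m, [23])


class TestPrCurve:
    def test_perfect_separator(self):
        y = [True] * 5 + [False] * 5
        s = [0.9, 0.8, 0.8, 0.7, 0.6, 0.4, 0.3, 0.2, 0.2, 0.1]
        curve = pr_curve(y, s)
        # every achievable recall admits an operating point with precision 1
        assert (curve.groupby("recall")["precision"].max() == 1.0).all()
        assert curve["recall"].iloc[-1] == 1.0

    def test_full_recall_precision_is_prevalence(self):
        rng = np.random.default_rng(13)
        y = rng.random(500) < 0.3
        s = rng.random(500)
        curve = pr_curve(y, s)
        endpoint = curve[curve["recall"] == 1.0].iloc[-1]
        assert endpoint["precision"] == pytest.approx(y.mean())

    def test_one_point_per_distinct_score(self):
        curve = pr_curve([True, False, True], [0.5, 0.5, 0.9])
        assert len(curve) == 2

    def test_one_class_truth_rejected(self):
        with pytest.raises(ValueError):
            pr_curve([True, True], [0.4, 0.6])


class TestEvaluateLevel:
    def test_unknown_policies(self, tax):
        y_true = ["EPI: Case report"] * 4
        y_pred = ["ORIGINAL", "ORIGINAL", "NON-ORIGINAL", UNKNOWN]
        excl = evaluate_level(y_true, y_pred, tax, "class")
        strict = evaluate_level(y_true, y_pred, tax, "class", unknown_policy="wrong")
        assert excl.n_evaluated == 3 and excl.coverage == 0.75
        assert strict.n_evaluated == 4
        assert excl.per_label.loc["ORIGINAL", "recall"] == pytest.approx(2 / 3)
        assert strict.per_label.loc["ORIGINAL", "recall"] == pytest.approx(2 / 4)


@pytest.fixture(scope="module")
def sim(tax):
    rng = np.random.default_rng(17)
    truth = list(rng.choice(tax.leaf_order, 600))
    inputs = simulate_predictions(
        truth,
        tax,
        PredictionSimulatorConfig(per_model_accuracy=0.9, concentration=6.0, seed=17),
    )
    return truth, inputs


class TestKvoteGrid:
    def test_inactive_thresholds_cover_everything(self, tax, sim):
        truth, inputs = sim
        grid = kvote_grid(
            inputs, truth, tax, "class", "ORIGINAL", t_values=(1,), t_v_values=(0.0,), rules=()
        )
        row = grid.iloc[0]
        assert row["coverage"] == 1.0
        # at the binary level 5 votes cannot tie; t=1 equals plain majority
        maj = kvote_grid(
            inputs, truth, tax, "class", "ORIGINAL",
            t_values=(), t_v_values=(0.0,), rules=(("majority", False),),
        ).iloc[0]
        assert row["f1"] == pytest.approx(maj["f1"])

    def test_coverage_non_increasing_in_t(self, tax, sim):
        truth, inputs = sim
        grid = kvote_grid(
            inputs, truth, tax, "class", "ORIGINAL",
            t_values=(1, 2, 3, 4, 5), t_v_values=(0.6,), rules=(),
        )
        covs = grid.sort_values("t")["coverage"].to_numpy()
        assert (np.diff(covs) <= 1e-12).all()

    def test_unanimity_buys_precision_at_reduced_coverage(self, tax, sim):
        truth, inputs = sim
        grid = kvote_grid(
            inputs, truth, tax, "class", "ORIGINAL",
            t_values=(), t_v_values=(0.6,),
            rules=(("majority", False), ("unanimity", False)),
        ).set_index("rule")
        unani, major = grid.loc["unanimity"], grid.loc["majority"]
        assert unani["coverage"] < 1.0
        assert unani["precision"] >= major["precision"]

    def test_zero_coverage_row_flagged(self, tax, sim):
        truth, inputs = sim
        grid = kvote_grid(
            inputs, truth, tax, "sub-subclass", "EPI: Case report",
            t_values=(5,), t_v_values=(0.999999,), rules=(),
        )
        row = grid.iloc[0]
        if row["coverage"] == 0.0:
            assert np.isnan(row["precision"]) and np.isnan(row["f1"])
        else:  # decided set may be tiny but metrics must then be finite
            assert np.isfinite(row["precision"])
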