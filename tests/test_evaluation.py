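import math

import numpy as np
import pytest

from pathdx.evaluation import (
    auroc,
    bootstrap_ci,
    confusion_at_threshold,
    delong_compare,
    f1,
    metrics_report,
    npv,
    ppv,
    sensitivity,
    sensitivity_grid,
    specificity,
    subgroup_report,
    threshold_sweep,
)


class TestConfusion:
    def test_basic_counts(self):
        assert confusion_at_threshold([0.9, 0.1], [1, 0], 0.5) == (1, 0, 1, 0)

    def test_threshold_zero_predicts_all_positive(self, rng):
        scores = rng.random(50)
        labels = rng.integers(0, 2, 50)
        tp, fp, tn, fn = confusion_at_threshold(scores, labels, 0.0)
        assert tn == fn == 0
        assert tp + fp == 50

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            confusion_at_threshold([], [], 0.5)

    def test_matches_per_item_loop_oracle(self, rng):
        scores = rng.random(1000)
        labels = rng.integers(0, 2, 1000)
        t = 0.37
        tp = fp = tn = fn = 0
        for s, y in zip(scores, labels):  # brute-force recount
            if s >= t:
                tp, fp = tp + (y == 1), fp + (y == 0)
            else:
                tn, fn = tn + (y == 0), fn + (y == 1)
        assert confusion_at_threshold(scores, labels, t) == (tp, fp, tn, fn)


class TestRatios:
    def test_zero_denominators_are_nan_not_zero(self):
        assert math.isnan(ppv(0, 0))
        assert math.isnan(sensitivity(0, 0))
        assert math.isnan(specificity(0, 0))
        assert math.isnan(npv(0, 0))
        assert math.isnan(f1(float("nan"), 0.5))

    def test_f1_from_rates_equals_f1_from_counts(self, rng):
        for _ in range(20):
            tp, fp, fn = (int(x) for x in rng.integers(1, 500, 3))
            from_rates = f1(ppv(tp, fp), sensitivity(tp, fn))
            from_counts = 2 * tp / (2 * tp + fp + fn)
            assert abs(from_rates - from_counts) < 1e-12


class TestAuroc:
    def test_perfect_separation(self):
        assert auroc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert auroc([0.5] * 10, [1, 0] * 5) == 0.5

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            auroc([0.1, 0.2], [1, 1])

    def test_matches_pair_counting_oracle(self, rng):
        scores = np.round(rng.random(200), 2)  # coarse grid forces ties
        labels = rng.integers(0, 2, 200)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        wins = sum(
            1.0 if p > n else (0.5 if p == n else 0.0) for p in pos for n in neg
        )
        assert abs(auroc(scores, labels) - wins / (len(pos) * len(neg))) < 1e-12

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.random(300)
        labels = rng.integers(0, 2, 300)
        transformed = np.exp(5 * scores) / (1 + np.exp(5 * scores))
        assert auroc(scores, labels) == pytest.approx(
            auroc(transformed, labels), abs=1e-12
        )


class TestBootstrap:
    def test_same_seed_same_interval(self, rng):
        scores = rng.random(100)
        labels = rng.integers(0, 2, 100)
        a = bootstrap_ci(scores, labels, auroc, n_boot=200, seed=4)
        b = bootstrap_ci(scores, labels, auroc, n_boot=200, seed=4)
        assert a == b

    def test_perfect_classifier_collapses_to_one(self):
        labels = np.array([1] * 30 + [0] * 30)
        scores = labels * 0.8 + 0.1
        lo, hi = bootstrap_ci(scores, labels, auroc, n_boot=100, seed=0)
        assert (lo, hi) == (1.0, 1.0)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_ci([0.5] * 10, [0, 1] * 5, auroc)


class TestDeLong:
    def test_identical_scores_give_zero_diff_p_one(self, rng):
        scores = rng.random(80)
        labels = rng.integers(0, 2, 80)
        diff, p = delong_compare(scores, scores, labels)
        assert diff == 0.0
        assert p == 1.0

    def test_antisymmetric(self, rng):
        a = rng.random(100)
        b = rng.random(100)
        labels = np.array([1] * 50 + [0] * 50)
        d_ab, p_ab = delong_compare(a, b, labels)
        d_ba, p_ba = delong_compare(b, a, labels)
        assert d_ab == pytest.approx(-d_ba)
        assert p_ab == pytest.approx(p_ba)

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            delong_compare([0.1], [0.2], [1])

    def test_detects_a_clearly_better_model(self, rng):
        labels = rng.integers(0, 2, 300)
        good = labels + rng.normal(0, 0.4, 300)
        bad = rng.normal(0, 1, 300)
        diff, p = delong_compare(good, bad, labels)
        assert diff > 0.2 and p < 0.01


class TestThresholdSweep:
    def test_predicted_positive_monotone_in_threshold(self, rng):
        rows = threshold_sweep(rng.random(500), rng.integers(0, 2, 500))
        counts = [r.n_predicted_positive for r in rows]
        assert counts == sorted(counts, reverse=True)

    def test_threshold_zero_ppv_equals_prevalence(self, rng):
        scores = rng.random(400)
        labels = rng.integers(0, 2, 400)
        (row,) = threshold_sweep(scores, labels, [0.0])
        assert row.ppv == pytest.approx(labels.mean())

    def test_rows_recompose_from_confusion_counts(self, rng):
        scores = rng.random(300)
        labels = rng.integers(0, 2, 300)
        thresholds = [0.2, 0.5, 0.8]
        for row, t in zip(threshold_sweep(scores, labels, thresholds), thresholds):
            tp, fp, tn, fn = confusion_at_threshold(scores, labels, t)
            assert row.n_true_positive == tp
            assert row.n_predicted_positive == tp + fp
            assert row.n_positives == tp + fn  # conservation at every row

    def test_counts_internally_consistent(self, rng):
        rows = threshold_sweep(rng.random(200), rng.integers(0, 2, 200))
        for r in rows:
            assert r.n_true_positive <= min(r.n_predicted_positive, r.n_positives)


class TestMetricsReport:
    def test_values_in_unit_interval_and_ci_brackets_point(self, rng):
        labels = rng.integers(0, 2, 200)
        scores = np.clip(labels * 0.4 + rng.random(200) * 0.5, 0, 1)
        rep = metrics_report(scores, labels, threshold=0.4, n_boot=100, seed=1)
        for v in (rep.auroc, rep.precision_pos, rep.recall_pos, rep.f1_pos,
                  rep.specificity, rep.npv):
            assert 0.0 <= v <= 1.0
        lo, hi = rep.ci["auroc"]
        assert lo <= rep.auroc <= hi


class TestSensitivityGrid:
    @staticmethod
    def _stub_cell(lookback, trim):
        rng = np.random.default_rng(lookback * 10 + trim)
        labels = rng.integers(0, 2, 200)
        strength = (lookback / 36) * (1 - trim / 6)
        scores = np.clip(0.5 + strength * (labels - 0.5) + rng.normal(0, 0.2, 200), 0, 1)
        return scores, labels

    def test_grid_has_nine_cells_and_selected_cell(self):
        cells = sensitivity_grid(self._stub_cell)
        assert len(cells) == 9
        selected = [c for c in cells if c.selected]
        assert len(selected) == 1
        assert (selected[0].lookback_months, selected[0].trim_months) == (36, 1)

    def test_sparse_cell_flagged_not_dropped(self):
        def sparse(lookback, trim):
            scores, labels = self._stub_cell(lookback, trim)
            labels = np.zeros_like(labels)
            labels[:3] = 1
            return scores, labels

        cells = sensitivity_grid(sparse, min_cases=10)
        assert len(cells) == 9
        assert all(c.flagged and c.report is None for c in cells)


class TestSubgroupReport:
    def test_identical_multisets_identical_metrics(self):
        scores = np.array([0.9, 0.2, 0.8, 0.1] * 30)
        labels = np.array([1, 0, 1, 0] * 30)
        groups = np.array((["a"] * 60) + (["b"] * 60))
        rep = subgroup_report(scores, labels, {"g": groups}, min_group_size=10)
        a = rep["g"]["a"]["report"]
        b = rep["g"]["b"]["report"]
        assert a.auroc == b.auroc and a.precision_pos == b.precision_pos

    def test_pooled_tp_equals_sum_of_group_tps(self, rng):
        scores = rng.random(300)
        labels = rng.integers(0, 2, 300)
        groups = rng.choice(["x", "y", "z"], 300)
        rep = subgroup_report(scores, labels, {"g": groups}, threshold=0.4,
                              min_group_size=1)
        tp_total = confusion_at_threshold(scores, labels, 0.4)[0]
        tp_sum = 0
        for g in ("x", "y", "z"):
            r = rep["g"][g]["report"]
            tp_sum += round(r.recall_pos * labels[groups == g].sum())
        assert tp_sum == tp_total

    def test_group_auroc_equals_subset_recomputation(self, rng):
        scores = rng.random(300)
        labels = rng.integers(0, 2, 300)
        groups = rng.choice(["x", "y"], 300)
        rep = subgroup_report(scores, labels, {"g": groups}, min_group_size=1)
        for g in ("x", "y"):
            mask = groups == g
            assert rep["g"][g]["report"].auroc == pytest.approx(
                auroc(scores[mask], labels[mask])
            )

    def test_small_groups_flagged(self, rng):
        scores = rng.random(100)
        labels = rng.integers(0, 2, 100)
        groups = np.array(["big"] * 97 + ["tiny"] * 3)
        rep = subgroup_report(scores, labels, {"g": groups}, min_group_size=10)
        assert "flagged" in rep["g"]["tiny"]
        assert "report" in rep["g"]["big"]
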