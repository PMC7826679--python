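"""Metric closed forms, the O(N²) AP oracle, and an independent scikit-learn
cross-check of average precision."""

import numpy as np
import pytest
from sklearn.metrics import average_precision_score

from farnet.evaluation import (
    ConfusionCounts,
    average_precision,
    confidence_grid,
    confusion_counts,
    evaluate,
    f1_scores,
    map_score,
    precision_recall,
)


def brute_force_ap(scores: np.ndarray, y: np.ndarray) -> float:
    """O(N²) ranking oracle: precision at each positive's rank, averaged."""
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], i))
    precisions = []
    for rank, idx in enumerate(order, start=1):
        if y[idx] == 1:
            hits = sum(1 for j in order[:rank] if y[j] == 1)
            precisions.append(hits / rank)
    return float(np.mean(precisions))


class TestAveragePrecision:
    def test_worked_ranking(self):
        ap = average_precision([0.9, 0.8, 0.3], [1, 0, 1])
        assert ap == pytest.approx((1 + 2 / 3) / 2, abs=1e-12)
        assert ap == pytest.approx(0.8333, abs=1e-4)

    def test_perfect_and_degenerate_rankings(self):
        assert average_precision([0.9, 0.8, 0.1], [1, 1, 0]) == pytest.approx(1.0)
        assert average_precision([0.2, 0.5, 0.9], [1, 1, 1]) == pytest.approx(1.0)
        with pytest.raises(ValueError, match="positive"):
            average_precision([0.5, 0.5], [0, 0])

    @pytest.mark.parametrize("n", [5, 17, 50])
    def test_matches_quadratic_oracle(self, n, rng):
        for _ in range(20):
            scores = rng.uniform(size=n)
            y = (rng.uniform(size=n) < 0.4).astype(int)
            if y.sum() == 0:
                y[rng.integers(n)] = 1
            assert average_precision(scores, y) == pytest.approx(
                brute_force_ap(scores, y), abs=1e-12
            )

    def test_matches_sklearn_on_untied_scores(self, rng):
        for _ in range(20):
            scores = rng.permutation(np.linspace(0.01, 0.99, 30))
            y = (rng.uniform(size=30) < 0.5).astype(int)
            if y.sum() == 0:
                y[0] = 1
            assert average_precision(scores, y) == pytest.approx(
                average_precision_score(y, scores), abs=1e-10
            )

    def test_invariant_to_monotone_transforms(self, rng):
        scores = rng.uniform(size=40)
        y = (rng.uniform(size=40) < 0.3).astype(int)
        y[0] = 1
        base = average_precision(scores, y)
        assert average_precision(3 * scores + 2, y) == pytest.approx(base)
        assert average_precision(np.tanh(scores), y) == pytest.approx(base)


class TestConfusionAndPR:
    def test_perfect_predictions(self):
        y = np.array([[1, 0], [0, 1], [1, 1]])
        counts = confusion_counts(y, y.astype(float) * 0.98 + 0.01)
        assert (counts.fp == 0).all() and (counts.fn == 0).all()
        pr = precision_recall(counts)
        np.testing.assert_allclose(pr["precision"], 1.0)
        np.testing.assert_allclose(pr["recall"], 1.0)

    def test_threshold_is_strict(self):
        y = np.ones((4, 1), dtype=int)
        counts = confusion_counts(y, np.full((4, 1), 0.5), threshold=0.5)
        assert counts.tp[0] == 0 and counts.fn[0] == 4  # 0.5 is not > 0.5

    def test_toy_counting(self):
        y = np.zeros((12, 1), dtype=int)
        y[:8, 0] = 1
        conf = np.zeros((12, 1))
        conf[:8, 0] = 0.9  # all 8 positives predicted positive
        conf[8:10, 0] = 0.9  # plus 2 false positives
        counts = confusion_counts(y, conf)
        assert counts.tp[0] == 8 and counts.fp[0] == 2 and counts.fn[0] == 0

    def test_precision_recall_worked_example(self):
        counts = ConfusionCounts(
            tp=np.array([8]), fp=np.array([2]), fn=np.array([2]), tn=np.array([0]), threshold=0.5
        )
        pr = precision_recall(counts)
        assert pr["precision"][0] == pytest.approx(0.8)
        assert pr["recall"][0] == pytest.approx(0.8)

    def test_degenerate_zero_over_zero(self):
        counts = ConfusionCounts(
            tp=np.array([0]), fp=np.array([0]), fn=np.array([5]), tn=np.array([0]), threshold=0.5
        )
        pr = precision_recall(counts)
        assert pr["precision"][0] == 0.0 and pr["precision_undefined"][0]
        assert pr["recall"][0] == 0.0 and not pr["recall_undefined"][0]

    def test_shape_and_threshold_validation(self):
        with pytest.raises(ValueError):
            confusion_counts(np.zeros((3, 2)), np.zeros((3, 3)))
        with pytest.raises(ValueError):
            confusion_counts(np.zeros((3, 2)), np.zeros((3, 2)), threshold=1.5)


class TestF1:
    def test_hand_computed_micro_macro(self):
        counts = ConfusionCounts(
            tp=np.array([2, 1]),
            fp=np.array([1, 0]),
            fn=np.array([1, 1]),
            tn=np.array([0, 2]),
            threshold=0.5,
        )
        micro, macro = f1_scores(counts)
        assert micro == pytest.approx(2 / 3, abs=1e-12)
        assert macro == pytest.approx(2 / 3, abs=1e-12)

    def test_micro_equals_macro_for_identical_counts(self, rng):
        tp, fp, fn = 5, 2, 3
        counts = ConfusionCounts(
            tp=np.full(4, tp), fp=np.full(4, fp), fn=np.full(4, fn), tn=np.full(4, 0), threshold=0.5
        )
        micro, macro = f1_scores(counts)
        assert micro == pytest.approx(macro)

    def test_perfect_predictions_give_one(self):
        counts = ConfusionCounts(
            tp=np.array([3, 4]), fp=np.zeros(2, int), fn=np.zeros(2, int), tn=np.array([1, 0]),
            threshold=0.5,
        )
        assert f1_scores(counts) == (pytest.approx(1.0), pytest.approx(1.0))


class TestMapAndReport:
    def test_map_is_mean_as_percent(self):
        assert map_score([1.0, 0.5]) == pytest.approx(75.0)
        assert map_score([0.42]) == pytest.approx(42.0)
        with pytest.raises(ValueError):
            map_score([])

    def test_report_consistency(self, rng):
        y = (rng.uniform(size=(30, 8)) < 0.4).astype(int)
        y[0, :] = 1  # every label has at least one positive
        conf = np.clip(rng.uniform(size=(30, 8)), 0.01, 0.99)
        report = evaluate(y, conf, list("abcdefgh"))
        assert len(report.ap_pct) == 8
        assert report.map_pct == pytest.approx(np.mean(list(report.ap_pct.values())))
        assert 0 <= report.micro_f1_pct <= 100
        table = report.to_table()
        assert "mAP" in table and "micro-F1" in table

    def test_report_json_roundtrip(self, tmp_path, rng):
        y = np.ones((5, 2), dtype=int)
        conf = rng.uniform(size=(5, 2))
        report = evaluate(y, conf, ["a", "b"])
        report.to_json(tmp_path / "r.json")
        import json

        back = json.loads((tmp_path / "r.json").read_text())
        assert back["map_pct"] == pytest.approx(report.map_pct)


class TestConfidenceGrid:
    def test_default_selection_and_shape(self, rng):
        conf = rng.uniform(size=(10, 8))
        labels = ["n", "r", "mr", "sr", "c", "s", "p", "bp"]
        grid = confidence_grid(conf, labels)
        assert grid.shape == (10, 4)
        np.testing.assert_array_equal(grid[:, 0], conf[:, 1])  # column r
        assert (grid >= 0).all() and (grid <= 1).all()

    def test_unknown_label_rejected(self, rng):
        with pytest.raises(KeyError, match="zz"):
            confidence_grid(rng.uniform(size=(5, 3)), ["a", "b", "c"], selected=("zz",))

    def test_figure_written(self, tmp_path, rng):
        conf = rng.uniform(size=(20, 8))
        labels = ["n", "r", "mr", "sr", "c", "s", "p", "bp"]
        confidence_grid(conf, labels, figure_path=tmp_path / "grid.png")
        assert (tmp_path / "grid.png").stat().st_size > 0
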