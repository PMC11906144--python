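import math

import numpy as np
import pytest

from odorcascade.metrics import (
    ConfusionCounts,
    classification_metrics,
    confusion_from_predictions,
    regression_metrics,
)


def direct_classification_oracle(tp, fp, fn, tn):
    """Independent direct-summation implementation of the four indices."""
    out = {}
    out["accuracy"] = (tp + tn) / (tp + fp + fn + tn)
    out["precision"] = tp / (tp + fp) if tp + fp else 0.0
    out["recall"] = tp / (tp + fn) if tp + fn else 0.0
    p, r = out["precision"], out["recall"]
    out["f_measure"] = 2 * p * r / (p + r) if p + r else 0.0
    return out


class TestClassificationMetrics:
    def test_worked_example(self):
        m = classification_metrics(ConfusionCounts(tp=2, fp=1, fn=1, tn=6))
        assert m["accuracy"] == pytest.approx(0.8)
        assert m["precision"] == pytest.approx(2 / 3)
        assert m["recall"] == pytest.approx(2 / 3)
        assert m["f_measure"] == pytest.approx(2 / 3)

    def test_perfect_classifier(self):
        m = classification_metrics(ConfusionCounts(tp=5, fp=0, fn=0, tn=7))
        assert all(m[k] == 1.0 for k in ["accuracy", "precision", "recall",
                                          "f_measure"])
        assert not m.undefined

    def test_zero_denominator_policy(self):
        m = classification_metrics(ConfusionCounts(tp=0, fp=0, fn=2, tn=3))
        assert m["precision"] == 0.0
        assert "precision" in m.undefined

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError, match="undefined"):
            classification_metrics(ConfusionCounts(0, 0, 0, 0))

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(-1, 0, 0, 1)

    def test_agrees_with_direct_oracle_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(500):
            tp, fp, fn, tn = rng.integers(0, 50, size=4)
            if tp + fp + fn + tn == 0:
                continue
            m = classification_metrics(ConfusionCounts(tp, fp, fn, tn))
            oracle = direct_classification_oracle(tp, fp, fn, tn)
            for k, v in oracle.items():
                assert m[k] == pytest.approx(v, abs=1e-12)

    def test_f_is_harmonic_mean_when_defined(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            tp, fp, fn, tn = rng.integers(1, 30, size=4)
            m = classification_metrics(ConfusionCounts(tp, fp, fn, tn))
            p, r = m["precision"], m["recall"]
            assert m["f_measure"] == pytest.approx(2 / (1 / p + 1 / r), abs=1e-12)


class TestConfusionFromPredictions:
    def test_tally(self):
        c = confusion_from_predictions([1, 1, 0, 0, 1], [1, 0, 0, 1, 1])
        assert (c.tp, c.fp, c.fn, c.tn) == (2, 1, 1, 1)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            confusion_from_predictions([1, 0], [1])


class TestRegressionMetrics:
    def test_perfect_fit(self):
        m = regression_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert m["r2"] == 1.0 and m["mae"] == 0.0 and m["rmse"] == 0.0

    def test_mean_predictor_has_zero_r2(self):
        y = np.array([1.0, 2.0, 3.0, 6.0])
        m = regression_metrics(y, np.full(4, y.mean()))
        assert m["r2"] == pytest.approx(0.0, abs=1e-12)

    def test_worked_example(self):
        m = regression_metrics([0.0, 2.0], [1.0, 1.0])
        assert m["mae"] == 1.0 and m["rmse"] == 1.0
        assert m["r2"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_observations_flag_r2(self):
        m = regression_metrics([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
        assert "r2" in m.undefined
        assert m["mae"] == pytest.approx(2 / 3)

    def test_agrees_with_direct_oracle_on_random_vectors(self):
        rng = np.random.default_rng(2)
        for _ in range(500):
            n = int(rng.integers(2, 40))
            y = rng.normal(size=n)
            yhat = rng.normal(size=n)
            m = regression_metrics(y, yhat)
            resid = sum((a - b) ** 2 for a, b in zip(y, yhat))
            total = sum((a - y.mean()) ** 2 for a in y)
            assert m["r2"] == pytest.approx(1 - resid / total, abs=1e-12)
            assert m["mae"] == pytest.approx(
                sum(abs(a - b) for a, b in zip(y, yhat)) / n, abs=1e-12
            )
            assert m["rmse"] == pytest.approx(math.sqrt(resid / n), abs=1e-12)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            regression_metrics([1.0], [1.0])
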