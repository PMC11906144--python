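"""Classification and regression evaluation metrics.

Classification models are scored by accuracy, precision, recall and
F-measure computed from the confusion counts:

    accuracy  = (TP + TN) / (TP + FP + FN + TN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F         = 2 * precision * recall / (precision + recall)

Regression models are scored by the coefficient of determination, mean
absolute error and root mean square error:

    r2   = 1 - sum (y - y_hat)^2 / sum (y - y_mean)^2
    MAE  = sum |y - y_hat| / n
    RMSE = sqrt( sum (y - y_hat)^2 / n )

Any ratio with a zero denominator is reported as 0.0 and its name added to
the result's ``undefined`` set, so pooled tables never silently propagate
NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_from_predictions(y_true, y_pred, positive=1) -> ConfusionCounts:
    """Tally confusion counts from paired label vectors."""
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    if yt.shape != yp.shape:
        raise ValueError("y_true and y_pred differ in shape")
    pos_t = yt == positive
    pos_p = yp == positive
    return ConfusionCounts(
        tp=int(np.sum(pos_t & pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
    )


@dataclass
class MetricResult:
    """Metric values plus the names of any zero-denominator metrics."""

    values: dict[str, float]
    undefined: set[str] = field(default_factory=set)

    def __getitem__(self, name: str) -> float:
        return self.values[name]


def _ratio(num: float, den: float, name: str, undefined: set[str]) -> float:
    if den == 0:
        undefined.add(name)
        return 0.0
    return num / den


def classification_metrics(c: ConfusionCounts) -> MetricResult:
    """Accuracy, precision, recall and F-measure from confusion counts."""
    if c.total == 0:
        raise ValueError("all confusion counts are zero; metrics are undefined")
    undefined: set[str] = set()
    accuracy = (c.tp + c.tn) / c.total
    precision = _ratio(c.tp, c.tp + c.fp, "precision", undefined)
    recall = _ratio(c.tp, c.tp + c.fn, "recall", undefined)
    f = _ratio(2 * precision * recall, precision + recall, "f_measure", undefined)
    return MetricResult(
        {
            "accuracy": accuracy,
            "precision": precision,
            "recall": recall,
            "f_measure": f,
        },
        undefined,
    )


def regression_metrics(y_true, y_pred) -> MetricResult:
    """r², MAE and RMSE for paired observation/prediction vectors.

    A constant observed vector leaves r² undefined (zero total sum of
    squares); it is reported as 0.0 with ``'r2'`` flagged, while MAE and
    RMSE are returned normally.
    """
    y = np.asarray(y_true, dtype=float)
    yhat = np.asarray(y_pred, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("observed and estimated vectors differ in shape")
    n = y.size
    if n < 2:
        raise ValueError("need at least 2 samples")
    undefined: set[str] = set()
    resid_ss = float(np.sum((y - yhat) ** 2))
    total_ss = float(np.sum((y - y.mean()) ** 2))
    if total_ss == 0:
        undefined.add("r2")
        r2 = 0.0
    else:
        r2 = 1.0 - resid_ss / total_ss
    mae = float(np.sum(np.abs(y - yhat))) / n
    rmse = math.sqrt(resid_ss / n)
    return MetricResult({"r2": r2, "mae": mae, "rmse": rmse}, undefined)
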