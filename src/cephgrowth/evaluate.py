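"""Test-set evaluation metrics for the two proxy tasks.

Age regression: MAE, RMSE and the coefficient of determination R^2.  Sex
classification: confusion counts and accuracy / precision / recall / F1
with *female as the positive class* and a 0.5 decision threshold on the
female probability.  Undefined metrics (R^2 under zero-variance truth,
precision with no positive predictions) are reported as None with a reason
code, never silently as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class RegressionReport:
    n: int
    mae: float
    rmse: float
    r2: float | None
    undefined: dict[str, str] = field(default_factory=dict)


@dataclass
class ClassificationReport:
    n: int
    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    precision: float | None
    recall: float | None
    f1: float | None
    undefined: dict[str, str] = field(default_factory=dict)


def regression_metrics(y_true, y_pred) -> RegressionReport:
    """MAE = (1/N)Σ|y−y'|, RMSE = sqrt((1/N)Σ(y−y')²),
    R² = 1 − Σ(y−y')² / Σ(y−ȳ)²."""
    y = np.asarray(y_true, dtype=float).reshape(-1)
    yp = np.asarray(y_pred, dtype=float).reshape(-1)
    if y.size == 0 or y.shape != yp.shape:
        raise ValueError("y_true and y_pred must be equal, non-zero length")
    err = y - yp
    mae = float(np.abs(err).mean())
    rmse = float(np.sqrt((err ** 2).mean()))
    ss_res = float((err ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    undefined = {}
    if ss_tot == 0.0:
        r2 = None
        undefined["r2"] = "zero variance in y_true"
    else:
        r2 = 1.0 - ss_res / ss_tot
    return RegressionReport(n=y.size, mae=mae, rmse=rmse, r2=r2,
                            undefined=undefined)


def classification_metrics(labels, scores, threshold: float = 0.5
                           ) -> ClassificationReport:
    """Confusion-matrix metrics at a probability threshold.

    ``labels``: 1 = female (positive), 0 = male.  ``scores``: predicted
    female probability in [0, 1]; a score >= threshold predicts female.
    """
    y = np.asarray(labels).astype(int).reshape(-1)
    s = np.asarray(scores, dtype=float).reshape(-1)
    if y.size == 0 or y.shape != s.shape:
        raise ValueError("labels and scores must be equal, non-zero length")
    if s.min() < 0.0 or s.max() > 1.0:
        raise ValueError("scores must lie in [0, 1]")
    pred = (s >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    acc = (tp + tn) / y.size
    undefined = {}
    precision = tp / (tp + fp) if (tp + fp) > 0 else None
    if precision is None:
        undefined["precision"] = "no positive predictions"
    recall = tp / (tp + fn) if (tp + fn) > 0 else None
    if recall is None:
        undefined["recall"] = "no positive labels"
    if precision is None or recall is None or (precision + recall) == 0:
        f1 = None
        undefined.setdefault("f1", "precision or recall undefined or both zero")
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return ClassificationReport(n=y.size, tp=tp, tn=tn, fp=fp, fn=fn,
                                accuracy=acc, precision=precision,
                                recall=recall, f1=f1, undefined=undefined)
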