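"""Classification metrics with percentile-bootstrap confidence intervals.

Accuracy, sensitivity, specificity and F1 follow the usual confusion-matrix
definitions

    ACC = (TP+TN)/(TP+TN+FP+FN)    SEN = TP/(TP+FN)
    SPE = TN/(TN+FP)               F1  = 2TP/(2TP+FP+FN)

with a score >= threshold predicted positive (ties go to the depressed
class, for bit-exact reproducibility).  AUC is the rank-based
(Mann-Whitney) probability P(score+ > score-) + 0.5 P(equal).  Confidence
intervals are seeded percentile bootstraps over (score, label) pairs;
replicates on which a metric is undefined (e.g. a single-class resample for
AUC) are skipped and counted.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
from sklearn.metrics import roc_auc_score

METRIC_NAMES = ("auc", "acc", "sen", "spe", "f1")


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion(scores, labels, threshold: float = 0.5) -> ConfusionMatrix:
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if scores.size == 0:
        raise ValueError("empty input")
    if scores.shape != labels.shape:
        raise ValueError("scores/labels length mismatch")
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionMatrix(
        tp=int(np.sum(pred & pos)),
        tn=int(np.sum(~pred & ~pos)),
        fp=int(np.sum(pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN",
                      stacklevel=3)
        return float("nan")
    return num / den


def metrics_from_cm(cm: ConfusionMatrix) -> tuple[float, float, float, float]:
    """(accuracy, sensitivity, specificity, F1)."""
    if cm.n == 0:
        raise ValueError("empty confusion matrix")
    acc = (cm.tp + cm.tn) / cm.n
    sen = _safe_div(cm.tp, cm.tp + cm.fn, "sensitivity")
    spe = _safe_div(cm.tn, cm.tn + cm.fp, "specificity")
    f1 = _safe_div(2 * cm.tp, 2 * cm.tp + cm.fp + cm.fn, "F1")
    return acc, sen, spe, f1


def auc(scores, labels) -> float:
    """Tie-corrected Mann-Whitney AUC."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=np.float64)))


def _metric_value(name: str, scores, labels, threshold: float) -> float:
    labels = np.asarray(labels)
    if name == "auc":
        if len(np.unique(labels)) < 2:
            return float("nan")
        return auc(scores, labels)
    cm = confusion(scores, labels, threshold)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        acc, sen, spe, f1 = metrics_from_cm(cm)
    return {"acc": acc, "sen": sen, "spe": spe, "f1": f1}[name]


def bootstrap_ci(
    scores,
    labels,
    metric: str | Callable = "auc",
    replicates: int = 1000,
    seed: int = 0,
    threshold: float = 0.5,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Seeded percentile bootstrap CI for one metric."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    n = scores.shape[0]
    if n < 10:
        raise ValueError("bootstrap needs n >= 10")
    rng = np.random.default_rng(seed)
    fn = (metric if callable(metric)
          else lambda s, l: _metric_value(metric, s, l, threshold))
    vals = np.empty(replicates)
    for r in range(replicates):
        idx = rng.integers(0, n, size=n)
        vals[r] = fn(scores[idx], labels[idx])
    degenerate = int(np.isnan(vals).sum())
    if degenerate > replicates / 2:
        raise ValueError(
            f"{degenerate}/{replicates} bootstrap replicates degenerate; "
            "data too small or too imbalanced")
    good = vals[~np.isnan(vals)]
    lo, hi = np.percentile(good, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


@dataclass
class MetricsReport:
    point: dict[str, float]
    ci: dict[str, tuple[float, float]]
    n: int
    threshold: float
    replicates: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "threshold": self.threshold,
            "bootstrap": {"replicates": self.replicates, "seed": self.seed},
            "metrics": {
                name: {
                    "value": self.point[name],
                    "percent": 100.0 * self.point[name],
                    "ci95": list(self.ci[name]),
                    "ci95_percent": [100.0 * v for v in self.ci[name]],
                }
                for name in METRIC_NAMES
            },
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    def to_csv_row(self, label: str = "") -> str:
        """One comma-separated line (with header) for tabulation across runs."""
        header = ["run", "n"] + [f"{m}{s}" for m in METRIC_NAMES
                                 for s in ("", "_lo", "_hi")]
        row = [label, str(self.n)]
        for m in METRIC_NAMES:
            row += [f"{self.point[m]:.6f}",
                    f"{self.ci[m][0]:.6f}", f"{self.ci[m][1]:.6f}"]
        return ",".join(header) + "\n" + ",".join(row) + "\n"


def evaluate_scores(
    scores,
    labels,
    threshold: float = 0.5,
    replicates: int = 1000,
    seed: int = 0,
) -> MetricsReport:
    """Full five-metric report with bootstrap CIs from scores and labels."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if scores.size == 0:
        raise ValueError("empty evaluation set")
    point = {name: _metric_value(name, scores, labels, threshold)
             for name in METRIC_NAMES}
    ci = {name: bootstrap_ci(scores, labels, name, replicates, seed, threshold)
          for name in METRIC_NAMES}
    return MetricsReport(point, ci, int(scores.size), threshold, replicates, seed)


def evaluate(model, dataset, test_idx, threshold: float = 0.5,
             replicates: int = 1000, seed: int = 0) -> MetricsReport:
    """Evaluate a trained model on the test partition of *dataset*."""
    from .model import predict_proba_batched

    test_idx = np.asarray(test_idx, dtype=np.int64)
    if test_idx.size == 0:
        raise ValueError("empty test set")
    scores = predict_proba_batched(dataset.matrix[test_idx], model)
    return evaluate_scores(scores, dataset.labels[test_idx], threshold,
                           replicates, seed)
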