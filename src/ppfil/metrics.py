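"""Classification metrics and simulated latency/throughput counters.

Rates are reported on the percentage scale. Binary metrics take label 1 as
the positive class; multi-class metrics are macro-averaged one-vs-rest.
Zero-denominator cases (no predicted positives, no actual positives) are
defined as 0 by convention. ``loss_percent`` is 100 - accuracy, the
complement convention used alongside true cross-entropy, which is reported
separately and never conflated with it. Latency/throughput are logical
simulation counters, flagged hardware-dependent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_counts",
    "classification_metrics",
    "average_client_loss",
    "simulated_latency_throughput",
]


@dataclass
class ConfusionCounts:
    """One-vs-rest counts per class; ``classes[i]`` indexes row i."""

    classes: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    tn: np.ndarray

    def for_class(self, label: int) -> tuple[int, int, int, int]:
        i = int(np.flatnonzero(self.classes == label)[0])
        return int(self.tp[i]), int(self.fp[i]), int(self.fn[i]), int(self.tn[i])


@dataclass
class MetricsReport:
    precision: float  # percent
    recall: float  # percent
    f_measure: float  # percent
    accuracy: float  # percent
    cross_entropy: float
    loss_percent: float  # 100 - accuracy, the table-complement convention
    simulated_latency: float = 0.0  # hardware-dependent, excluded from checks
    simulated_throughput: float = 0.0
    traces: dict = field(default_factory=dict)


def confusion_counts(truth: np.ndarray, predicted: np.ndarray) -> ConfusionCounts:
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape != predicted.shape:
        raise ValueError("truth and prediction lengths differ")
    classes = np.unique(np.concatenate([truth, predicted]))
    tp = np.array([np.sum((truth == c) & (predicted == c)) for c in classes])
    fp = np.array([np.sum((truth != c) & (predicted == c)) for c in classes])
    fn = np.array([np.sum((truth == c) & (predicted != c)) for c in classes])
    tn = len(truth) - tp - fp - fn
    return ConfusionCounts(classes, tp, fp, fn, tn)


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def classification_metrics(
    counts: ConfusionCounts, positive: int | None = 1
) -> tuple[float, float, float, float]:
    """(precision, recall, F-measure, accuracy), all in percent.

    Binary inputs score the stated positive class (default label 1);
    multi-class inputs are macro-averaged one-vs-rest.
    """
    n_total = int(counts.tp[0] + counts.fp[0] + counts.fn[0] + counts.tn[0])
    accuracy = 100.0 * _safe_div(float(counts.tp.sum()), n_total)
    if len(counts.classes) == 2 and positive is not None and positive in counts.classes:
        tp, fp, fn, _ = counts.for_class(positive)
        p = _safe_div(tp, tp + fp)
        r = _safe_div(tp, tp + fn)
        f = _safe_div(2 * p * r, p + r)
        return 100.0 * p, 100.0 * r, 100.0 * f, accuracy
    ps, rs, fs = [], [], []
    for tp, fp, fn in zip(counts.tp, counts.fp, counts.fn):
        p = _safe_div(int(tp), int(tp + fp))
        r = _safe_div(int(tp), int(tp + fn))
        ps.append(p)
        rs.append(r)
        fs.append(_safe_div(2 * p * r, p + r))
    return 100.0 * np.mean(ps), 100.0 * np.mean(rs), 100.0 * np.mean(fs), accuracy


def average_client_loss(losses: list[float] | np.ndarray) -> float:
    """Mean of per-client losses."""
    losses = np.asarray(losses, dtype=float)
    if losses.size == 0:
        raise ValueError("no client losses")
    return float(losses.mean())


def simulated_latency_throughput(
    total_time: float, n_rounds: int, n_transactions: int
) -> tuple[float, float]:
    """(latency, throughput) from logical counters: latency = total time /
    rounds; throughput = transactions / total time. Hardware-dependent."""
    if n_rounds < 1:
        raise ValueError("need at least one round")
    latency = total_time / n_rounds
    throughput = n_transactions / total_time if total_time > 0 else 0.0
    return latency, throughput
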