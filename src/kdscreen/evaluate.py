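"""Fixed-recall evaluation harness.

Clinical screening for a rare, high-stakes condition is operated at a
sensitivity floor: the decision threshold is the *largest* score cut whose
recall still meets the target (80/85/90/95% by default), so the achieved
("actual") recall is the minimal recall at or above the target. Rows with
score >= threshold are predicted positive (ties predicted positive).

From the resulting confusion counts the harness derives recall,
specificity, precision (PPV), NPV, F1 and F2 (F-beta with beta = 2,
weighting recall four times as heavily as precision: 5PR / (4P + R)),
plus ROC / PR curves with their areas.

The threshold is calibrated on the evaluation set itself by default —
reproducing the published per-dataset "actual recall" protocol — which
leaks the operating point; calibrating on a held-out split instead is
supported by simply passing that split's scores to
:func:`calibrate_threshold` and carrying the threshold over.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import precision_recall_curve, roc_curve

DEFAULT_RECALL_TARGETS = (0.80, 0.85, 0.90, 0.95)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def positives(self) -> int:
        return self.tp + self.fn

    @property
    def negatives(self) -> int:
        return self.fp + self.tn


@dataclass(frozen=True)
class ThresholdCalibration:
    target_recall: float
    achieved_recall: float
    threshold: float


@dataclass(frozen=True)
class MetricsReport:
    counts: ConfusionCounts
    recall: float
    specificity: float
    precision: float
    npv: float
    f1: float
    f2: float
    threshold: float = float("nan")
    target_recall: float = float("nan")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["counts"] = asdict(self.counts)
        return d


def percent(x: float) -> float:
    """Half-up rounding of a proportion to one decimal of a percentage.

    195/229 -> 85.2; 14547/14700 -> 99.0. Used for display and for the
    worked-example checks against printed tables.
    """
    return float(Decimal(x * 100).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def calibrate_threshold(
    scores: np.ndarray, labels: np.ndarray, target_recall: float
) -> ThresholdCalibration:
    """Largest threshold whose recall (at score >= t) meets the target.

    Since recall is non-increasing in the threshold, this is the cut with
    the minimal achieved recall still >= target; it always exists because
    t = min(scores) yields recall 1.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if not 0.0 < target_recall <= 1.0:
        raise ValueError("target_recall must be in (0, 1]")
    pos_scores = scores[labels == 1]
    if pos_scores.size == 0 or (labels == 0).sum() == 0:
        raise ValueError("both classes must be present")
    n_pos = pos_scores.size
    # recall at t is (# positive scores >= t) / n_pos; candidates are the
    # observed positive scores sorted descending.
    cand = np.unique(pos_scores)[::-1]
    for t in cand:
        ach = (pos_scores >= t).sum() / n_pos
        if ach >= target_recall:
            return ThresholdCalibration(target_recall, float(ach), float(t))
    t = float(cand[-1])  # pragma: no cover - loop always satisfies at min
    return ThresholdCalibration(target_recall, 1.0, t)


def confusion_at(
    scores: np.ndarray, labels: np.ndarray, threshold: float
) -> ConfusionCounts:
    """Counts under the prediction rule score >= threshold -> positive."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape[0] != labels.shape[0]:
        raise ValueError("scores and labels must have equal length")
    pred = scores >= threshold
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    return ConfusionCounts(tp, fp, fn, tn)


def metrics_from_confusion(
    counts: ConfusionCounts,
    threshold: float = float("nan"),
    target_recall: float = float("nan"),
) -> MetricsReport:
    """Derive the screening metric suite from confusion counts.

    Precision is 0 (flagged by tp+fp == 0 in the counts) when nothing is
    predicted positive; F1/F2 are then 0 as well.
    """
    if counts.positives == 0 or counts.negatives == 0:
        raise ValueError("both classes must be present in the counts")
    recall = counts.tp / counts.positives
    specificity = counts.tn / counts.negatives
    precision = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 0.0
    npv = counts.tn / (counts.tn + counts.fn) if counts.tn + counts.fn else 0.0
    pr = precision * recall
    f1 = 2 * pr / (precision + recall) if precision + recall else 0.0
    f2 = 5 * pr / (4 * precision + recall) if 4 * precision + recall else 0.0
    return MetricsReport(
        counts=counts,
        recall=recall,
        specificity=specificity,
        precision=precision,
        npv=npv,
        f1=f1,
        f2=f2,
        threshold=threshold,
        target_recall=target_recall,
    )


def roc_pr_curves(scores: np.ndarray, labels: np.ndarray) -> dict:
    """Threshold-sweep ROC and PR curves with their areas.

    ROC AUC equals the normalized Mann-Whitney U statistic (ties counted
    half); PR AUC uses step interpolation.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present")
    fpr, tpr, roc_thr = roc_curve(labels, scores)
    prec, rec, pr_thr = precision_recall_curve(labels, scores)
    auc_roc = float(_trapezoid_auc(fpr, tpr))
    # step-interpolated area: sum P(r_i) * (r_i - r_{i+1}) over the sweep
    auc_pr = float(-np.sum(np.diff(rec) * prec[:-1]))
    return {
        "fpr": fpr,
        "tpr": tpr,
        "roc_thresholds": roc_thr,
        "precision": prec,
        "recall": rec,
        "pr_thresholds": pr_thr,
        "auc_roc": auc_roc,
        "auc_pr": auc_pr,
    }


def evaluate_scores(
    scores: np.ndarray,
    labels: np.ndarray,
    targets: tuple[float, ...] = DEFAULT_RECALL_TARGETS,
) -> list[MetricsReport]:
    """One metrics report per recall target on a fixed score vector."""
    out = []
    for target in targets:
        cal = calibrate_threshold(scores, labels, target)
        counts = confusion_at(scores, labels, cal.threshold)
        out.append(metrics_from_confusion(counts, cal.threshold, target))
    return out


def recall_sweep(model, table, targets: tuple[float, ...] = DEFAULT_RECALL_TARGETS) -> list[MetricsReport]:
    """Calibrate-and-score sweep for a trained stacking model on a cohort."""
    from .ensemble import predict_scores  # local import to avoid a cycle

    scores = predict_scores(model, table)
    return evaluate_scores(scores, table.labels, targets)


def sweep_frame(reports: list[MetricsReport], dataset: str = "") -> pd.DataFrame:
    """Render sweep reports as a display table (percentages, one decimal)."""
    rows = []
    for r in reports:
        rows.append(
            {
                "recall_target": percent(r.target_recall),
                "dataset": dataset,
                "actual_recall": percent(r.recall),
                "precision": percent(r.precision),
                "specificity": percent(r.specificity),
                "f1": percent(r.f1),
                "f2": percent(r.f2),
                "tp": r.counts.tp,
                "fp": r.counts.fp,
                "fn": r.counts.fn,
                "tn": r.counts.tn,
            }
        )
    return pd.DataFrame(rows)
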