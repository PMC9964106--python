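"""Evaluation: confusion-matrix metrics, tenfold CV, length-binned analysis.

The five reported metrics are specificity TN/(TN+FP), accuracy
(TP+TN)/total, precision TP/(TP+FP), recall TP/(TP+FN) and F1 =
2*precision*recall/(precision+recall).  Cross-validation is stratified;
the per-fold metrics are summarized by their median (the headline
number) with the mean reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

METRIC_NAMES = ("specificity", "accuracy", "precision", "recall", "f1")


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class MetricsReport:
    tp: int
    tn: int
    fp: int
    fn: int
    specificity: float
    accuracy: float
    precision: float
    recall: float
    f1: float
    degenerate: bool = False  # True if any ratio had a zero denominator

    def as_dict(self) -> dict:
        return asdict(self)


def confusion(labels: np.ndarray, probs: np.ndarray, threshold: float = 0.5) -> tuple[int, int, int, int]:
    """2x2 counts (tp, tn, fp, fn); predicted positive iff prob > threshold."""
    labels = np.asarray(labels)
    probs = np.asarray(probs)
    if labels.shape != probs.shape:
        raise EvaluationError("labels/probs length mismatch")
    pred = probs > threshold
    pos = labels == 1
    tp = int(np.sum(pred & pos))
    tn = int(np.sum(~pred & ~pos))
    fp = int(np.sum(pred & ~pos))
    fn = int(np.sum(~pred & pos))
    return tp, tn, fp, fn


def metrics(counts: tuple[int, int, int, int]) -> MetricsReport:
    """The five classification metrics from confusion counts.

    A ratio with zero denominator is reported as 0 and flags the report as
    degenerate rather than raising, so sparse CV folds survive.
    """
    tp, tn, fp, fn = counts
    if min(tp, tn, fp, fn) < 0:
        raise EvaluationError("negative confusion counts")
    total = tp + tn + fp + fn
    if total == 0:
        raise EvaluationError("all confusion counts zero")
    degenerate = False

    def ratio(num: float, den: float) -> float:
        nonlocal degenerate
        if den == 0:
            degenerate = True
            return 0.0
        return num / den

    specificity = ratio(tn, tn + fp)
    accuracy = (tp + tn) / total
    precision = ratio(tp, tp + fp)
    recall = ratio(tp, tp + fn)
    f1 = ratio(2 * precision * recall, precision + recall)
    return MetricsReport(tp, tn, fp, fn, specificity, accuracy, precision, recall, f1, degenerate)


def evaluate_predictions(labels: np.ndarray, probs: np.ndarray, threshold: float = 0.5) -> MetricsReport:
    return metrics(confusion(labels, probs, threshold))


def kfold_cv(
    pairs: Sequence,
    labels: np.ndarray,
    pipeline_fn: Callable[[list, list], np.ndarray],
    k: int = 10,
    seed: int = 0,
) -> tuple[list[MetricsReport], pd.DataFrame]:
    """Stratified k-fold cross-validation.

    ``pipeline_fn(train_idx, test_idx)`` trains on the train split and
    returns probabilities for the test split.  Returns per-fold reports and
    a summary frame with the median and mean of each metric across folds.
    """
    labels = np.asarray(labels)
    n = len(pairs)
    if k > n:
        raise EvaluationError(f"k={k} exceeds n={n}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    reports: list[MetricsReport] = []
    for train_idx, test_idx in skf.split(np.zeros(n), labels):
        probs = pipeline_fn(list(train_idx), list(test_idx))
        reports.append(evaluate_predictions(labels[test_idx], np.asarray(probs)))
    summary = summarize_folds(reports)
    return reports, summary


def summarize_folds(reports: list[MetricsReport]) -> pd.DataFrame:
    per_fold = pd.DataFrame([r.as_dict() for r in reports])
    rows = {}
    for m in METRIC_NAMES:
        rows[m] = {"median": per_fold[m].median(), "mean": per_fold[m].mean()}
    return pd.DataFrame(rows).T[["median", "mean"]]


def length_binned_eval(
    pairs: Sequence,
    labels: np.ndarray,
    lncrna_lengths: np.ndarray,
    eval_fn: Callable[[list], MetricsReport | None],
    bin_edges: Sequence[int] = (500, 1000, 1500, 2000, 2500, 3000),
    cumulative: bool = True,
) -> dict[int, MetricsReport | None]:
    """Evaluate on groups of pairs keyed by maximum lncRNA length.

    With ``cumulative`` (default) the group at edge e contains every pair
    whose lncRNA is at most e nt — so groups are nested; otherwise groups
    are disjoint ranges between consecutive edges.  Empty groups map to
    None (flagged, not fatal).
    """
    edges = list(bin_edges)
    if edges != sorted(edges):
        raise EvaluationError("bin edges must be sorted ascending")
    lncrna_lengths = np.asarray(lncrna_lengths)
    out: dict[int, MetricsReport | None] = {}
    prev = 0
    for edge in edges:
        if cumulative:
            idx = np.nonzero(lncrna_lengths <= edge)[0]
        else:
            idx = np.nonzero((lncrna_lengths > prev) & (lncrna_lengths <= edge))[0]
            prev = edge
        out[edge] = eval_fn(list(idx)) if len(idx) else None
    return out
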