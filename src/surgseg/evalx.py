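"""Evaluation of predicted segmentations against ground truth.

Accuracy is frame-level: build the K x K confusion matrix ``C`` whose entry
``C[i, j]`` counts frames placed in predicted cluster ``i`` and true task
``j``, find the cluster-to-task permutation ``P`` maximizing ``tr(C P)``
with the Hungarian algorithm, and report matched frames over total frames.
Per-task precision/recall/F1 reuse the accuracy-optimal matching.  The
proportional-duration baseline predicts boundaries from average normalized
task durations alone and is the floor any temporal clustering method must
beat.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import linear_sum_assignment

from .containers import ConfusionMatrix, Segmentation, TaskMetrics
from .errors import ValidationError


def confusion_matrix(pred: Segmentation, truth: Segmentation) -> ConfusionMatrix:
    """Frame-count confusion matrix between prediction (rows) and truth (columns)."""
    if pred.N != truth.N:
        raise ValidationError(f"frame counts differ: pred N={pred.N}, truth N={truth.N}")
    K = max(pred.K, truth.K)
    p = pred.frame_labels()
    t = truth.frame_labels()
    C = np.bincount(p * K + t, minlength=K * K).reshape(K, K)
    return ConfusionMatrix(C=C, K=K, N=pred.N)


def optimal_matching(C: ConfusionMatrix) -> np.ndarray:
    """Hungarian matching maximizing matched frames; ``match[j] = predicted
    cluster assigned to true task j``."""
    rows, cols = linear_sum_assignment(-C.C)
    match = np.empty(C.K, dtype=np.int64)
    match[cols] = rows
    return match


def cluster_accuracy(C: ConfusionMatrix) -> float:
    """Fraction of frames correctly labeled under the optimal cluster-task
    permutation, ``max_P tr(C P) / N``."""
    total = int(C.C.sum())
    if total == 0:
        raise ValidationError("confusion matrix is all zeros")
    match = optimal_matching(C)
    return float(C.C[match, np.arange(C.K)].sum()) / total


def per_task_metrics(C: ConfusionMatrix) -> TaskMetrics:
    """Per-task precision, recall and F1 under the accuracy-optimal matching.

    A task with no true frames has undefined recall; its entries are NaN and
    it is excluded from the macro-F1 average.
    """
    match = optimal_matching(C)
    K = C.K
    precision = np.full(K, np.nan)
    recall = np.full(K, np.nan)
    f1 = np.full(K, np.nan)
    for k in range(K):
        tp = C.C[match[k], k]
        pred_total = C.C[match[k], :].sum()
        true_total = C.C[:, k].sum()
        if true_total == 0:
            continue
        precision[k] = tp / pred_total if pred_total else 0.0
        recall[k] = tp / true_total
        pr = precision[k] + recall[k]
        f1[k] = 2.0 * precision[k] * recall[k] / pr if pr > 0 else 0.0
    valid = ~np.isnan(f1)
    if not valid.any():
        raise ValidationError("no task has true frames")
    return TaskMetrics(
        precision=precision,
        recall=recall,
        f1=f1,
        macro_f1=float(f1[valid].mean()),
        matching=match,
    )


def proportional_baseline(train_truths: list[Segmentation], target_N: int) -> Segmentation:
    """Segment a target trial purely from average normalized task durations.

    Each training truth contributes its task durations normalized by trial
    length; the per-task means are renormalized to sum to one, cumulated,
    scaled to ``target_N`` frames and rounded to monotone integer boundaries
    with at least one frame per task.  Labels are 0..K-1 in task order.
    """
    if not train_truths:
        raise ValidationError("need at least one training truth")
    K = train_truths[0].K
    for s in train_truths:
        if s.K != K or not np.array_equal(s.labels, np.arange(K)):
            raise ValidationError("all training truths must have the same tasks in order 0..K-1")
    if target_N < K:
        raise ValidationError(f"target_N={target_N} cannot hold {K} non-empty tasks")
    props = np.mean(
        [s.segment_lengths / s.N for s in train_truths], axis=0
    )
    props = props / props.sum()
    bounds = np.rint(np.concatenate(([0.0], np.cumsum(props))) * target_N).astype(np.int64)
    bounds[0], bounds[-1] = 0, target_N
    # enforce at least one frame per task, keeping boundaries monotone
    for m in range(1, K):
        bounds[m] = max(bounds[m], bounds[m - 1] + 1)
    for m in range(K - 1, 0, -1):
        bounds[m] = min(bounds[m], bounds[m + 1] - 1)
    return Segmentation(boundaries=bounds, labels=np.arange(K), K=K, N=target_N)


def evaluate(pred: Segmentation, truth: Segmentation) -> dict:
    """Convenience bundle: accuracy, per-task metrics and the confusion matrix."""
    C = confusion_matrix(pred, truth)
    tm = per_task_metrics(C)
    return {
        "accuracy": cluster_accuracy(C),
        "macro_f1": tm.macro_f1,
        "precision": tm.precision,
        "recall": tm.recall,
        "f1": tm.f1,
        "matching": tm.matching,
        "confusion": C,
    }
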