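"""Evaluation statistics: accuracy, ROC/AUC, and the DeLong test.

The AUC is computed as the tie-aware Mann-Whitney statistic (ties count 1/2)
via midranks, together with its per-observation placement components: for
each positive the fraction of negatives it outranks (V10) and for each
negative one minus the fraction of positives ranking below it (V01). Those
components carry the sampling structure the DeLong (1988) test needs: for
two score vectors over the same labelled test set, the variance of the AUC
difference follows from the empirical covariances of the paired placements,
giving a z statistic with a two-sided normal p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm, rankdata

from .errors import ContractError, DegenerateInputError

__all__ = ["RocResult", "DeLongComparison", "accuracy", "auc", "delong_test",
           "roc_points", "pairwise_delong"]

_VAR_FLOOR = 1e-12


@dataclass(frozen=True)
class RocResult:
    """Scores/labels with the Mann-Whitney AUC and DeLong placements."""

    scores: np.ndarray
    labels: np.ndarray
    auc: float
    placement_pos: np.ndarray  # V10, one per positive
    placement_neg: np.ndarray  # V01, one per negative


@dataclass(frozen=True)
class DeLongComparison:
    auc_a: float
    auc_b: float
    var_diff: float
    z_stat: float
    p_value: float


def accuracy(labels, predictions) -> float:
    """Fraction of exact matches between binary labels and predictions."""
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if labels.size == 0:
        raise DegenerateInputError("cannot compute accuracy of an empty set")
    if labels.shape != predictions.shape:
        raise ContractError("labels and predictions length mismatch")
    return float((labels == predictions).mean())


def auc(scores, labels) -> RocResult:
    """Tie-aware AUC with DeLong placement components, via midranks."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ContractError("scores and labels must be equal-length 1-D arrays")
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise DegenerateInputError("AUC needs both classes present")
    combined = rankdata(np.concatenate([pos, neg]))  # midranks
    rank_pos_within = rankdata(pos)
    rank_neg_within = rankdata(neg)
    v10 = (combined[:m] - rank_pos_within) / n
    v01 = 1.0 - (combined[m:] - rank_neg_within) / m
    value = float((combined[:m].sum() - m * (m + 1) / 2.0) / (m * n))
    return RocResult(scores=scores, labels=labels, auc=value,
                     placement_pos=v10, placement_neg=v01)


def delong_test(result_a: RocResult, result_b: RocResult) -> DeLongComparison:
    """DeLong test for two correlated AUCs on the same labelled test set.

    The variance of auc_a - auc_b is estimated from the empirical covariance
    matrices of the paired placement components; near-zero variance (e.g. a
    model compared with itself) yields z = 0, p = 1 by convention.
    """
    if not np.array_equal(result_a.labels, result_b.labels):
        raise ContractError("DeLong test requires the same labelled test set")
    m = len(result_a.placement_pos)
    n = len(result_a.placement_neg)
    diff = result_a.auc - result_b.auc
    if np.array_equal(result_a.scores, result_b.scores):
        return DeLongComparison(auc_a=result_a.auc, auc_b=result_b.auc,
                                var_diff=0.0, z_stat=0.0, p_value=1.0)
    if m < 2 or n < 2:
        raise DegenerateInputError("need >=2 observations per class for DeLong")
    s10 = np.cov(result_a.placement_pos, result_b.placement_pos, ddof=1)
    s01 = np.cov(result_a.placement_neg, result_b.placement_neg, ddof=1)
    var_diff = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    var_diff = max(float(var_diff), 0.0)
    if var_diff < _VAR_FLOOR:
        z, p = 0.0, 1.0
    else:
        z = diff / np.sqrt(var_diff)
        p = float(2.0 * norm.sf(abs(z)))
    return DeLongComparison(auc_a=result_a.auc, auc_b=result_b.auc,
                            var_diff=var_diff, z_stat=float(z), p_value=p)


def roc_points(result: RocResult) -> np.ndarray:
    """(fpr, tpr) pairs over all score thresholds, for plotting/export."""
    order = np.argsort(-result.scores, kind="stable")
    labels = result.labels[order]
    scores = result.scores[order]
    tps = np.cumsum(labels == 1)
    fps = np.cumsum(labels == 0)
    # keep the last point of each tied-score block
    keep = np.r_[scores[1:] != scores[:-1], True]
    tpr = np.r_[0.0, tps[keep] / max(tps[-1], 1)]
    fpr = np.r_[0.0, fps[keep] / max(fps[-1], 1)]
    return np.column_stack([fpr, tpr])


def pairwise_delong(results: dict[str, RocResult]
                    ) -> dict[str, dict[str, float | None]]:
    """Full matrix of pairwise DeLong p-values (diagonal is 1 by convention).

    Entries that cannot be computed (too few observations in a class) are
    reported as None."""
    matrix: dict[str, dict[str, float | None]] = {}
    for a in results:
        matrix[a] = {}
        for b in results:
            try:
                matrix[a][b] = delong_test(results[a], results[b]).p_value
            except DegenerateInputError:
                matrix[a][b] = None
    return matrix
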