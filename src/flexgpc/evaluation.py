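"""Prediction-accuracy and feature-selection-stability metrics.

Accuracy@k scores multi-label predictions by the fraction of an instance's
positive labels retrieved among its k highest-scoring labels,
micro-averaged (summed numerators over summed denominators) across
instances.  AUC is the usual Mann-Whitney statistic for a binary outcome.

Stability quantifies how reproducible the learned masks are across
independent training runs: RankSim compares two masks by the fraction of
rank positions occupied by the same feature in their descending-value
orderings, and Stability(i) averages RankSim over all ordered pairs of the
B runs (including a run with itself, so identical runs score exactly 1 and
any run set scores at least 1/B).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

__all__ = [
    "MaskRunSet",
    "accuracy_at_k",
    "auc",
    "rank_sim",
    "stability",
    "mean_stability",
]


@dataclass(frozen=True)
class MaskRunSet:
    """B x n x d stack of masks from B training runs on the same data."""

    masks: np.ndarray

    def __post_init__(self):
        masks = np.asarray(self.masks, dtype=np.float64)
        object.__setattr__(self, "masks", masks)
        if masks.ndim != 3 or masks.shape[0] < 1:
            raise ValueError("masks must be a B x n x d array with B >= 1")
        if masks.min() < 0 or masks.max() > 1:
            raise ValueError("mask entries must lie in [0, 1]")

    @property
    def B(self) -> int:
        return self.masks.shape[0]


def accuracy_at_k(Ytrue: np.ndarray, scores: np.ndarray, k: int) -> float:
    """Micro-averaged top-k retrieval of positive labels.

    Instances with no positive labels are skipped (their denominator is
    zero).  ``k`` larger than the label space is truncated with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    Y = np.atleast_2d(np.asarray(Ytrue))
    S = np.atleast_2d(np.asarray(scores, dtype=np.float64))
    if Y.shape != S.shape:
        raise ValueError(f"label/score shape mismatch {Y.shape} vs {S.shape}")
    c = Y.shape[1]
    if k > c:
        warnings.warn(f"k={k} exceeds label space size {c}; truncating", stacklevel=2)
        k = c
    hits = 0
    positives = 0
    for y, s in zip(Y, S):
        npos = int((y > 0).sum())
        if npos == 0:
            continue
        topk = np.argsort(-s, kind="stable")[:k]
        hits += int((y[topk] > 0).sum())
        positives += npos
    if positives == 0:
        raise ValueError("no instance has a positive label")
    return hits / positives


def auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve (Mann-Whitney with 0.5 credit for ties)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: both classes must be present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=np.float64)))


def _ranking(m: np.ndarray) -> np.ndarray:
    """Feature indices sorted by descending mask value, ties by index."""
    # stable sort on -m keeps ascending-index order among ties
    return np.argsort(-np.asarray(m, dtype=np.float64), kind="stable")


def rank_sim(mp: np.ndarray, mq: np.ndarray) -> float:
    """Fraction of rank positions holding the same feature in both masks."""
    mp = np.asarray(mp, dtype=np.float64)
    mq = np.asarray(mq, dtype=np.float64)
    if mp.shape != mq.shape or mp.ndim != 1:
        raise ValueError("masks must be equal-length vectors")
    return float((_ranking(mp) == _ranking(mq)).mean())


def stability(runs: MaskRunSet, i: int) -> float:
    """Mean RankSim over all ordered pairs of runs for instance i."""
    masks = runs.masks[:, i, :]
    B = runs.B
    rankings = np.stack([_ranking(m) for m in masks])
    total = 0.0
    for p in range(B):
        for q in range(B):
            total += float((rankings[p] == rankings[q]).mean())
    return total / B**2


def mean_stability(runs: MaskRunSet) -> float:
    """Stability averaged over all instances."""
    n = runs.masks.shape[1]
    return float(np.mean([stability(runs, i) for i in range(n)]))
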