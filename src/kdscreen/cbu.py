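"""Clustering-based undersampling (CBU).

The training cohort is partitioned with k-means++ (configurable distance
metric) and low-information clusters are discarded by rule: clusters
containing no positive cases, and the negatives of clusters whose
negative-to-positive ratio exceeds a threshold (default 200). Positives
inside over-threshold clusters are retained by default, so undersampling
never reduces the minority class.

The k-means implementation is written here rather than delegated because
the method under test swaps the assignment metric (Euclidean, Manhattan or
cosine) while keeping coordinate-mean centroid updates — a pragmatic
"metric-swapped Lloyd" variant. True k-medians / spherical k-means are out
of scope. Clustering operates on raw, unscaled features by default; an
optional standardization flag exists for external data.

Determinism contract: D-squared (k-means++) seeding uses the configured
seed; distance ties break toward the lowest cluster index; clusters emptied
during Lloyd iteration are re-seeded from the point farthest from its
assigned centroid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .cohort import CohortTable

_METRICS = {"euclidean": "euclidean", "manhattan": "cityblock", "cosine": "cosine"}


@dataclass(frozen=True)
class ClusteringConfig:
    k: int = 10
    metric: str = "euclidean"
    max_iter: int = 100
    tol: float = 1e-4
    seed: int = 0
    standardize: bool = False

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.tol < 0:
            raise ValueError("tol must be non-negative")
        if self.metric not in _METRICS:
            raise ValueError(f"metric must be one of {sorted(_METRICS)}")


@dataclass
class ClusterAssignment:
    config: ClusteringConfig
    labels_by_row: np.ndarray   # cluster index per row, in [0, k)
    centroids: np.ndarray       # (k, n_features)
    n_iter_run: int

    @property
    def k(self) -> int:
        return self.centroids.shape[0]


@dataclass(frozen=True)
class ClusterSummary:
    cluster_id: int
    n_pos: int
    n_neg: int
    neg_per_pos: float  # NaN when pure negative

    @property
    def pure_negative(self) -> bool:
        return self.n_pos == 0


@dataclass(frozen=True)
class FilterPolicy:
    """Discard rule: pure-negative clusters and negatives of clusters beyond
    ``max_neg_per_pos`` (strict comparison; a cluster exactly at the boundary
    is retained)."""

    max_neg_per_pos: float = 200.0
    drop_pure_negative: bool = True
    retain_positives_from_dropped: bool = True

    def __post_init__(self) -> None:
        if self.max_neg_per_pos <= 0:
            raise ValueError("max_neg_per_pos must be positive")


def _distances(X: np.ndarray, C: np.ndarray, metric: str) -> np.ndarray:
    return cdist(X, C, metric=_METRICS[metric])


def _plus_plus_seeding(X: np.ndarray, k: int, metric: str, rng: np.random.Generator) -> np.ndarray:
    n = X.shape[0]
    centers = [int(rng.integers(n))]
    for _ in range(1, k):
        d = _distances(X, X[centers], metric).min(axis=1) ** 2
        total = d.sum()
        if total <= 0:
            # all remaining points coincide with a center; pick any
            centers.append(int(rng.integers(n)))
            continue
        centers.append(int(rng.choice(n, p=d / total)))
    return X[centers].copy()


def assign_clusters(table: CohortTable, config: ClusteringConfig) -> ClusterAssignment:
    """k-means++ clustering of the cohort's feature matrix.

    Lloyd iterations assign by the configured metric and update centroids by
    the coordinate-wise mean; iteration stops when the largest centroid
    movement (Euclidean) falls below ``tol`` or after ``max_iter`` rounds.
    """
    X = table.values
    if table.n_rows < config.k:
        raise ValueError(
            f"need at least k={config.k} rows, got {table.n_rows}"
        )
    if config.metric == "cosine":
        norms = np.linalg.norm(X, axis=1)
        zero = np.flatnonzero(norms == 0)
        if zero.size:
            raise ValueError(
                f"row {int(zero[0])} is a zero vector; cosine distance undefined"
            )
    if config.standardize:
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd

    rng = np.random.default_rng(config.seed)
    C = _plus_plus_seeding(X, config.k, config.metric, rng)
    assign = np.zeros(table.n_rows, dtype=int)
    n_iter = 0
    for n_iter in range(1, config.max_iter + 1):
        D = _distances(X, C, config.metric)
        assign = D.argmin(axis=1)  # argmin breaks ties toward lowest index
        newC = C.copy()
        for c in range(config.k):
            members = np.flatnonzero(assign == c)
            if members.size:
                newC[c] = X[members].mean(axis=0)
            else:
                # re-seed the empty cluster from the globally farthest point
                far = int(D[np.arange(len(assign)), assign].argmax())
                newC[c] = X[far]
                assign[far] = c
        movement = np.linalg.norm(newC - C, axis=1).max()
        C = newC
        if movement < config.tol:
            break
    # final assignment against the converged centroids
    assign = _distances(X, C, config.metric).argmin(axis=1)
    return ClusterAssignment(config=config, labels_by_row=assign, centroids=C, n_iter_run=n_iter)


def summarize_clusters(
    assignment: ClusterAssignment, labels: np.ndarray | Sequence[int]
) -> list[ClusterSummary]:
    """Per-cluster positive/negative counts for every non-empty cluster."""
    labels = np.asarray(labels, dtype=int)
    if labels.shape[0] != assignment.labels_by_row.shape[0]:
        raise ValueError("labels length does not match cluster assignment")
    out = []
    for c in range(assignment.k):
        members = assignment.labels_by_row == c
        if not members.any():
            continue
        n_pos = int(labels[members].sum())
        n_neg = int(members.sum() - n_pos)
        ratio = n_neg / n_pos if n_pos else math.nan
        out.append(ClusterSummary(c, n_pos, n_neg, ratio))
    return out


def filter_clusters(
    table: CohortTable,
    assignment: ClusterAssignment,
    policy: FilterPolicy = FilterPolicy(),
) -> CohortTable:
    """Apply the discard rule, returning rows in stable original order.

    Pure-negative clusters are removed entirely (when ``drop_pure_negative``);
    clusters with neg/pos strictly above ``max_neg_per_pos`` lose their
    negatives, keeping positives unless ``retain_positives_from_dropped``
    is off (the literal whole-cluster reading).
    """
    if assignment.labels_by_row.shape[0] != table.n_rows:
        raise ValueError("assignment does not match table")
    keep = np.ones(table.n_rows, dtype=bool)
    for s in summarize_clusters(assignment, table.labels):
        members = assignment.labels_by_row == s.cluster_id
        if s.pure_negative:
            if policy.drop_pure_negative:
                keep[members] = False
        elif s.neg_per_pos > policy.max_neg_per_pos:
            if policy.retain_positives_from_dropped:
                keep[members & (table.labels == 0)] = False
            else:
                keep[members] = False
    return table.subset(np.flatnonzero(keep))


def random_undersample(
    table: CohortTable, target_ratio: float = 1.0, seed: int = 0
) -> CohortTable:
    """Uniform random undersampling of negatives to ``target_ratio`` neg/pos.

    Baseline comparator for CBU. The default target of 1.0 is the
    conventional balanced undersampler (the default of standard resampling
    toolkits); any ratio can be requested, e.g. the negative budget a
    cluster filter would have retained. Positives are untouched; negatives
    are sampled without replacement down to ``floor(target_ratio * n_pos)``
    (or kept whole if already at or below the target). Stable row order.
    """
    if target_ratio <= 0:
        raise ValueError("target_ratio must be positive")
    n_keep = int(target_ratio * table.n_pos)
    neg_idx = np.flatnonzero(table.labels == 0)
    if neg_idx.size <= n_keep:
        return table.subset(np.arange(table.n_rows))
    rng = np.random.default_rng(seed)
    kept_neg = rng.choice(neg_idx, size=n_keep, replace=False)
    keep = np.sort(np.concatenate([np.flatnonzero(table.labels == 1), kept_neg]))
    return table.subset(keep)
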