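"""Clustering of embedded coordinates and chance-adjusted partition scores.

k-means (k-means++ / Lloyd, best of several restarts) is delegated to
scikit-learn; the adjusted Rand score and adjusted mutual information are
implemented here from the contingency table, since their adjustment
contracts (expected value 0 under random labelings, maximum 1 on identical
partitions) are load-bearing for the pipeline's conclusions and are pinned
by independent brute-force oracles in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln
from sklearn.cluster import KMeans

from whitemap.embedding import EmbeddingResult
from whitemap.io_core import ValidationError

__all__ = [
    "ClusteringResult",
    "ContingencyTable",
    "kmeans",
    "contingency_table",
    "adjusted_rand_score",
    "adjusted_mutual_information",
    "evaluate_embedding",
]


@dataclass(frozen=True)
class ClusteringResult:
    labels: np.ndarray
    k: int
    inertia: float
    seed: int
    n_restarts: int


@dataclass(frozen=True)
class ContingencyTable:
    """Cross-tabulation of two labelings of the same N objects."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or np.any(counts < 0):
            raise ValidationError("contingency counts must be a nonnegative matrix")

    @property
    def row_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def n(self) -> int:
        return int(self.counts.sum())


def kmeans(
    X: np.ndarray,
    k: int,
    seed: int = 0,
    n_restarts: int = 10,
) -> ClusteringResult:
    """Lloyd's algorithm with k-means++ initialization, best inertia over
    ``n_restarts``; deterministic for a fixed seed."""
    X = np.asarray(X, dtype=float)
    if not 1 <= k <= X.shape[0]:
        raise ValidationError(f"k={k} out of range [1, {X.shape[0]}]")
    km = KMeans(
        n_clusters=k,
        init="k-means++",
        n_init=n_restarts,
        random_state=seed,
        algorithm="lloyd",
    ).fit(X)
    return ClusteringResult(
        labels=km.labels_.astype(np.int64),
        k=k,
        inertia=float(km.inertia_),
        seed=seed,
        n_restarts=n_restarts,
    )


def _check_labels(truth: Sequence, pred: Sequence) -> tuple[np.ndarray, np.ndarray]:
    truth, pred = np.asarray(truth), np.asarray(pred)
    if truth.shape != pred.shape or truth.ndim != 1:
        raise ValidationError("label vectors must be 1-D and equal length")
    if truth.size < 2:
        raise ValidationError("need at least 2 labeled objects")
    return truth, pred


def contingency_table(truth: Sequence, pred: Sequence) -> ContingencyTable:
    truth, pred = _check_labels(truth, pred)
    _, ti = np.unique(truth, return_inverse=True)
    _, pi = np.unique(pred, return_inverse=True)
    counts = np.zeros((ti.max() + 1, pi.max() + 1), dtype=np.int64)
    np.add.at(counts, (ti, pi), 1)
    return ContingencyTable(counts=counts)


def _comb2(x: np.ndarray) -> np.ndarray:
    return x * (x - 1) // 2


def adjusted_rand_score(truth: Sequence, pred: Sequence) -> float:
    """Hubert-Arabie ARS: (Index - E[Index]) / (MaxIndex - E[Index]).

    1 iff the two labelings induce the same partition; expected value 0
    for independent random labelings; invariant to label renaming.
    """
    table = contingency_table(truth, pred)
    nij = table.counts
    a, b = table.row_marginals, table.col_marginals
    n = table.n
    sum_comb = _comb2(nij).sum()
    sum_a = _comb2(a).sum()
    sum_b = _comb2(b).sum()
    total = _comb2(np.int64(n))
    expected = sum_a * sum_b / total
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:  # both partitions trivial (all-one-cluster or all-singletons)
        return 1.0
    return float((sum_comb - expected) / (max_index - expected))


def _entropy(marginals: np.ndarray, n: int) -> float:
    p = marginals[marginals > 0] / n
    return float(-(p * np.log(p)).sum())


def _mutual_information(table: ContingencyTable) -> float:
    n = table.n
    nij = table.counts
    a = table.row_marginals
    b = table.col_marginals
    mask = nij > 0
    i, j = np.nonzero(mask)
    nz = nij[mask].astype(float)
    return float(
        np.sum(nz / n * (np.log(n * nz) - np.log(a[i] * b[j].astype(float))))
    )


def _expected_mutual_information(table: ContingencyTable) -> float:
    """E[MI] under the permutation (hypergeometric) null, by direct
    summation over all feasible cell counts."""
    n = table.n
    a = table.row_marginals
    b = table.col_marginals
    log_fact = gammaln(np.arange(n + 2) + 1.0)  # log(x!)
    emi = 0.0
    for ai in a:
        for bj in b:
            lo = max(int(ai + bj - n), 1)
            hi = int(min(ai, bj))
            for t in range(lo, hi + 1):
                log_p = (
                    log_fact[ai]
                    + log_fact[bj]
                    + log_fact[n - ai]
                    + log_fact[n - bj]
                    - log_fact[n]
                    - log_fact[t]
                    - log_fact[ai - t]
                    - log_fact[bj - t]
                    - log_fact[n - ai - bj + t]
                )
                emi += (t / n) * (np.log(t * n) - np.log(ai * float(bj))) * np.exp(log_p)
    return float(emi)


def adjusted_mutual_information(truth: Sequence, pred: Sequence) -> float:
    """AMI = (MI - E[MI]) / (mean(H_truth, H_pred) - E[MI]) with E[MI]
    under the hypergeometric permutation model.

    Degenerate single-cluster-vs-single-cluster input (both entropies 0,
    hence identical partitions) scores 1; other vanishing normalizers
    score 0.
    """
    table = contingency_table(truth, pred)
    h_t = _entropy(table.row_marginals, table.n)
    h_p = _entropy(table.col_marginals, table.n)
    if h_t == 0.0 and h_p == 0.0:
        return 1.0
    mi = _mutual_information(table)
    emi = _expected_mutual_information(table)
    normalizer = (h_t + h_p) / 2.0 - emi
    if abs(normalizer) < np.finfo(float).eps:
        return 0.0
    return float((mi - emi) / normalizer)


def evaluate_embedding(
    coords: EmbeddingResult | np.ndarray,
    subject_labels: Sequence,
    task_labels: Sequence,
    seed: int = 0,
    n_restarts: int = 10,
) -> pd.DataFrame:
    """Cluster the embedded coordinates twice — k = number of subjects,
    scored against subject labels, and k = number of tasks, scored against
    task labels — and return the 2x2 {AMI, ARS} x {task, subject} table."""
    X = coords.coordinates if isinstance(coords, EmbeddingResult) else np.asarray(coords)
    subject_labels = np.asarray(subject_labels)
    task_labels = np.asarray(task_labels)
    if len(subject_labels) != X.shape[0] or len(task_labels) != X.shape[0]:
        raise ValidationError("label lengths must match the number of rows")
    k_subject = len(np.unique(subject_labels))
    k_task = len(np.unique(task_labels))
    by_subject = kmeans(X, k_subject, seed=seed, n_restarts=n_restarts)
    by_task = kmeans(X, k_task, seed=seed, n_restarts=n_restarts)
    return pd.DataFrame(
        {
            "task": {
                "AMI": adjusted_mutual_information(task_labels, by_task.labels),
                "ARS": adjusted_rand_score(task_labels, by_task.labels),
            },
            "subject": {
                "AMI": adjusted_mutual_information(subject_labels, by_subject.labels),
                "ARS": adjusted_rand_score(subject_labels, by_subject.labels),
            },
        }
    )
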