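"""Distances between scans and connectomes.

Implements the Frobenius distance on raw task scans, fidelity and the Bures
distance on PSD connectomes, and the composed dM dissimilarity (de-mean +
whiten the parent, extract the task scan, Frobenius distance).  dM is not a
metric — it can break the triangle inequality — and nothing here assumes
otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from whitemap.io_core import (
    DistanceMatrix,
    ParentScan,
    TaskScan,
    ValidationError,
)
from whitemap.whitening import WhitenedParentScan, preprocess_parent

logger = logging.getLogger(__name__)

__all__ = [
    "Connectome",
    "correlation_connectome",
    "covariance_connectome",
    "psd_sqrt",
    "fidelity",
    "bures_distance",
    "frobenius_distance",
    "dm_distance",
    "pairwise_distances",
]

_PSD_TOL = 1e-10


@dataclass(frozen=True)
class Connectome:
    """Symmetric PSD region-by-region matrix summarizing a task scan."""

    matrix: np.ndarray
    kind: Literal["correlation", "covariance"]
    subject_id: str = ""
    task_label: str = ""

    def __post_init__(self) -> None:
        A = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", A)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValidationError("connectome must be a square matrix")
        if not np.allclose(A, A.T, rtol=0, atol=1e-10):
            raise ValidationError("connectome must be symmetric")
        eigvals = np.linalg.eigvalsh(A)
        lam_max = max(float(eigvals[-1]), 0.0)
        if eigvals[0] < -_PSD_TOL * max(lam_max, 1.0):
            raise ValidationError(
                f"connectome is not PSD (min eigenvalue {eigvals[0]:.3g})"
            )
        if self.kind == "correlation":
            if not np.allclose(np.diagonal(A), 1.0, atol=1e-8):
                raise ValidationError(
                    "correlation connectome must have unit diagonal"
                )

    @property
    def m(self) -> int:
        return self.matrix.shape[0]


def _scan_data(T: TaskScan | np.ndarray) -> np.ndarray:
    return T.data if isinstance(T, TaskScan) else np.asarray(T, dtype=float)


def correlation_connectome(T: TaskScan | np.ndarray) -> Connectome:
    """Pearson correlation of the rows of a task scan, region against
    region.

    Raises on constant rows (correlation undefined), naming the first
    offending region index.
    """
    data = _scan_data(T)
    if data.shape[1] < 3:
        raise ValidationError("need at least 3 time points for correlation")
    sd = data.std(axis=1, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValidationError(
            f"region {bad[0]} has constant signal; correlation undefined"
        )
    C = np.corrcoef(data, rowvar=True)
    C = np.clip((C + C.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    # clamp tiny negative eigenvalues from roundoff so Connectome validates
    eigvals, eigvecs = np.linalg.eigh(C)
    if eigvals[0] < 0:
        eigvals = np.clip(eigvals, 0.0, None)
        C = (eigvecs * eigvals) @ eigvecs.T
        C = (C + C.T) / 2.0
        np.fill_diagonal(C, 1.0)
    subject = T.subject_id if isinstance(T, TaskScan) else ""
    task = T.task_label if isinstance(T, TaskScan) else ""
    return Connectome(matrix=C, kind="correlation", subject_id=subject, task_label=task)


def covariance_connectome(T: TaskScan | np.ndarray) -> Connectome:
    """Sample covariance (ddof=1) of the rows of a task scan."""
    data = _scan_data(T)
    if data.shape[1] < 2:
        raise ValidationError("need at least 2 time points for covariance")
    W = np.atleast_2d(np.cov(data, rowvar=True, ddof=1))
    W = (W + W.T) / 2.0
    subject = T.subject_id if isinstance(T, TaskScan) else ""
    task = T.task_label if isinstance(T, TaskScan) else ""
    return Connectome(matrix=W, kind="covariance", subject_id=subject, task_label=task)


def psd_sqrt(A: np.ndarray, tol: float = _PSD_TOL) -> np.ndarray:
    """Symmetric PSD square root via eigendecomposition; negative
    eigenvalues within ``-tol * lambda_max`` are clamped to zero."""
    A = np.asarray(A, dtype=float)
    A = (A + A.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(A)
    lam_max = max(float(eigvals[-1]), 0.0)
    if eigvals[0] < -tol * max(lam_max, 1.0):
        raise ValidationError(
            f"input not PSD (min eigenvalue {eigvals[0]:.3g})"
        )
    eigvals = np.clip(eigvals, 0.0, None)
    R = (eigvecs * np.sqrt(eigvals)) @ eigvecs.T
    return (R + R.T) / 2.0


def _as_matrix(A: Connectome | np.ndarray) -> np.ndarray:
    return A.matrix if isinstance(A, Connectome) else np.asarray(A, dtype=float)


def fidelity(A: Connectome | np.ndarray, B: Connectome | np.ndarray) -> float:
    """Fidelity of two PSD matrices: ``(tr sqrt(sqrt(A) B sqrt(A)))**2``."""
    A, B = _as_matrix(A), _as_matrix(B)
    if A.shape != B.shape:
        raise ValidationError(f"shape mismatch {A.shape} vs {B.shape}")
    rootA = psd_sqrt(A)
    inner = rootA @ B @ rootA
    eigvals = np.linalg.eigvalsh((inner + inner.T) / 2.0)
    trace_root = float(np.sqrt(np.clip(eigvals, 0.0, None)).sum())
    return trace_root**2


def bures_distance(
    A: Connectome | np.ndarray, B: Connectome | np.ndarray
) -> float:
    """Bures distance ``sqrt(tr A + tr B - 2 sqrt(F(A, B)))``.

    The radicand is clamped at 0 against roundoff so that the distance of a
    matrix to itself is exactly 0.
    """
    Am, Bm = _as_matrix(A), _as_matrix(B)
    if Am.shape != Bm.shape:
        raise ValidationError(f"shape mismatch {Am.shape} vs {Bm.shape}")
    if Am is Bm or np.array_equal(Am, Bm):
        return 0.0
    trace_sum = float(np.trace(Am) + np.trace(Bm))
    radicand = trace_sum - 2.0 * np.sqrt(fidelity(Am, Bm))
    # A ~= B leaves machine-eps noise in the radicand; its square root
    # would be ~1e-8, far above the true distance, so zero it out
    if radicand < 64.0 * np.finfo(float).eps * abs(trace_sum):
        return 0.0
    return float(np.sqrt(radicand))


def frobenius_distance(
    A: TaskScan | np.ndarray, B: TaskScan | np.ndarray
) -> float:
    """Frobenius (entrywise Euclidean) distance between equal-shape
    matrices."""
    A, B = _scan_data(A), _scan_data(B)
    if A.shape != B.shape:
        raise ValidationError(
            f"shape mismatch {A.shape} vs {B.shape}; unequal task-scan "
            "lengths must be truncated to a common length first"
        )
    return float(np.linalg.norm(A - B))


# ---------------------------------------------------------------------------
# the dM dissimilarity
# ---------------------------------------------------------------------------


def _whitened_block(
    wp: WhitenedParentScan, interval_index: int
) -> np.ndarray:
    intervals = wp.annotation.intervals
    if not 0 <= interval_index < len(intervals):
        raise ValidationError(
            f"interval index {interval_index} out of range "
            f"[0, {len(intervals)})"
        )
    start, end, _ = intervals[interval_index]
    return wp.data[:, start:end]


def _common_length(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if X.shape[0] != Y.shape[0]:
        raise ValidationError(
            f"region count mismatch {X.shape[0]} vs {Y.shape[0]}"
        )
    if X.shape[1] != Y.shape[1]:
        L = min(X.shape[1], Y.shape[1])
        logger.warning(
            "task scans have unequal lengths %d vs %d; truncating both "
            "to %d from the block start",
            X.shape[1],
            Y.shape[1],
            L,
        )
        X, Y = X[:, :L], Y[:, :L]
    return X, Y


def dm_distance(
    parent1: ParentScan,
    parent2: ParentScan,
    idx1: int,
    idx2: int,
    ridge: float = 0.0,
) -> float:
    """dM dissimilarity between two task scans, referenced by parent scan
    and interval index.

    Each parent is de-meaned and whitened as a whole, the indexed task
    scans are extracted from the whitened parents, and their Frobenius
    distance is returned.  Symmetric and zero on identical arguments, but
    NOT a metric (the triangle inequality can fail).
    """
    wp1 = preprocess_parent(parent1, ridge=ridge)
    wp2 = (
        wp1
        if parent2 is parent1
        else preprocess_parent(parent2, ridge=ridge)
    )
    X = _whitened_block(wp1, idx1)
    Y = _whitened_block(wp2, idx2)
    X, Y = _common_length(X, Y)
    return frobenius_distance(X, Y)


# ---------------------------------------------------------------------------
# pairwise assembly
# ---------------------------------------------------------------------------


def _task_scan_id(T: TaskScan, i: int) -> str:
    base = f"{T.subject_id}:{T.task_label}"
    return f"{base}#{i}"


def _pairwise_from_blocks(
    blocks: list[np.ndarray], ids: list[str], metric_name: str
) -> DistanceMatrix:
    L = min(b.shape[1] for b in blocks)
    if any(b.shape[1] != L for b in blocks):
        logger.warning("truncating task scans to common length %d", L)
    flat = np.stack([b[:, :L].ravel() for b in blocks])
    diff = flat[:, None, :] - flat[None, :, :]
    values = np.sqrt((diff**2).sum(axis=2))
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(values=values, object_ids=tuple(ids), metric_name=metric_name)


def pairwise_distances(
    objects: Sequence,
    metric: Literal["frobenius_raw", "bures_connectome", "dm"],
    ridge: float = 0.0,
    connectome_kind: Literal["correlation", "covariance"] = "correlation",
) -> DistanceMatrix:
    """Assemble the full pairwise distance matrix for one of the three
    pipeline metrics.

    ``frobenius_raw`` and ``bures_connectome`` take a sequence of
    :class:`TaskScan`; ``dm`` takes a sequence of ``(ParentScan,
    interval_index)`` pairs and whitens each distinct parent exactly once.
    """
    n = len(objects)
    if n < 2:
        raise ValidationError("need at least 2 objects for pairwise distances")

    if metric == "frobenius_raw":
        scans: list[TaskScan] = list(objects)
        ids = [_task_scan_id(T, i) for i, T in enumerate(scans)]
        return _pairwise_from_blocks(
            [T.data for T in scans], ids, "frobenius_raw"
        )

    if metric == "bures_connectome":
        scans = list(objects)
        ids = [_task_scan_id(T, i) for i, T in enumerate(scans)]
        make = (
            correlation_connectome
            if connectome_kind == "correlation"
            else covariance_connectome
        )
        conns = [make(T) for T in scans]
        roots = [psd_sqrt(C.matrix) for C in conns]
        traces = [float(np.trace(C.matrix)) for C in conns]
        values = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                inner = roots[i] @ conns[j].matrix @ roots[i]
                ev = np.linalg.eigvalsh((inner + inner.T) / 2.0)
                sqrt_fid = float(np.sqrt(np.clip(ev, 0.0, None)).sum())
                rad = traces[i] + traces[j] - 2.0 * sqrt_fid
                values[i, j] = values[j, i] = np.sqrt(max(rad, 0.0))
        return DistanceMatrix(
            values=values, object_ids=tuple(ids), metric_name="bures_connectome"
        )

    if metric == "dm":
        pairs: list[tuple[ParentScan, int]] = list(objects)
        cache: dict[int, WhitenedParentScan] = {}
        blocks, ids = [], []
        for i, (parent, idx) in enumerate(pairs):
            key = id(parent)
            if key not in cache:
                cache[key] = preprocess_parent(parent, ridge=ridge)
            wp = cache[key]
            blocks.append(np.asarray(_whitened_block(wp, idx)))
            label = wp.annotation.intervals[idx][2]
            ids.append(f"{parent.subject_id}:{label}#{i}")
        return _pairwise_from_blocks(blocks, ids, "dm")

    raise ValidationError(f"unknown metric {metric!r}")
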