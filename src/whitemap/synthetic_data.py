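"""Synthetic cohorts of parent scans with the three statistical structures
the pipeline's distances are designed to detect:

1. per-subject, per-region mean offsets that are nearly constant across a
   subject's tasks (picked up by the raw Frobenius distance);
2. subject-specific inter-region correlation structure (picked up by the
   Bures distance on connectomes);
3. task-specific spatial activation patterns, shared across subjects, which
   survive de-meaning and whitening (picked up by the dM dissimilarity).

A "retest" session regenerates every parent with the same task multiset in
a fixed permuted order and fresh noise draws.  All randomness descends
hierarchically from ``(seed, stream-tag, subject, task-slot)`` so outputs
are reproducible regardless of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

from whitemap.io_core import ParentScan, TaskAnnotation, ValidationError

__all__ = [
    "CohortConfig",
    "generate_subject_profile",
    "generate_task_pattern",
    "generate_task_patterns",
    "generate_parent_scan",
    "generate_cohort",
    "RETEST_ORDER_8",
]

#: fixed reordering applied to 8-task retest sessions
RETEST_ORDER_8 = (2, 3, 5, 6, 0, 7, 1, 4)

# internal RNG stream tags
_STREAM_SHARED = 0
_STREAM_PROFILE = 1
_STREAM_NOISE = 2
_STREAM_RETEST = 3


@dataclass(frozen=True)
class CohortConfig:
    """Knobs of the synthetic cohort generator.

    Desk-scale defaults keep full-pipeline runs to seconds; the nominal
    shape of the real data (268 regions, 959 subjects) is reachable by
    overriding ``m_regions``/``n_subjects`` but is not exercised in tests.
    """

    n_subjects: int = 20
    n_tasks: int = 8
    m_regions: int = 30
    timepoints_per_task: int = 60
    subject_mean_scale: float = 20.0
    subject_cov_strength: float = 0.8
    task_signal_strength: float = 3.0
    noise_sd: float = 0.5
    seed: int = 0
    session: Literal["test", "retest"] = "test"

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValidationError("n_subjects must be >= 1")
        if self.n_tasks < 2:
            raise ValidationError("n_tasks must be >= 2")
        if self.n_tasks > self.m_regions:
            raise ValidationError(
                "n_tasks > m_regions: cannot orthogonalize task patterns"
            )
        for name in (
            "subject_mean_scale",
            "task_signal_strength",
            "noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not 0.0 <= self.subject_cov_strength < 1.0:
            raise ValidationError("subject_cov_strength must be in [0, 1)")
        if self.total_timepoints <= self.m_regions:
            raise ValidationError(
                "total time points <= m_regions: whitening will be "
                "singular; increase timepoints_per_task"
            )
        if self.session not in ("test", "retest"):
            raise ValidationError("session must be 'test' or 'retest'")

    @property
    def total_timepoints(self) -> int:
        return self.n_tasks * self.timepoints_per_task

    @property
    def task_labels(self) -> tuple[str, ...]:
        return tuple(f"task{t}" for t in range(self.n_tasks))

    def task_order(self) -> tuple[int, ...]:
        """Block order of tasks within a parent scan for this session."""
        if self.session == "test":
            return tuple(range(self.n_tasks))
        if self.n_tasks == 8:
            return RETEST_ORDER_8
        rng = np.random.default_rng([self.seed, _STREAM_RETEST])
        return tuple(int(t) for t in rng.permutation(self.n_tasks))


def generate_subject_profile(
    config: CohortConfig, subject_index: int
) -> tuple[np.ndarray, np.ndarray]:
    """Per-subject (mean_offsets, correlation_factor).

    ``mean_offsets`` is a shared baseline plus a per-subject perturbation
    with spread ``subject_mean_scale``; ``correlation_factor`` is the SPD
    mixing matrix ``C_s = (1 - w) I + w Q_s L Q_s^T`` with a seeded random
    orthogonal ``Q_s`` and positive spectrum ``L``.  Deterministic given
    (seed, subject_index).
    """
    m = config.m_regions
    shared_rng = np.random.default_rng([config.seed, _STREAM_SHARED])
    baseline = 1000.0 + 50.0 * shared_rng.standard_normal(m)
    rng = np.random.default_rng([config.seed, _STREAM_PROFILE, subject_index])
    mean_offsets = baseline + config.subject_mean_scale * rng.standard_normal(m)
    w = config.subject_cov_strength
    Q = np.linalg.qr(rng.standard_normal((m, m)))[0]
    lam = rng.uniform(0.2, 2.0, size=m)
    C = (1.0 - w) * np.eye(m) + w * (Q * lam) @ Q.T
    return mean_offsets, (C + C.T) / 2.0


def generate_task_patterns(config: CohortConfig) -> np.ndarray:
    """All task patterns as an (n_tasks, m) array of orthonormal rows,
    shared by every subject and session; deterministic given the seed."""
    rng = np.random.default_rng([config.seed, _STREAM_SHARED, 1])
    raw = rng.standard_normal((config.m_regions, config.n_tasks))
    Q = np.linalg.qr(raw)[0]  # orthonormal columns
    return Q.T.copy()


def generate_task_pattern(config: CohortConfig, task_index: int) -> np.ndarray:
    """Unit-norm spatial loading vector of one task."""
    if not 0 <= task_index < config.n_tasks:
        raise ValidationError(f"task index {task_index} out of range")
    return generate_task_patterns(config)[task_index]


def activation_waveform(length: int) -> np.ndarray:
    """Raised-cosine bump spanning a task block (smooth on/off ramp)."""
    j = np.arange(length)
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * (j + 0.5) / length))


def generate_parent_scan(config: CohortConfig, subject_index: int) -> ParentScan:
    """One parent scan: task blocks concatenated in the session's task
    order, each block carrying the subject's mean offsets and correlation
    flavor plus the task's activation pattern and white noise."""
    m, L = config.m_regions, config.timepoints_per_task
    mean_offsets, C = generate_subject_profile(config, subject_index)
    # C = Q((1-w)I + wL)Q^T, so the symmetric square root is cheap via eigh
    eigvals, eigvecs = np.linalg.eigh(C)
    C_root = (eigvecs * np.sqrt(np.clip(eigvals, 0.0, None))) @ eigvecs.T
    patterns = generate_task_patterns(config)
    wave = activation_waveform(L)
    session_code = 0 if config.session == "test" else 1
    blocks = []
    intervals = []
    for slot, task_index in enumerate(config.task_order()):
        rng = np.random.default_rng(
            [config.seed, _STREAM_NOISE, subject_index, slot, session_code]
        )
        z = rng.standard_normal((m, L))
        eps = rng.standard_normal((m, L))
        block = (
            mean_offsets[:, None]
            + C_root @ z
            + config.task_signal_strength
            * np.outer(patterns[task_index], wave)
            + config.noise_sd * eps
        )
        blocks.append(block)
        start = slot * L
        intervals.append((start, start + L, config.task_labels[task_index]))
    return ParentScan(
        data=np.concatenate(blocks, axis=1),
        subject_id=f"sub{subject_index:03d}",
        annotation=TaskAnnotation(tuple(intervals)),
        session_id=config.session,
    )


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[ParentScan], pd.DataFrame]:
    """All parent scans plus a per-task-scan label table with columns
    (scan_id, subject, task, interval_index, session)."""
    parents = [
        generate_parent_scan(config, s) for s in range(config.n_subjects)
    ]
    rows = []
    for parent in parents:
        for idx, (_, _, label) in enumerate(parent.annotation):
            rows.append(
                {
                    "scan_id": f"{parent.subject_id}:{label}",
                    "subject": parent.subject_id,
                    "task": label,
                    "interval_index": idx,
                    "session": parent.session_id,
                }
            )
    return parents, pd.DataFrame(rows)
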