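import numpy as np
import pytest

from whitemap import CohortConfig, ParentScan, TaskAnnotation


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_spd(rng, m, jitter=1e-3):
    """Random symmetric positive-definite matrix."""
    M = rng.standard_normal((m, m))
    A = M @ M.T + jitter * np.eye(m)
    return (A + A.T) / 2.0


def random_correlation(rng, m):
    """Random correlation matrix (unit diagonal, PSD)."""
    A = random_spd(rng, m)
    d = 1.0 / np.sqrt(np.diagonal(A))
    C = A * np.outer(d, d)
    C = (C + C.T) / 2.0
    np.fill_diagonal(C, 1.0)
    return C


def make_parent(rng, m=6, n=40, n_intervals=2, subject_id="subA"):
    """Small random parent scan with equal-width contiguous intervals."""
    width = n // n_intervals
    intervals = tuple(
        (i * width, (i + 1) * width, f"task{i}") for i in range(n_intervals)
    )
    return ParentScan(
        data=rng.standard_normal((m, n)),
        subject_id=subject_id,
        annotation=TaskAnnotation(intervals),
    )


@pytest.fixture
def tiny_cohort_config():
    """Four-subject cohort small enough for per-test pipeline runs."""
    return CohortConfig(
        n_subjects=4,
        n_tasks=4,
        m_regions=12,
        timepoints_per_task=40,
        seed=99,
    )
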