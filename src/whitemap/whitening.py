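"""Two-stage de-individualization of parent scans.

Stage 1 subtracts each region's temporal mean (removing per-subject,
per-region signal offsets); stage 2 applies Mahalanobis/ZCA whitening
against the covariance of the de-meaned parent, so the whitened rows have
identity covariance — erasing the subject-specific correlation structure.
Both stages operate on the whole parent scan before any task extraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from whitemap.io_core import ParentScan, TaskAnnotation, ValidationError

__all__ = [
    "WhitenedParentScan",
    "SingularCovarianceError",
    "demean_rows",
    "covariance_of_rows",
    "inverse_sqrt_psd",
    "whiten",
    "preprocess_parent",
]

#: eigenvalue floor, relative to the largest eigenvalue, used when forming
#: the symmetric inverse square root
EIGENVALUE_FLOOR = 1e-12

#: condition-number threshold beyond which whitening refuses to proceed
CONDITION_THRESHOLD = 1e12


class SingularCovarianceError(np.linalg.LinAlgError):
    """The (ridged) covariance is numerically singular."""


@dataclass(frozen=True)
class WhitenedParentScan:
    """A parent scan after de-meaning and whitening.

    When ``ridge_used == 0`` and the covariance was full rank, the sample
    covariance of the rows of ``data`` is the identity to tolerance.
    """

    data: np.ndarray
    subject_id: str
    annotation: TaskAnnotation
    session_id: str = "test"
    ridge_used: float = 0.0


def demean_rows(S: np.ndarray) -> np.ndarray:
    """Subtract each row's arithmetic mean; output rows have mean 0."""
    S = np.asarray(S, dtype=float)
    if S.size == 0:
        raise ValidationError("cannot de-mean an empty matrix")
    if S.ndim != 2:
        raise ValidationError("expected a 2-D matrix")
    return S - S.mean(axis=1, keepdims=True)


def covariance_of_rows(S_bar: np.ndarray) -> np.ndarray:
    """Sample covariance (1/(n-1) normalizer) of the rows of ``S_bar``.

    Equals ``S_bar @ S_bar.T / (n - 1)`` when the rows are mean-zero.
    """
    S_bar = np.asarray(S_bar, dtype=float)
    if S_bar.ndim != 2:
        raise ValidationError("expected a 2-D matrix")
    if S_bar.shape[1] < 2:
        raise ValidationError("need at least 2 time points for covariance")
    W = np.cov(S_bar, rowvar=True, ddof=1)
    return np.atleast_2d(W)


def inverse_sqrt_psd(
    W: np.ndarray,
    condition_threshold: float = CONDITION_THRESHOLD,
) -> np.ndarray:
    """Symmetric inverse square root of a PSD matrix via eigendecomposition.

    Eigenvalues below ``EIGENVALUE_FLOOR * lambda_max`` trigger a
    :class:`SingularCovarianceError` rather than silent regularization;
    likewise a condition number above ``condition_threshold``.
    """
    W = np.asarray(W, dtype=float)
    W = (W + W.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(W)
    lam_max = float(eigvals[-1])
    if lam_max <= 0:
        raise SingularCovarianceError(
            "covariance has no positive eigenvalues; whitening undefined"
        )
    floor = EIGENVALUE_FLOOR * lam_max
    lam_min = float(eigvals[0])
    if lam_min < floor or lam_max / max(lam_min, np.finfo(float).tiny) > condition_threshold:
        raise SingularCovarianceError(
            f"covariance condition number "
            f"{lam_max / max(lam_min, np.finfo(float).tiny):.3g} exceeds "
            f"{condition_threshold:.3g}; add a ridge or use more time points"
        )
    inv_sqrt = (eigvecs * (1.0 / np.sqrt(eigvals))) @ eigvecs.T
    return (inv_sqrt + inv_sqrt.T) / 2.0


def whiten(
    S_bar: np.ndarray,
    ridge: float = 0.0,
    condition_threshold: float = CONDITION_THRESHOLD,
) -> np.ndarray:
    """Whiten a mean-zero matrix: ``(W + ridge*I)^{-1/2} @ S_bar`` with
    ``W = cov(S_bar, S_bar)``.

    With ``ridge == 0`` and full-rank ``W``, the row covariance of the
    result equals the identity to ~1e-8 relative tolerance.
    """
    if ridge < 0:
        raise ValidationError("ridge must be >= 0")
    S_bar = np.asarray(S_bar, dtype=float)
    W = covariance_of_rows(S_bar)
    if ridge > 0:
        W = W + ridge * np.eye(W.shape[0])
    inv_sqrt = inverse_sqrt_psd(W, condition_threshold=condition_threshold)
    return inv_sqrt @ S_bar


def preprocess_parent(
    parent: ParentScan,
    ridge: float = 0.0,
    condition_threshold: float = CONDITION_THRESHOLD,
) -> WhitenedParentScan:
    """De-mean then whiten a full parent scan, carrying its annotation
    through so task scans are extracted from whitened data afterwards."""
    S_bar = demean_rows(parent.data)
    Sw = whiten(S_bar, ridge=ridge, condition_threshold=condition_threshold)
    return WhitenedParentScan(
        data=Sw,
        subject_id=parent.subject_id,
        annotation=parent.annotation,
        session_id=parent.session_id,
        ridge_used=float(ridge),
    )
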