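"""Robust Karhunen-Loeve (KLT) ST-segment basis functions.

Pattern vectors from annotated intervals are grouped into classes, each
class replaced by its mean, and a covariance matrix formed from the
centralized class means.  Eigenvectors of that covariance, in descending
eigenvalue order, are the KLT basis.  Replacing intervals by their means
before forming the covariance makes the estimate robust to the very
different beat counts and noise levels of individual intervals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import numpy.typing as npt

from stmorph.basis import BasisMatrix, STWindowSpec, lpt_basis

__all__ = [
    "IntervalClass",
    "RobustCovariance",
    "KLTModel",
    "DegenerateInputError",
    "reject_outliers",
    "build_classes",
    "robust_covariance",
    "derive_klt",
    "coefficient_stds",
    "train_klt",
]

logger = logging.getLogger(__name__)

INTERVAL_LABELS = ("ischaemic_deviation", "non_ischaemic_deviation", "no_deviation")


class DegenerateInputError(ValueError):
    """All patterns rejected, or otherwise unusable input."""


@dataclass
class IntervalClass:
    """Pattern vectors of one annotated interval, summarized by their mean (uV)."""

    label: str
    members: npt.NDArray[np.float64]  # (n_members, M)
    mean: npt.NDArray[np.float64] = field(init=False)

    def __post_init__(self) -> None:
        self.members = np.atleast_2d(np.asarray(self.members, dtype=float))
        if self.members.shape[0] == 0:
            raise ValueError("an interval class needs at least one member")
        self.mean = self.members.mean(axis=0)


@dataclass
class RobustCovariance:
    """Covariance of centralized interval-class means (uV^2)."""

    matrix: npt.NDArray[np.float64]
    grand_mean: npt.NDArray[np.float64]
    n_classes: int


@dataclass
class KLTModel:
    basis: BasisMatrix
    eigenvalues: npt.NDArray[np.float64]
    stds: npt.NDArray[np.float64] | None = None  # per-coefficient sigma, uV


def reject_outliers(
    patterns: npt.NDArray[np.float64],
    residual_threshold: float | None = None,
    robust_z_threshold: float = 4.0,
) -> npt.NDArray[np.float64]:
    """Drop patterns far from the per-sample median pattern.

    The distance of each pattern is its RMS deviation from the elementwise
    median vector; patterns whose distance exceeds ``robust_z_threshold``
    times the median of those distances are rejected.  ``residual_threshold``
    (uV) adds an optional absolute cap on the RMS deviation.  This is a
    deliberately simple, deterministic stand-in for full feature-space
    noise/outlier screening.
    """
    patterns = np.atleast_2d(np.asarray(patterns, dtype=float))
    if patterns.shape[0] == 0:
        raise DegenerateInputError("no patterns supplied")
    median_pattern = np.median(patterns, axis=0)
    rms = np.sqrt(np.mean((patterns - median_pattern) ** 2, axis=1))
    keep = rms <= robust_z_threshold * np.median(rms)
    if residual_threshold is not None:
        keep &= rms <= residual_threshold
    if not np.any(keep):
        raise DegenerateInputError("outlier rejection removed every pattern")
    return patterns[keep]


def build_classes(
    corpus: list[tuple[str, npt.NDArray[np.float64]]],
) -> list[IntervalClass]:
    """One class per annotated interval; empty intervals are skipped with a warning.

    ``corpus`` holds (label, patterns) pairs, one per interval, with leads
    already pooled (pattern vectors from every lead contribute alike).
    """
    classes: list[IntervalClass] = []
    for label, patterns in corpus:
        patterns = np.atleast_2d(np.asarray(patterns, dtype=float))
        if patterns.shape[0] == 0:
            logger.warning("skipping empty interval with label %r", label)
            continue
        classes.append(IntervalClass(label=label, members=patterns))
    return classes


def robust_covariance(classes: list[IntervalClass], divisor: str = "K") -> RobustCovariance:
    """Covariance of the class means about their grand mean.

    Every class contributes one observation (its mean) regardless of how
    many beats it holds.  ``divisor`` selects the population form ``K``
    (default) or the sample form ``K-1``.
    """
    if len(classes) < 2:
        raise ValueError("need at least 2 interval classes")
    means = np.stack([c.mean for c in classes])
    grand_mean = means.mean(axis=0)
    centered = means - grand_mean
    k = len(classes)
    denom = k if divisor == "K" else k - 1
    matrix = (centered.T @ centered) / denom
    return RobustCovariance(matrix=matrix, grand_mean=grand_mean, n_classes=k)


def derive_klt(
    cov: RobustCovariance,
    reference_basis: BasisMatrix | None = None,
    window: STWindowSpec | None = None,
) -> KLTModel:
    """Eigendecompose the robust covariance into an orthonormal KLT basis.

    Columns are ordered by descending eigenvalue (ties broken by original
    index).  Each eigenvector's sign is fixed so its inner product with the
    same-index column of ``reference_basis`` (the LPT basis by default) is
    >= 0 -- the leading KLT shapes resemble the low-order Legendre shapes,
    so this anchors an otherwise arbitrary convention.
    """
    matrix = np.asarray(cov.matrix, dtype=float)
    m = matrix.shape[0]
    sym_err = np.max(np.abs(matrix - matrix.T))
    scale = max(np.max(np.abs(matrix)), 1.0)
    if sym_err > 1e-8 * scale:
        raise ValueError(f"covariance not symmetric (max asymmetry {sym_err:.3g})")
    matrix = 0.5 * (matrix + matrix.T)

    eigvals, eigvecs = np.linalg.eigh(matrix)
    order = np.argsort(-eigvals, kind="stable")
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    eigvals = np.clip(eigvals, 0.0, None)

    if reference_basis is None:
        reference_basis = lpt_basis(m, window=window)
    for k in range(m):
        if np.dot(eigvecs[:, k], reference_basis.entries[:, k]) < 0:
            eigvecs[:, k] = -eigvecs[:, k]

    if window is None:
        window = reference_basis.window
    basis = BasisMatrix(entries=eigvecs, kind="KLT", window=window)
    return KLTModel(basis=basis, eigenvalues=eigvals)


def coefficient_stds(
    corpus: npt.NDArray[np.float64],
    basis: BasisMatrix,
    n_coeffs: int = 9,
    ddof: int = 1,
) -> npt.NDArray[np.float64]:
    """Per-coefficient sample standard deviations over a pattern-vector corpus.

    Projects every pattern onto the first ``n_coeffs`` basis columns and
    returns the standard deviation of each coefficient (sample estimator,
    ``ddof=1``).  Zero-variance coefficients are floored at 1e-12 with a
    warning so downstream normalization stays defined.
    """
    corpus = np.atleast_2d(np.asarray(corpus, dtype=float))
    if corpus.shape[0] < 2:
        raise ValueError("corpus must hold at least 2 pattern vectors")
    coeffs = corpus @ basis.entries[:, :n_coeffs]
    stds = coeffs.std(axis=0, ddof=ddof)
    if np.any(stds < 1e-12):
        warnings.warn(
            "zero-variance coefficient(s) floored at 1e-12 for normalization",
            stacklevel=2,
        )
        stds = np.maximum(stds, 1e-12)
    return stds


def train_klt(
    corpus: list[tuple[str, npt.NDArray[np.float64]]],
    *,
    robust_z_threshold: float = 4.0,
    n_coeffs: int = 9,
    window: STWindowSpec | None = None,
) -> KLTModel:
    """End-to-end KLT training: outlier rejection, class means, covariance, eigenbasis.

    Also fills ``stds`` with the coefficient standard deviations of the
    pooled (post-rejection) corpus under the derived basis.
    """
    cleaned: list[tuple[str, npt.NDArray[np.float64]]] = []
    for label, patterns in corpus:
        patterns = np.atleast_2d(np.asarray(patterns, dtype=float))
        if patterns.shape[0] == 0:
            logger.warning("skipping empty interval with label %r", label)
            continue
        try:
            kept = reject_outliers(patterns, robust_z_threshold=robust_z_threshold)
        except DegenerateInputError:
            logger.warning("interval with label %r fully rejected; skipping", label)
            continue
        cleaned.append((label, kept))
    classes = build_classes(cleaned)
    cov = robust_covariance(classes)
    model = derive_klt(cov, window=window)
    pooled = np.vstack([patterns for _, patterns in cleaned])
    model.stds = coefficient_stds(pooled, model.basis, n_coeffs=n_coeffs)
    return model
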