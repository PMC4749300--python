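"""Discrete orthonormal Legendre-polynomial (LPT) ST-segment basis functions.

The ST window of each heartbeat is represented by ``M`` equally spaced
samples.  Mapping the window onto ``[-1, 1]`` and orthonormalizing the
monomials 1, x, x^2, ... under the discrete (weighted) inner product yields
a basis whose first three functions are a constant, a linear ramp and a
quadratic bowl -- exactly the shapes of ST level shift, ST slope change and
ST scooping.  Projections onto this basis therefore read those morphology
categories off directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import numpy.typing as npt

__all__ = [
    "STWindowSpec",
    "BasisMatrix",
    "NumericalDegeneracyError",
    "legendre_polynomial",
    "build_monomial_matrix",
    "gram_schmidt_orthonormalize",
    "orthonormality_error",
    "lpt_basis",
]


class NumericalDegeneracyError(RuntimeError):
    """Raised when orthogonalization encounters a numerically rank-deficient set."""


@dataclass(frozen=True)
class STWindowSpec:
    """Location of the ST analysis window relative to the fiducial point F.

    Defaults: 32 samples spanning F+40 ms .. F+160 ms (a 120 ms window).
    """

    start_offset_ms: float = 40.0
    end_offset_ms: float = 160.0
    n_samples: int = 32

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.end_offset_ms <= self.start_offset_ms:
            raise ValueError("end_offset_ms must exceed start_offset_ms")

    @property
    def duration_ms(self) -> float:
        return self.end_offset_ms - self.start_offset_ms

    def offsets_ms(self) -> npt.NDArray[np.float64]:
        """Sample offsets from F in ms, endpoint inclusive."""
        return np.linspace(self.start_offset_ms, self.end_offset_ms, self.n_samples)

    def to_dict(self) -> dict:
        return {
            "start_offset_ms": self.start_offset_ms,
            "end_offset_ms": self.end_offset_ms,
            "n_samples": self.n_samples,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "STWindowSpec":
        return cls(
            start_offset_ms=float(d["start_offset_ms"]),
            end_offset_ms=float(d["end_offset_ms"]),
            n_samples=int(d["n_samples"]),
        )


@dataclass
class BasisMatrix:
    """An M x M orthonormal transformation matrix over an ST window.

    Columns are basis functions; ``entries[:, k]`` sampled at the window's
    abscissae.  Orthonormality holds under the weighted inner product
    ``sum_k w_k u_k v_k``.
    """

    entries: npt.NDArray[np.float64]
    kind: str  # "LPT" | "KLT"
    window: STWindowSpec = field(default_factory=STWindowSpec)
    weights: npt.NDArray[np.float64] | None = None

    def __post_init__(self) -> None:
        self.entries = np.asarray(self.entries, dtype=float)
        if self.entries.ndim != 2 or self.entries.shape[0] != self.entries.shape[1]:
            raise ValueError("basis entries must be a square matrix")
        if self.weights is None:
            self.weights = np.ones(self.entries.shape[0])
        else:
            self.weights = np.asarray(self.weights, dtype=float)
            if np.any(self.weights <= 0):
                raise ValueError("weights must be positive")

    @property
    def M(self) -> int:
        return self.entries.shape[0]


def legendre_polynomial(n: int, x):
    """Evaluate the Legendre polynomial P_n(x) by the three-term recurrence.

    ``(j+1) P_{j+1} = (2j+1) x P_j - j P_{j-1}`` seeded with P_0 = 1,
    P_1 = x.  Values of ``x`` outside [-1, 1] are permitted (the recurrence
    is valid everywhere) but orthogonality only holds on [-1, 1].

    Parameters
    ----------
    n : int
        Polynomial degree, >= 0.
    x : float or array-like
        Evaluation point(s).
    """
    if n < 0 or int(n) != n:
        raise ValueError(f"degree must be a non-negative integer, got {n!r}")
    n = int(n)
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    p_prev = np.ones_like(x)
    if n == 0:
        return float(p_prev) if scalar else p_prev
    p_cur = x.copy()
    for j in range(1, n):
        p_next = ((2 * j + 1) * x * p_cur - j * p_prev) / (j + 1)
        p_prev, p_cur = p_cur, p_next
    return float(p_cur) if scalar else p_cur


def monomial_abscissae(M: int) -> npt.NDArray[np.float64]:
    """M equally spaced points on [-1, 1], endpoints included."""
    if M < 2:
        raise ValueError("M must be >= 2")
    i = np.arange(1, M + 1, dtype=float)
    return 2.0 * (i - 1.0) / (M - 1.0) - 1.0


def build_monomial_matrix(M: int) -> npt.NDArray[np.float64]:
    """Monomials x^(j-1) sampled on the M-point grid over [-1, 1].

    Entry (i, j) is ``x_i ** (j-1)`` with ``x_i = 2(i-1)/(M-1) - 1``; the
    first column is all ones.
    """
    x = monomial_abscissae(M)
    return x[:, None] ** np.arange(M)[None, :]


def gram_schmidt_orthonormalize(
    m: npt.NDArray[np.float64],
    weights: npt.NDArray[np.float64] | None = None,
    *,
    kind: str = "LPT",
    window: STWindowSpec | None = None,
) -> BasisMatrix:
    """Weighted modified Gram-Schmidt orthonormalization of the columns of ``m``.

    Columns are processed left to right, each orthogonalized against the
    already-orthonormal ones (modified, not classical, GS -- the monomial
    matrix is badly conditioned and classical GS loses orthogonality much
    faster).  Each column is normalized to unit weighted norm and its sign
    fixed so that the value at the last abscissa (x = +1) is >= 0, matching
    P_n(1) = 1.
    """
    m = np.asarray(m, dtype=float)
    n_rows, n_cols = m.shape
    w = np.ones(n_rows) if weights is None else np.asarray(weights, dtype=float)
    if w.shape != (n_rows,) or np.any(w <= 0):
        raise ValueError("weights must be positive with one entry per row")

    psi = m.copy()
    for j in range(n_cols):
        v = psi[:, j]
        for k in range(j):
            v = v - np.dot(w * psi[:, k], v) * psi[:, k]
        # one re-orthogonalization pass; "twice is enough" for MGS drift
        for k in range(j):
            v = v - np.dot(w * psi[:, k], v) * psi[:, k]
        norm = np.sqrt(np.dot(w, v * v))
        if norm < 1e-300:
            raise NumericalDegeneracyError(
                f"column {j} numerically dependent on previous columns"
            )
        v = v / norm
        if v[-1] < 0:
            v = -v
        psi[:, j] = v

    if window is None:
        window = STWindowSpec(n_samples=n_rows)
    return BasisMatrix(entries=psi, kind=kind, window=window, weights=w)


def orthonormality_error(b: BasisMatrix, first_k: int) -> tuple[float, float]:
    """Deviation of the weighted Gram matrix of the first ``first_k`` columns from I.

    Returns ``(max |G_kk - 1|, max |G_kl| for k != l)``.
    """
    if first_k > b.M:
        raise ValueError("first_k exceeds the basis dimension")
    cols = b.entries[:, :first_k]
    gram = cols.T @ (b.weights[:, None] * cols)
    diag_err = float(np.max(np.abs(np.diag(gram) - 1.0)))
    off = gram - np.diag(np.diag(gram))
    offdiag_err = float(np.max(np.abs(off))) if first_k > 1 else 0.0
    return diag_err, offdiag_err


def lpt_basis(
    M: int = 32,
    weights: npt.NDArray[np.float64] | None = None,
    window: STWindowSpec | None = None,
) -> BasisMatrix:
    """The discrete orthonormal Legendre (LPT) basis of size M x M."""
    if window is None:
        window = STWindowSpec(n_samples=M)
    omega = build_monomial_matrix(M)
    return gram_schmidt_orthonormalize(omega, weights, kind="LPT", window=window)
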