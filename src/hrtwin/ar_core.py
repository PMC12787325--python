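"""Autoregressive core: lag designs, minimum-norm least squares, one-step prediction.

The model is the classical AR(m) with intercept on a minute-indexed heart-rate
series h_1..h_N (beats per minute, 1-based index):

    h*_{k+1} = a_0 + sum_{i=1..m} a_i * h_{k+1-i}

where a_1 multiplies the most recent observation h_k.  Parameters are
estimated by least squares over every in-window one-step relation
(targets h_{m+1}..h_k); when the lag design is rank deficient — constant
heart-rate stretches make this a real occurrence, not a corner case — the
minimum Euclidean-norm minimizer is returned.

Everything here is pure, deterministic computation; the rolling protocol
lives in :mod:`hrtwin.rolling`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .exceptions import (
    InsufficientHistoryError,
    NonFiniteDesignError,
    WindowTooShortError,
)

__all__ = [
    "HeartRateSeries",
    "ARParameterVector",
    "LagDesign",
    "build_lag_design",
    "solve_min_norm",
    "predict_next",
]

#: Relative tolerance for rank determination in the minimum-norm solver:
#: singular values below RANK_RTOL * s_max are treated as zero.
RANK_RTOL = 1e-10


@dataclass(frozen=True)
class HeartRateSeries:
    """A participant's ordered minute-level heart-rate sequence.

    Parameters
    ----------
    participant_id:
        Opaque label for the person the series belongs to.
    values:
        Heart rate in beats per minute, one value per minute, 1-based
        conceptual index k = 1..N.  Stored as a read-only float64 array.
        All values must be finite and strictly positive.
    """

    participant_id: str
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=np.float64)
        if arr.ndim != 1 or arr.size < 1:
            raise ValueError("heart-rate series must be a non-empty 1-d sequence")
        if not np.all(np.isfinite(arr)):
            raise ValueError(
                f"participant {self.participant_id!r}: non-finite heart-rate value"
            )
        if np.any(arr <= 0):
            raise ValueError(
                f"participant {self.participant_id!r}: heart rate must be > 0 bpm"
            )
        arr = arr.copy()
        arr.flags.writeable = False
        object.__setattr__(self, "values", arr)

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass(frozen=True)
class ARParameterVector:
    """Intercept a_0 (bpm) plus lag coefficients a_1..a_m (dimensionless).

    ``coefficients[0]`` is a_1, the weight of the most recent observation.
    """

    intercept: float
    coefficients: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        coef = np.asarray(self.coefficients, dtype=np.float64)
        if coef.ndim != 1 or coef.size < 1:
            raise ValueError("need at least one lag coefficient (m >= 1)")
        if not (np.isfinite(self.intercept) and np.all(np.isfinite(coef))):
            raise ValueError("parameter vector entries must all be finite")
        coef = coef.copy()
        coef.flags.writeable = False
        object.__setattr__(self, "coefficients", coef)

    @property
    def order(self) -> int:
        """The model order m."""
        return int(self.coefficients.size)

    def as_array(self) -> np.ndarray:
        """Return (a_0, a_1, ..., a_m) as a fresh array of length m+1."""
        return np.concatenate(([self.intercept], self.coefficients))

    def padded(self, m_max: int) -> np.ndarray:
        """Return (a_0, ..., a_{m_max}) with exact zeros beyond a_m.

        This is the fixed-width summary-row convention: unused higher-lag
        coefficients are reported as literal 0.
        """
        if m_max < self.order:
            raise ValueError(f"m_max={m_max} smaller than model order {self.order}")
        out = np.zeros(m_max + 1)
        out[: self.order + 1] = self.as_array()
        return out


@dataclass(frozen=True)
class LagDesign:
    """Predictor matrix and target vector for one fit window.

    Row j (0-based) holds (1, h_{i-1}, ..., h_{i-m}) for target index
    i = m+1+j, so applying the model to row j reproduces the fitted value
    for target ``y[j]`` = h_{m+1+j}.
    """

    X: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    order: int
    window_end: int  # the (1-based) index k of the last observation used

    @property
    def n_rows(self) -> int:
        return int(self.X.shape[0])


def build_lag_design(series: HeartRateSeries, m: int, k: int) -> LagDesign:
    """Lay out the one-step lag regression for the window h_1..h_k.

    Produces k - m rows and m + 1 columns (leading column of ones); the
    window end must satisfy the reliability constraint k >= 2m+1, which
    guarantees at least m+1 relations per parameter-bearing column.

    Raises
    ------
    WindowTooShortError
        If k < 2m+1.
    IndexError
        If k exceeds the series length.
    """
    if m < 1:
        raise ValueError(f"model order must be >= 1, got {m}")
    n = len(series)
    if k > n:
        raise IndexError(f"window end k={k} beyond series length N={n}")
    if k < 2 * m + 1:
        raise WindowTooShortError(
            f"window end k={k} violates k >= 2m+1 = {2 * m + 1} for order m={m}"
        )
    h = series.values
    n_rows = k - m
    X = np.empty((n_rows, m + 1))
    X[:, 0] = 1.0
    # column 1+i holds lag i+1: h_{t-1-i} for targets t = m+1..k (1-based)
    for lag in range(1, m + 1):
        X[:, lag] = h[m - lag : k - lag]
    y = h[m:k].copy()
    return LagDesign(X=X, y=y, order=m, window_end=k)


def solve_min_norm(design: LagDesign) -> ARParameterVector:
    """Least-squares fit; the minimum-norm minimizer when rank deficient.

    Solves ``argmin_a ||X a - y||_2`` and, among all minimizers, returns the
    one of smallest Euclidean norm, via an SVD-based solver with singular
    values below ``RANK_RTOL * s_max`` treated as zero.
    """
    X, y = design.X, design.y
    if X.shape[0] < 1:
        raise ValueError("design must have at least one row")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise NonFiniteDesignError("lag design contains non-finite entries")
    sol, _, _, _ = scipy.linalg.lstsq(X, y, cond=RANK_RTOL, lapack_driver="gelsd")
    return ARParameterVector(intercept=float(sol[0]), coefficients=sol[1:])


def predict_next(params: ARParameterVector, recent) -> float:
    """One-step-ahead prediction h*_{k+1} from the last m observations.

    ``recent`` is ordered oldest-to-newest; only its last ``params.order``
    values are used, with a_1 multiplying the newest one.  The prediction is
    real-valued — never rounded to integer bpm.
    """
    recent = np.asarray(recent, dtype=np.float64)
    m = params.order
    if recent.ndim != 1 or recent.size < m:
        raise InsufficientHistoryError(
            f"need at least m={m} recent values, got {recent.size}"
        )
    window = recent[-m:]
    # a_1 pairs with h_k (newest), a_m with h_{k+1-m}
    return float(params.intercept + params.coefficients @ window[::-1])
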