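"""Centered multivariate multiple regression (MVMR) and unconstrained CCA.

A group of K neighboring voxel time courses ``Y`` (n x K) is regressed on a
shared temporal design ``X`` (n x p) through a single spatial weight vector:
``Y @ alpha ~ X @ beta``.  Minimizing ``||Y alpha - X beta||^2`` over both
vectors (up to scale) is equivalent to canonical correlation analysis: the
optimal ``alpha`` is the leading eigenvector of
``S_yy^{-1} S_yx S_xx^{-1} S_xy`` with eigenvalue ``lambda_m = r^2`` where
``r`` is the maximal canonical correlation between the voxel set and the
design.  ``beta`` then follows by ordinary least squares on ``Y alpha``.

The eigenproblem is solved in symmetric whitened form (SVD of
``S_yy^{-1/2} S_yx S_xx^{-1/2}``) for numerical stability.  Near-singular
voxel covariances (e.g. duplicated series) are repaired by a small ridge and
a warning rather than an exception, so degenerate synthetic inputs do not
crash batch runs.

Conventions
-----------
* all data are column centered; designs contain no constant column,
* the eigenvector sign is chosen so ``sum(alpha) >= 0``,
* ``alpha`` is rescaled to unit sum of magnitudes and ``beta`` is recomputed
  afterwards, so the least-squares relation holds for the scaled pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
import scipy.linalg

from .errors import (
    DegenerateNeighborhoodError,
    InvalidInputError,
    NumericalFailureError,
    SingularDesignError,
)

if TYPE_CHECKING:  # pragma: no cover
    from .search import NeighborhoodConfig

#: relative tolerance on column means for the "centered" invariant
_CENTER_TOL = 1e-8
#: condition number above which a voxel covariance is ridge-repaired
_RIDGE_CONDITION = 1e12
#: tolerance on the canonical eigenvalue exceeding its theoretical bound 1
_LAMBDA_TOL = 1e-6


def center_columns(M: np.ndarray) -> np.ndarray:
    """Subtract the mean from each column of ``M``.

    Idempotent; removes constant columns entirely.  Raises
    :class:`InvalidInputError` for inputs with fewer than 2 rows, where a
    column mean leaves nothing behind.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim == 1:
        M = M[:, None]
    if M.shape[0] < 2:
        raise InvalidInputError(
            f"centering needs at least 2 rows, got {M.shape[0]}"
        )
    return M - M.mean(axis=0, keepdims=True)


def _check_centered(M: np.ndarray, what: str) -> None:
    scale = np.abs(M).max(initial=0.0) + 1.0
    if np.abs(M.mean(axis=0)).max(initial=0.0) > _CENTER_TOL * scale:
        raise InvalidInputError(f"columns of {what} are not centered")


@dataclass(frozen=True)
class DesignMatrix:
    """Temporal model: n time points x p column-centered, nonconstant regressors.

    Derived quantities used throughout the package (Gram matrix, its inverse
    and the inverse symmetric square root of ``S_xx``) are computed once at
    construction.
    """

    X: np.ndarray
    regressor_names: tuple[str, ...]

    def __post_init__(self) -> None:
        X = np.atleast_2d(np.asarray(self.X, dtype=float))
        object.__setattr__(self, "X", X)
        names = tuple(self.regressor_names)
        object.__setattr__(self, "regressor_names", names)
        n, p = X.shape
        if len(names) != p:
            raise InvalidInputError(
                f"{len(names)} regressor names for {p} columns"
            )
        if n <= p:
            raise InvalidInputError(f"need n > p, got n={n}, p={p}")
        _check_centered(X, "X")
        norms = np.linalg.norm(X, axis=0)
        if np.any(norms == 0.0):
            bad = [names[i] for i in np.flatnonzero(norms == 0.0)]
            raise SingularDesignError(
                f"constant (zero after centering) regressors: {bad}"
            )
        # rank check; name offending columns via pivoted QR
        s = np.linalg.svd(X, compute_uv=False)
        if s[-1] <= 1e-10 * s[0]:
            _, R, piv = scipy.linalg.qr(X, pivoting=True, mode="economic")
            rdiag = np.abs(np.diag(R))
            bad = [names[piv[i]] for i in np.flatnonzero(rdiag <= 1e-10 * rdiag[0])]
            raise SingularDesignError(
                f"design matrix is rank deficient; offending columns: {bad}"
            )
        XtX = X.T @ X
        XtX_inv = np.linalg.inv(XtX)
        # inverse symmetric square root of S_xx = XtX / (n - 1)
        w, V = np.linalg.eigh(XtX / (n - 1))
        Wx = (V * (1.0 / np.sqrt(w))) @ V.T
        object.__setattr__(self, "_XtX", XtX)
        object.__setattr__(self, "_XtX_inv", XtX_inv)
        object.__setattr__(self, "_Wx", Wx)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def XtX(self) -> np.ndarray:
        return self._XtX

    @property
    def XtX_inv(self) -> np.ndarray:
        return self._XtX_inv

    @property
    def Sxx_inv_sqrt(self) -> np.ndarray:
        """Inverse symmetric square root of the design sample covariance."""
        return self._Wx


@dataclass(frozen=True)
class NeighborhoodTimeSeries:
    """Column-centered series of K voxels in one local neighborhood."""

    Y: np.ndarray
    voxel_ids: tuple
    center_index: int

    def __post_init__(self) -> None:
        Y = np.atleast_2d(np.asarray(self.Y, dtype=float))
        if Y.shape[0] == 1 and len(self.voxel_ids) == 1:
            Y = Y.T
        object.__setattr__(self, "Y", Y)
        K = Y.shape[1]
        if not (1 <= K <= 9):
            raise InvalidInputError(f"K must be in [1, 9], got {K}")
        if len(self.voxel_ids) != K:
            raise InvalidInputError("voxel_ids length does not match K")
        if not (0 <= self.center_index < K):
            raise InvalidInputError("center voxel must be among the K columns")
        _check_centered(Y, "Y")

    @classmethod
    def from_raw(cls, Y, voxel_ids, center_index) -> "NeighborhoodTimeSeries":
        """Center raw series and wrap them."""
        return cls(center_columns(Y), tuple(voxel_ids), center_index)

    @property
    def K(self) -> int:
        return self.Y.shape[1]


@dataclass(frozen=True)
class SampleCovariances:
    """Sample covariances with the 1/(n-1) normalization; ``S_xy`` is p x K."""

    S_yy: np.ndarray
    S_xx: np.ndarray
    S_xy: np.ndarray

    @classmethod
    def from_data(cls, X: np.ndarray, Y: np.ndarray) -> "SampleCovariances":
        n = X.shape[0]
        return cls(
            S_yy=Y.T @ Y / (n - 1),
            S_xx=X.T @ X / (n - 1),
            S_xy=X.T @ Y / (n - 1),
        )


@dataclass
class CCASolution:
    """One converged local CCA fit.

    ``alpha`` has unit sum of magnitudes; ``beta`` is the least-squares fit
    of ``Y @ alpha`` on the design; ``rss`` is the residual sum of squares
    ``||Y alpha - X beta||^2`` on that scale.
    """

    alpha: np.ndarray
    beta: np.ndarray
    r: float
    center_index: int
    config: "NeighborhoodConfig | None" = None
    rss: float = field(default=np.nan)

    @property
    def lambda_m(self) -> float:
        return self.r**2

    @property
    def K(self) -> int:
        return self.alpha.shape[0]


def glm_fit(X: DesignMatrix, v: np.ndarray) -> np.ndarray:
    """Least-squares coefficients ``(X'X)^{-1} X' v``.

    ``v`` may be a single n-vector or an n x m matrix (columns fitted
    independently).  The residual is orthogonal to the design columns.
    """
    v = np.asarray(v, dtype=float)
    if v.shape[0] != X.n:
        raise InvalidInputError(
            f"response length {v.shape[0]} does not match design n={X.n}"
        )
    return X.XtX_inv @ (X.X.T @ v)


def alpha_to_beta(X: DesignMatrix, Y: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Temporal coefficients implied by spatial weights: ``(X'X)^{-1} X' Y alpha``."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    return glm_fit(X, Y @ np.asarray(alpha, dtype=float))


def beta_to_alpha(X: DesignMatrix, Y: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Spatial weights implied by temporal coefficients: ``(Y'Y)^{-1} Y' X beta``."""
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    G = Y.T @ Y
    rhs = Y.T @ (X.X @ np.asarray(beta, dtype=float))
    try:
        return scipy.linalg.solve(G, rhs, assume_a="pos")
    except (scipy.linalg.LinAlgError, np.linalg.LinAlgError) as exc:
        raise DegenerateNeighborhoodError(
            "voxel Gram matrix is singular"
        ) from exc


def _inv_sqrt_psd(S: np.ndarray, what: str) -> np.ndarray:
    """Inverse symmetric square root with ridge repair for near-singular S."""
    S = np.atleast_2d(S)
    K = S.shape[0]
    w, V = np.linalg.eigh(S)
    if w[-1] <= 0.0:
        raise DegenerateNeighborhoodError(f"{what} is not positive definite")
    if w[0] <= 0.0 or w[-1] / max(w[0], np.finfo(float).tiny) > _RIDGE_CONDITION:
        eps = 1e-10 * np.trace(S) / K
        warnings.warn(
            f"{what} is near singular (condition > {_RIDGE_CONDITION:.0e}); "
            f"adding ridge {eps:.3e}",
            RuntimeWarning,
            stacklevel=3,
        )
        w, V = np.linalg.eigh(S + eps * np.eye(K))
        if w[0] <= 0.0:
            raise DegenerateNeighborhoodError(f"{what} is singular beyond repair")
    return (V * (1.0 / np.sqrt(w))) @ V.T


def _leading_whitened_alpha(
    S_yy: np.ndarray, S_xy: np.ndarray, Wx: np.ndarray
) -> tuple[np.ndarray, float]:
    """Leading canonical pair from the whitened cross-covariance SVD.

    Returns the (unnormalized) spatial eigenvector and the maximal canonical
    correlation r.  Raises :class:`NumericalFailureError` if the squared
    singular value exceeds 1 beyond tolerance.
    """
    Wy = _inv_sqrt_psd(S_yy, "S_yy")
    A = Wy @ S_xy.T @ Wx  # K x p whitened cross-covariance
    U, s, _ = np.linalg.svd(A)
    lam = s[0] ** 2
    if lam > 1.0 + _LAMBDA_TOL:
        raise NumericalFailureError(
            f"canonical eigenvalue {lam:.6g} exceeds its bound 1"
        )
    r = float(np.sqrt(min(lam, 1.0)))
    return Wy @ U[:, 0], r


def normalize_alpha(alpha: np.ndarray) -> np.ndarray:
    """Apply the sign convention (``sum(alpha) >= 0``) and unit-magnitude-sum scale."""
    alpha = np.asarray(alpha, dtype=float).copy()
    s = alpha.sum()
    if s < 0.0 or (s == 0.0 and alpha[np.argmax(np.abs(alpha))] < 0.0):
        alpha = -alpha
    total = np.abs(alpha).sum()
    if total == 0.0:
        raise NumericalFailureError("zero spatial weight vector")
    return alpha / total


def max_canonical_correlation(
    X: DesignMatrix, Y: NeighborhoodTimeSeries | np.ndarray
) -> CCASolution:
    """Unconstrained local CCA between a voxel neighborhood and the design.

    For ``K = 1`` the result reduces to the multiple correlation of that
    voxel with the design (``r = sqrt(R^2)`` of the ordinary regression).
    """
    if isinstance(Y, NeighborhoodTimeSeries):
        nbh = Y
    else:
        Ymat = np.atleast_2d(np.asarray(Y, dtype=float))
        if Ymat.shape[0] == 1:
            Ymat = Ymat.T
        nbh = NeighborhoodTimeSeries(Ymat, tuple(range(Ymat.shape[1])), 0)
    Ymat = nbh.Y
    K = nbh.K
    if X.n <= X.p + K:
        raise InvalidInputError(
            f"need n > p + K, got n={X.n}, p={X.p}, K={K}"
        )
    cov = SampleCovariances.from_data(X.X, Ymat)
    alpha, r = _leading_whitened_alpha(cov.S_yy, cov.S_xy, X.Sxx_inv_sqrt)
    alpha = normalize_alpha(alpha)
    beta = alpha_to_beta(X, Ymat, alpha)
    ya = Ymat @ alpha
    resid = ya - X.X @ beta
    return CCASolution(
        alpha=alpha,
        beta=beta,
        r=r,
        center_index=nbh.center_index,
        rss=float(resid @ resid),
    )
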