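"""Directional contrast statistics for local CCA and the classical GLM t.

Given a fitted local CCA pair (alpha, beta) and a contrast vector c over the
design regressors, the null hypothesis ``c' B alpha = c' beta = 0`` is tested
with a scalarized Wilks' Lambda,

    Lambda = E / (E + H),
    E = (Y alpha - X beta)' (Y alpha - X beta),
    H = (c' beta)^2 / (c' (X'X)^{-1} c),

signed by ``sign(c' beta)`` to obtain a directional statistic.  An
equivalent t-like form is

    t_c = c' beta * sqrt(DF) / sqrt(c' (X'X)^{-1} c * E),   DF = n - p - K,

where the degrees of freedom charge the size K of the spatial configuration,
so the same effect estimated with fewer voxels is more significant.  For
K = 1 (alpha = 1) this is exactly the classical GLM contrast t with
DF = n - p - 1.  The two forms are linked by the monotone bijection
``Lambda = 1 / (1 + t_c^2 / DF)`` at fixed DF, and t_c is invariant to the
overall scale of alpha (with beta rescaled accordingly).

t_c is *not* t-distributed under realistic nulls -- the adaptive spatial
kernel and the temporal/spatial correlation of fMRI noise both widen its
null distribution -- so significance is always assessed nonparametrically
(see :mod:`localcca.fwe`); no t CDF is applied here.

An unsigned F-type statistic ``F = ((1 - Lambda)/Lambda) * (nu_E / nu_H)``
is provided for multi-regressor effects where a direction is not meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cca import CCASolution, DesignMatrix, center_columns, glm_fit
from .errors import InvalidInputError, PerfectFitError


@dataclass(frozen=True)
class Contrast:
    """A nonzero weight vector over the design regressors."""

    c: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.c, dtype=float).ravel()
        if c.size == 0 or not np.any(c):
            raise InvalidInputError("contrast vector must be nonzero")
        object.__setattr__(self, "c", c)

    @classmethod
    def from_names(
        cls, weights: dict[str, float], design: DesignMatrix, name: str = ""
    ) -> "Contrast":
        """Build from named weights, e.g. ``{"E": 1, "C": -1}``."""
        unknown = set(weights) - set(design.regressor_names)
        if unknown:
            raise InvalidInputError(f"unknown regressors in contrast: {sorted(unknown)}")
        c = np.array([weights.get(n, 0.0) for n in design.regressor_names])
        return cls(c, name or "+".join(f"{w:+g}*{n}" for n, w in weights.items()))


@dataclass
class ContrastStatMap:
    """Per-voxel directional statistic with its bookkeeping maps.

    ``t`` holds the statistic (NaN outside the mask), ``df`` the per-voxel
    degrees of freedom n - p - K, ``K`` the configuration sizes, and
    ``lambda_signed`` the signed Wilks value in [-1, 1].
    """

    t: np.ndarray
    df: np.ndarray
    K: np.ndarray
    lambda_signed: np.ndarray
    mask: np.ndarray
    contrast: Contrast

    def values(self) -> np.ndarray:
        """Statistic values at in-mask voxels, flattened."""
        return self.t[self.mask]


def _contrast_variance_factor(X: DesignMatrix, c: np.ndarray) -> float:
    return float(c @ X.XtX_inv @ c)


def wilks_lambda(E_scalar: float, H_scalar: float) -> float:
    """Scalar Wilks' Lambda ``E / (E + H)``; equals 1 iff H = 0."""
    if E_scalar < 0.0 or H_scalar < 0.0:
        raise InvalidInputError("E and H must be nonnegative")
    if E_scalar == 0.0:
        raise PerfectFitError("zero residual: Lambda is degenerate")
    return E_scalar / (E_scalar + H_scalar)


def error_and_hypothesis(
    X: DesignMatrix, Y: np.ndarray, alpha: np.ndarray, c: Contrast | np.ndarray
) -> tuple[float, float, float]:
    """Scalar (E, H, c'beta) for a weight vector alpha on neighborhood Y."""
    cvec = c.c if isinstance(c, Contrast) else np.asarray(c, dtype=float)
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] == 1:
        Y = Y.T
    ya = Y @ np.asarray(alpha, dtype=float)
    beta = glm_fit(X, ya)
    resid = ya - X.X @ beta
    E = float(resid @ resid)
    cb = float(cvec @ beta)
    H = cb**2 / _contrast_variance_factor(X, cvec)
    return E, H, cb


def directional_lambda(
    sol: CCASolution, X: DesignMatrix, Y: np.ndarray, c: Contrast | np.ndarray
) -> float:
    """Signed Wilks statistic ``sign(c'beta) * Lambda``; 0 when c'beta = 0."""
    E, H, cb = error_and_hypothesis(X, Y, sol.alpha, c)
    if cb == 0.0:
        return 0.0
    return float(np.sign(cb)) * wilks_lambda(E, H)


def t_from_components(
    cb: float, c_var: float, rss: float, df: int
) -> float:
    """Directional statistic from precomputed pieces (used by map builders)."""
    if df <= 0:
        raise InvalidInputError(f"degrees of freedom must be positive, got {df}")
    if rss <= 0.0:
        raise PerfectFitError("zero residual: statistic is unbounded")
    return cb * np.sqrt(df) / np.sqrt(c_var * rss)


def t_c_statistic(
    sol: CCASolution,
    X: DesignMatrix,
    Y: np.ndarray,
    c: Contrast | np.ndarray,
) -> tuple[float, int]:
    """Directional t-like statistic and its DF = n - p - K for a CCA solution.

    Invariant to rescaling alpha (beta is recomputed from the given alpha),
    and identical to :func:`classical_t` when K = 1.
    """
    cvec = c.c if isinstance(c, Contrast) else np.asarray(c, dtype=float)
    E, _, cb = error_and_hypothesis(X, Y, sol.alpha, cvec)
    Ymat = np.atleast_2d(np.asarray(Y, dtype=float))
    if Ymat.shape[0] == 1:
        Ymat = Ymat.T
    ya = Ymat @ sol.alpha
    if E <= 1e-12 * float(ya @ ya):
        raise PerfectFitError("residual is zero to machine precision")
    K = sol.K
    df = X.n - X.p - K
    t = t_from_components(cb, _contrast_variance_factor(X, cvec), E, df)
    return float(t), df


def classical_t(
    X: DesignMatrix, y: np.ndarray, c: Contrast | np.ndarray
) -> tuple[float, int]:
    """Classical GLM contrast t on one centered voxel series, DF = n - p - 1."""
    cvec = c.c if isinstance(c, Contrast) else np.asarray(c, dtype=float)
    y = center_columns(np.asarray(y, dtype=float).ravel())[:, 0]
    beta = glm_fit(X, y)
    resid = y - X.X @ beta
    rss = float(resid @ resid)
    if rss <= 1e-12 * float(y @ y):
        raise PerfectFitError("residual is zero to machine precision")
    df = X.n - X.p - 1
    t = t_from_components(float(cvec @ beta), _contrast_variance_factor(X, cvec), rss, df)
    return float(t), df


def lambda_from_t(t: float | np.ndarray, df: int | np.ndarray) -> np.ndarray:
    """Signed Wilks value from the t-like statistic: ``sign(t)/(1 + t^2/DF)``."""
    t = np.asarray(t, dtype=float)
    return np.sign(t) / (1.0 + t**2 / np.asarray(df, dtype=float))


def f_statistic(lam: float, nu_H: float, nu_E: float) -> float:
    """F-type statistic from Wilks' Lambda: ``((1 - L)/L) * (nu_E / nu_H)``."""
    if not (0.0 < lam <= 1.0):
        raise InvalidInputError("Lambda must lie in (0, 1]")
    if nu_H < 1 or nu_E < 1:
        raise InvalidInputError("degrees of freedom must be >= 1")
    return (1.0 - lam) / lam * (nu_E / nu_H)
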