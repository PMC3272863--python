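"""Constrained-CCA configuration search in a local voxel neighborhood.

For each in-mask voxel, the best subset ("configuration") of its 3x3
neighborhood is sought: the unconstrained CCA solution of each candidate
subset is computed, solutions violating the spatial constraints are
discarded, and the feasible solution with maximal canonical correlation r
wins.  The constraints make the adaptive kernel behave like a smoothing
filter:

* all spatial weights share one sign (nonnegative under the package's sign
  convention),
* the center voxel's weight is at least ``center_min_fraction`` (default
  20%) of the maximum weight.

Two search strategies are provided.  :func:`exhaustive_ccca` enumerates all
``2^(N-1)`` center-containing subsets (256 for a full 3x3 window) and is the
reference.  :func:`region_growing_ccca` grows the configuration greedily
from the center, adding at each step the neighbor that yields the largest
feasible r, and stops when the gain drops below a tolerance; it is much
faster and agrees with the exhaustive search on the vast majority of
neighborhoods.  The single-voxel configuration is always feasible, so both
searches fall back to it when nothing else satisfies the constraints.

Searches operate on 2D slices: ``slice_data`` is an ``(ny, nx, n)`` array,
a voxel is an ``(iy, ix)`` index pair, and neighborhoods are clipped at the
image boundary and at an optional binary mask.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import prod
from typing import Sequence

import numpy as np

from .cca import (
    CCASolution,
    DesignMatrix,
    _leading_whitened_alpha,
    center_columns,
    normalize_alpha,
)
from .errors import InvalidInputError

#: improvement tolerance on r for the region-growing stopping rule
REGION_GROWING_TOL = 1e-6

#: lexicographically ordered offsets of a 3x3 in-plane window
WINDOW_3X3: tuple[tuple[int, int], ...] = tuple(
    (dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
)


@dataclass(frozen=True)
class NeighborhoodConfig:
    """A subset of window offsets, always containing the center ``(0, 0)``."""

    offsets: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        offsets = tuple(sorted(tuple(o) for o in self.offsets))
        object.__setattr__(self, "offsets", offsets)
        if (0, 0) not in offsets:
            raise InvalidInputError("configuration must contain the center (0, 0)")
        if len(set(offsets)) != len(offsets):
            raise InvalidInputError("configuration offsets must be unique")

    @property
    def K(self) -> int:
        return len(self.offsets)

    @property
    def center_index(self) -> int:
        return self.offsets.index((0, 0))


@dataclass(frozen=True)
class ConstraintSpec:
    """Spatial constraints on the CCA weight vector."""

    same_sign: bool = True
    center_min_fraction: float = 0.20

    def __post_init__(self) -> None:
        if not (0.0 <= self.center_min_fraction <= 1.0):
            raise InvalidInputError("center_min_fraction must be in [0, 1]")


def count_configurations(window_shape: Sequence[int]) -> int:
    """Number of center-containing subsets of a window: ``2^(N-1)``."""
    N = prod(int(s) for s in window_shape)
    if N < 1 or any(int(s) % 2 == 0 for s in window_shape):
        raise InvalidInputError("window dimensions must be odd and positive")
    return 2 ** (N - 1)


def enumerate_configurations(
    window_shape: Sequence[int] = (3, 3)
) -> list[NeighborhoodConfig]:
    """All center-containing subsets of a 2D window, K-then-lexicographic order.

    A 3x3 window yields 256 configurations.  Only 2D windows are
    materialized; for 3D counts use :func:`count_configurations`.
    """
    shape = tuple(int(s) for s in window_shape)
    if len(shape) != 2:
        raise InvalidInputError(
            "only 2D windows are materialized; use count_configurations "
            "for higher dimensions"
        )
    if any(s < 1 or s % 2 == 0 for s in shape):
        raise InvalidInputError("window dimensions must be odd and positive")
    half = tuple(s // 2 for s in shape)
    others = sorted(
        (dy, dx)
        for dy in range(-half[0], half[0] + 1)
        for dx in range(-half[1], half[1] + 1)
        if (dy, dx) != (0, 0)
    )
    configs = []
    for k in range(len(others) + 1):
        for combo in itertools.combinations(others, k):
            configs.append(NeighborhoodConfig(((0, 0),) + combo))
    configs.sort(key=lambda c: (c.K, c.offsets))
    return configs


def satisfies_constraints(
    sol: CCASolution | np.ndarray,
    spec: ConstraintSpec,
    center_index: int | None = None,
) -> bool:
    """Check the same-sign and center-weight constraints on a weight vector.

    Zeros never violate the same-sign rule.  Accepts either a
    :class:`CCASolution` (center index taken from it) or a bare alpha array
    with an explicit ``center_index``.
    """
    if isinstance(sol, CCASolution):
        alpha = sol.alpha
        center_index = sol.center_index
    else:
        alpha = np.asarray(sol, dtype=float)
        if center_index is None:
            raise InvalidInputError("center_index required with a bare alpha")
    tol = 1e-12 * (np.abs(alpha).max(initial=0.0) + 1.0)
    if spec.same_sign:
        if np.any(alpha > tol) and np.any(alpha < -tol):
            return False
    amax = np.abs(alpha).max(initial=0.0)
    if np.abs(alpha[center_index]) < spec.center_min_fraction * amax - tol:
        return False
    return True


class _PatchSolver:
    """Shared precomputation for all CCA solves within one 3x3 neighborhood.

    Centers the available voxel columns once and caches the Gram matrix
    ``G = Y'Y`` and the design cross-product ``C = X'Y`` so each subset
    solve reduces to a tiny eigen/SVD problem.
    """

    def __init__(self, X: DesignMatrix, Y_raw: np.ndarray):
        self.X = X
        self.Y = center_columns(Y_raw)
        self.n = X.n
        self.G = self.Y.T @ self.Y
        self.C = X.X.T @ self.Y  # p x m

    def solve(self, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, float]:
        """CCA on the column subset ``idx``; returns (alpha, beta, r, rss)."""
        X = self.X
        nm1 = self.n - 1
        S_yy = self.G[np.ix_(idx, idx)] / nm1
        S_xy = self.C[:, idx] / nm1
        alpha, r = _leading_whitened_alpha(S_yy, S_xy, X.Sxx_inv_sqrt)
        alpha = normalize_alpha(alpha)
        Ca = self.C[:, idx] @ alpha
        beta = X.XtX_inv @ Ca
        rss = float(alpha @ (self.G[np.ix_(idx, idx)] @ alpha) - beta @ Ca)
        return alpha, beta, r, max(rss, 0.0)


def _extract_neighborhood(
    slice_data: np.ndarray,
    voxel: tuple[int, int],
    mask: np.ndarray | None,
) -> tuple[list[tuple[int, int]], np.ndarray]:
    """In-mask 3x3 neighbors of ``voxel``: (lexicographic offsets, raw series)."""
    data = np.asarray(slice_data, dtype=float)
    if data.ndim != 3:
        raise InvalidInputError("slice_data must be (ny, nx, n)")
    ny, nx, _ = data.shape
    iy, ix = voxel
    if not (0 <= iy < ny and 0 <= ix < nx):
        raise InvalidInputError(f"voxel {voxel} outside the slice")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if not mask[iy, ix]:
            raise InvalidInputError(f"voxel {voxel} is outside the mask")
    offsets, cols = [], []
    for dy, dx in WINDOW_3X3:
        y, x = iy + dy, ix + dx
        if not (0 <= y < ny and 0 <= x < nx):
            continue
        if mask is not None and not mask[y, x]:
            continue
        offsets.append((dy, dx))
        cols.append(data[y, x, :])
    return offsets, np.column_stack(cols)


def _as_solution(
    offsets: Sequence[tuple[int, int]],
    idx: np.ndarray,
    alpha: np.ndarray,
    beta: np.ndarray,
    r: float,
    rss: float,
) -> CCASolution:
    # offsets list is lexicographic and idx increasing, so the chosen
    # offsets are already sorted and alpha stays aligned with them
    chosen = [offsets[i] for i in idx]
    config = NeighborhoodConfig(tuple(chosen))
    return CCASolution(
        alpha=np.asarray(alpha, dtype=float),
        beta=np.asarray(beta, dtype=float),
        r=float(r),
        center_index=config.center_index,
        config=config,
        rss=float(rss),
    )


def exhaustive_ccca(
    X: DesignMatrix,
    slice_data: np.ndarray,
    voxel: tuple[int, int],
    spec: ConstraintSpec = ConstraintSpec(),
    mask: np.ndarray | None = None,
) -> CCASolution:
    """Best feasible configuration by enumerating every center-containing subset.

    Among all subsets of the in-mask 3x3 neighborhood whose unconstrained
    CCA solution satisfies ``spec``, returns the one with maximal r.  Falls
    back to the single-voxel solution (always feasible) when no other subset
    qualifies.
    """
    offsets, Y_raw = _extract_neighborhood(slice_data, voxel, mask)
    solver = _PatchSolver(X, Y_raw)
    center_pos = offsets.index((0, 0))
    others = [i for i in range(len(offsets)) if i != center_pos]
    best = None
    for k in range(len(others) + 1):
        for combo in itertools.combinations(others, k):
            idx = np.array(sorted((center_pos,) + combo))
            alpha, beta, r, rss = solver.solve(idx)
            c_idx = int(np.flatnonzero(idx == center_pos)[0])
            if k > 0 and not satisfies_constraints(alpha, spec, c_idx):
                continue
            if best is None or r > best[0]:
                best = (r, idx, alpha, beta, rss)
    r, idx, alpha, beta, rss = best
    return _as_solution(offsets, idx, alpha, beta, r, rss)


def region_growing_ccca(
    X: DesignMatrix,
    slice_data: np.ndarray,
    voxel: tuple[int, int],
    spec: ConstraintSpec = ConstraintSpec(),
    mask: np.ndarray | None = None,
    tol: float = REGION_GROWING_TOL,
) -> CCASolution:
    """Greedy constrained-CCA search grown from the center voxel.

    Starts with the single-voxel configuration; at every step tentatively
    adds each remaining neighbor, keeps only additions whose unconstrained
    solution is feasible, and commits the one with the largest r (ties
    broken by smallest lexicographic offset).  Stops when the best addition
    improves r by no more than ``tol``.  By construction the returned r
    never exceeds the exhaustive search's r.
    """
    offsets, Y_raw = _extract_neighborhood(slice_data, voxel, mask)
    solver = _PatchSolver(X, Y_raw)
    center_pos = offsets.index((0, 0))
    selected = [center_pos]
    alpha, beta, r, rss = solver.solve(np.array(selected))
    current = (r, np.array(selected), alpha, beta, rss)
    remaining = [i for i in range(len(offsets)) if i != center_pos]
    while remaining:
        best_step = None
        for cand in remaining:  # lexicographic candidate order
            idx = np.array(sorted(selected + [cand]))
            alpha, beta, r, rss = solver.solve(idx)
            c_idx = int(np.flatnonzero(idx == center_pos)[0])
            if not satisfies_constraints(alpha, spec, c_idx):
                continue
            if best_step is None or r > best_step[0]:
                best_step = (r, cand, idx, alpha, beta, rss)
        if best_step is None or best_step[0] <= current[0] + tol:
            break
        r, cand, idx, alpha, beta, rss = best_step
        selected = sorted(selected + [cand])
        remaining.remove(cand)
        current = (r, idx, alpha, beta, rss)
    r, idx, alpha, beta, rss = current
    return _as_solution(offsets, idx, alpha, beta, r, rss)
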