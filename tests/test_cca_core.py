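"""Unit and property tests for the MVMR/CCA core."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from localcca import (
    DesignMatrix,
    NeighborhoodTimeSeries,
    alpha_to_beta,
    beta_to_alpha,
    center_columns,
    glm_fit,
    max_canonical_correlation,
)
from localcca.errors import (
    InvalidInputError,
    SingularDesignError,
)


class TestCenterColumns:
    def test_removes_constants(self):
        M = np.full((5, 2), 3.7)
        assert np.allclose(center_columns(M), 0.0)

    def test_idempotent(self, rng):
        M = center_columns(rng.standard_normal((10, 3)))
        assert np.allclose(center_columns(M), M)

    def test_mean_subtraction(self):
        out = center_columns(np.array([1.0, 2.0, 3.0]))
        assert np.allclose(out[:, 0], [-1.0, 0.0, 1.0])

    def test_rejects_single_row(self):
        with pytest.raises(InvalidInputError):
            center_columns(np.array([[1.0, 2.0]]))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 20), st.integers(1, 5))
    def test_columns_have_zero_mean(self, seed, n, p):
        M = np.random.default_rng(seed).normal(5.0, 2.0, (n, p))
        out = center_columns(M)
        assert out.shape == (n, p)
        assert np.allclose(out.mean(axis=0), 0.0, atol=1e-12)


class TestDesignMatrix:
    def test_rejects_constant_column(self):
        X = np.zeros((10, 2))
        X[:, 0] = center_columns(np.arange(10.0))[:, 0]
        with pytest.raises(SingularDesignError, match="constant"):
            DesignMatrix(X, ("good", "flat"))

    def test_rank_deficiency_names_columns(self, rng):
        a = center_columns(rng.standard_normal(20))[:, 0]
        X = np.column_stack([a, 2.0 * a, center_columns(rng.standard_normal(20))[:, 0]])
        with pytest.raises(SingularDesignError):
            DesignMatrix(X, ("a", "a_copy", "b"))

    def test_rejects_uncentered(self, rng):
        with pytest.raises(InvalidInputError):
            DesignMatrix(rng.normal(4.0, 1.0, (15, 2)), ("a", "b"))


class TestGLMFit:
    def test_exact_recovery(self, random_design):
        b = np.array([1.5, -2.0])
        assert np.allclose(glm_fit(random_design, random_design.X @ b), b)

    def test_orthogonal_response_gives_zero(self, random_design):
        rng = np.random.default_rng(3)
        y = rng.standard_normal(random_design.n)
        y = y - random_design.X @ glm_fit(random_design, y)  # residualize
        assert np.allclose(glm_fit(random_design, y), 0.0, atol=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        X = DesignMatrix(center_columns(rng.standard_normal((20, 2))), ("a", "b"))
        y = rng.standard_normal(20)
        oracle = np.linalg.pinv(X.X) @ y
        assert np.allclose(glm_fit(X, y), oracle, atol=1e-10)

    def test_residual_orthogonal_to_design(self, random_design, rng):
        y = rng.standard_normal(random_design.n)
        resid = y - random_design.X @ glm_fit(random_design, y)
        assert np.allclose(random_design.X.T @ resid, 0.0, atol=1e-9)


def _brute_force_r(X: DesignMatrix, Y: np.ndarray, n_dirs: int = 10_000) -> float:
    """Scan random unit spatial weights and maximize corr(Y a, fitted(Y a))."""
    rng = np.random.default_rng(99)
    K = Y.shape[1]
    A = rng.standard_normal((K, n_dirs))
    A /= np.linalg.norm(A, axis=0, keepdims=True)
    YA = Y @ A
    fitted = X.X @ glm_fit(X, YA)
    num = np.einsum("ij,ij->j", YA, fitted)
    den = np.linalg.norm(YA, axis=0) * np.linalg.norm(fitted, axis=0)
    with np.errstate(invalid="ignore"):
        r = num / den
    return float(np.nanmax(np.abs(r)))


class TestMaxCanonicalCorrelation:
    def test_single_voxel_is_multiple_correlation(self, random_design, rng):
        y = center_columns(rng.standard_normal(30))[:, 0]
        sol = max_canonical_correlation(random_design, y[:, None])
        fitted = random_design.X @ glm_fit(random_design, y)
        r2 = fitted @ fitted / (y @ y)
        assert sol.K == 1
        assert sol.r == pytest.approx(np.sqrt(r2), abs=1e-10)

    def test_exact_signal_gives_r_one(self, random_design):
        y = random_design.X @ np.array([1.0, 0.5])
        sol = max_canonical_correlation(random_design, y[:, None])
        assert sol.r == pytest.approx(1.0, abs=1e-10)

    def test_matches_nonsymmetric_eigen_oracle(self, random_design, rng):
        Y = center_columns(rng.standard_normal((30, 3)))
        sol = max_canonical_correlation(random_design, Y)
        n = 30
        S_yy = Y.T @ Y / (n - 1)
        S_xy = random_design.X.T @ Y / (n - 1)
        S_xx = random_design.X.T @ random_design.X / (n - 1)
        M = np.linalg.inv(S_yy) @ S_xy.T @ np.linalg.inv(S_xx) @ S_xy
        lam = np.max(np.linalg.eigvals(M).real)
        assert sol.lambda_m == pytest.approx(lam, abs=1e-10)

    def test_brute_force_never_beats_solver(self, random_design, rng):
        for K in (2, 3, 4):
            Y = center_columns(rng.standard_normal((30, K)))
            sol = max_canonical_correlation(random_design, Y)
            assert _brute_force_r(random_design, Y) <= sol.r + 1e-3

    def test_r_invariant_to_column_rescaling(self, random_design, rng):
        Y = center_columns(rng.standard_normal((30, 3)))
        r1 = max_canonical_correlation(random_design, Y).r
        Y2 = Y * np.array([3.0, 0.2, 11.0])
        r2 = max_canonical_correlation(random_design, Y2).r
        assert r1 == pytest.approx(r2, abs=1e-9)

    def test_alpha_scaling_and_sign_convention(self, random_design, rng):
        Y = center_columns(rng.standard_normal((30, 4)))
        sol = max_canonical_correlation(random_design, Y)
        assert np.abs(sol.alpha).sum() == pytest.approx(1.0, abs=1e-12)
        assert sol.alpha.sum() >= 0.0
        assert 0.0 <= sol.r <= 1.0

    def test_beta_is_least_squares_given_alpha(self, random_design, rng):
        """Perturbing beta can only increase the fitting error."""
        Y = center_columns(rng.standard_normal((30, 3)))
        sol = max_canonical_correlation(random_design, Y)
        ya = Y @ sol.alpha
        base = np.sum((ya - random_design.X @ sol.beta) ** 2)
        for _ in range(20):
            pert = sol.beta + rng.normal(0.0, 0.01, sol.beta.shape)
            assert np.sum((ya - random_design.X @ pert) ** 2) >= base - 1e-12

    def test_duplicated_voxel_series_ridge_warns(self, random_design, rng):
        y = center_columns(rng.standard_normal(30))[:, 0]
        Y = np.column_stack([y, y])
        with pytest.warns(RuntimeWarning, match="near singular"):
            sol = max_canonical_correlation(random_design, Y)
        assert 0.0 <= sol.r <= 1.0

    def test_requires_n_exceeding_p_plus_K(self, rng):
        X = DesignMatrix(center_columns(rng.standard_normal((8, 2))), ("a", "b"))
        Y = center_columns(rng.standard_normal((8, 6)))
        with pytest.raises(InvalidInputError):
            max_canonical_correlation(X, Y)


class TestAlphaBetaMaps:
    def test_roundtrip_is_fixed_point(self, random_design, rng):
        Y = center_columns(rng.standard_normal((30, 3)))
        sol = max_canonical_correlation(random_design, Y)
        beta = alpha_to_beta(random_design, Y, sol.alpha)
        alpha_back = beta_to_alpha(random_design, Y, beta)
        alpha_back /= np.abs(alpha_back).sum()
        if alpha_back.sum() < 0:
            alpha_back = -alpha_back
        assert np.allclose(alpha_back, sol.alpha, atol=1e-8)

    def test_zero_maps_to_zero(self, random_design, rng):
        Y = center_columns(rng.standard_normal((30, 3)))
        assert np.allclose(alpha_to_beta(random_design, Y, np.zeros(3)), 0.0)

    def test_matches_dense_matrix_oracle(self, random_design, rng):
        Y = center_columns(rng.standard_normal((30, 3)))
        alpha = rng.standard_normal(3)
        X = random_design.X
        oracle = np.linalg.inv(X.T @ X) @ X.T @ Y @ alpha
        assert np.allclose(alpha_to_beta(random_design, Y, alpha), oracle, atol=1e-10)
        beta = rng.standard_normal(2)
        oracle_a = np.linalg.inv(Y.T @ Y) @ Y.T @ X @ beta
        assert np.allclose(beta_to_alpha(random_design, Y, beta), oracle_a, atol=1e-10)


def test_neighborhood_series_validates_bounds(rng):
    Y = center_columns(rng.standard_normal((20, 3)))
    with pytest.raises(InvalidInputError):
        NeighborhoodTimeSeries(Y, (0, 1, 2), center_index=5)
    with pytest.raises(InvalidInputError):
        NeighborhoodTimeSeries(rng.standard_normal((20, 10)), tuple(range(10)), 0)
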