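"""Synthetic and surrogate data generation.

Everything the statistical machinery is validated on is generated here:

* :func:`fourier_resample` -- phase-randomized surrogates that preserve each
  series' amplitude spectrum exactly; one shared random phase vector is
  applied to every voxel, which also preserves inter-voxel phase
  differences and hence the spatial correlation structure,
* :func:`synthetic_resting_noise` -- a stand-in for resting-state fMRI
  noise: per-voxel AR(1) temporal autocorrelation, in-plane Gaussian
  spatial correlation, unit variance per voxel,
* activation signal as a unit-variance linear combination of the design
  regressors with random amplitudes, injected into randomly shaped
  center-containing clusters of 2-9 voxels inside a 3x3 patch,
* the noise-fraction mixture ``x = (1 - f) x_act + f x_null`` on active
  voxels (pure ``x_null`` elsewhere), giving ground-truth labels for ROC
  analysis by construction.

Noise-fraction values f = 0.55 and f = 0.65 correspond to peak
signal-to-noise ratios ``((1 - f)/f)^2`` of 67% and 29% and serve as the
"low noise" and "high noise" regimes.

All draws flow through :class:`numpy.random.Generator` objects so a single
top-level seed reproduces any simulation bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage
import scipy.signal

from .cca import DesignMatrix
from .errors import InvalidInputError, InvalidParameterError
from .search import NeighborhoodConfig

#: defaults for the resting-noise stand-in: lag-1 temporal autocorrelation
#: typical of unwhitened gray-matter BOLD at TR = 2 s, and a spatial kernel
#: calibrated so adjacent-voxel noise correlation is ~0.3, as reported for
#: raw (unsmoothed) EPI noise.
NOISE_AR_DEFAULT = 0.5
NOISE_FWHM_DEFAULT = 1.2

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass(frozen=True)
class SimulationSpec:
    """Conditions for one simulated activation patch."""

    f: float
    shape: NeighborhoodConfig
    amplitudes: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.f <= 1.0):
            raise InvalidParameterError("noise fraction f must lie in [0, 1]")
        amps = np.asarray(self.amplitudes, dtype=float)
        if np.any(amps < 0.0) or np.any(amps > 1.0):
            raise InvalidParameterError("amplitudes must lie in [0, 1]")
        object.__setattr__(self, "amplitudes", amps)


@dataclass(frozen=True)
class NullSurrogate:
    """Phase-randomized surrogate with the seed that produced it."""

    data: np.ndarray
    phase_permutation_seed: int | None


def fourier_resample(data: np.ndarray, seed=None) -> NullSurrogate:
    """Phase-randomized surrogate of ``(n, V)`` time-by-voxel data.

    The rFFT of every voxel series is rotated by one shared random phase
    vector (conjugate symmetry handled by the real FFT); the DC bin keeps
    zero phase shift so the per-voxel mean is preserved, and the Nyquist bin
    (even n) stays real.  Per-voxel amplitude spectra are preserved exactly
    and perfectly correlated voxels remain perfectly correlated.
    """
    x = np.asarray(data, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    n = x.shape[0]
    if n < 8:
        raise InvalidInputError("need at least 8 time points for resampling")
    rng = _as_rng(seed)
    spec = np.fft.rfft(x, axis=0)
    n_bins = spec.shape[0]
    phases = np.zeros(n_bins)
    hi = n_bins - 1 if n % 2 == 0 else n_bins  # keep Nyquist real for even n
    phases[1:hi] = rng.uniform(0.0, 2.0 * np.pi, hi - 1)
    spec = spec * np.exp(1j * phases)[:, None]
    out = np.fft.irfft(spec, n=n, axis=0)
    if squeeze:
        out = out[:, 0]
    seed_val = seed if isinstance(seed, (int, np.integer)) else None
    return NullSurrogate(data=out, phase_permutation_seed=seed_val)


def synthetic_resting_noise(
    shape: tuple[int, ...],
    n: int,
    spatial_fwhm: float = NOISE_FWHM_DEFAULT,
    ar_coeff: float = NOISE_AR_DEFAULT,
    seed=None,
) -> np.ndarray:
    """Resting-state-like noise of shape ``(*shape, n)``, unit variance per voxel.

    Temporal structure is a stationary AR(1) process with coefficient
    ``ar_coeff``; spatial structure comes from in-plane Gaussian smoothing
    with the given FWHM (in voxels).  After smoothing, each voxel series is
    re-standardized to zero mean and unit variance, so ``ar_coeff = 0`` and
    ``spatial_fwhm = 0`` yield plain white noise.
    """
    if not (0.0 <= ar_coeff < 1.0):
        raise InvalidParameterError("ar_coeff must lie in [0, 1)")
    if spatial_fwhm < 0.0:
        raise InvalidParameterError("spatial_fwhm must be nonnegative")
    rng = _as_rng(seed)
    shape = tuple(int(s) for s in shape)
    eps = rng.standard_normal((n, *shape))
    if ar_coeff > 0.0:
        # stationary AR(1): x_t = rho x_{t-1} + sqrt(1 - rho^2) eps_t
        eps = eps * np.sqrt(1.0 - ar_coeff**2)
        eps[0] /= np.sqrt(1.0 - ar_coeff**2)
        x = scipy.signal.lfilter([1.0], [1.0, -ar_coeff], eps, axis=0)
    else:
        x = eps
    if spatial_fwhm > 0.0:
        sigma = spatial_fwhm * _FWHM_TO_SIGMA
        x = scipy.ndimage.gaussian_filter(
            x, sigma=sigma, axes=tuple(range(1, x.ndim)), mode="reflect"
        )
    x = x - x.mean(axis=0, keepdims=True)
    sd = x.std(axis=0, keepdims=True)
    sd[sd == 0.0] = 1.0
    x = x / sd
    return np.moveaxis(x, 0, -1)


def make_activation_timecourse(
    X: DesignMatrix, amplitudes: np.ndarray
) -> np.ndarray:
    """Unit-variance linear combination of the design regressors.

    ``x_act = sum_i beta_i * regressor_i``, then variance-normalized to 1,
    so the overall amplitude scale drops out of the mixture.
    """
    amps = np.asarray(amplitudes, dtype=float).ravel()
    if amps.size != X.p:
        raise InvalidInputError(
            f"{amps.size} amplitudes for {X.p} regressors"
        )
    if not np.any(amps):
        raise InvalidInputError("all-zero amplitudes give no activation signal")
    x = X.X @ amps
    sd = x.std()
    if sd == 0.0:
        raise InvalidInputError("activation time course is constant")
    return x / sd


def injected_amplitudes(
    X: DesignMatrix, amplitudes: np.ndarray, f: float
) -> np.ndarray:
    """Regressor coefficients actually present in a mixed active voxel.

    Drawing amplitudes ``beta_i``, variance-normalizing the combination and
    mixing with noise fraction f rescales the generating coefficients: the
    signal entering the data is ``(1 - f) * X @ beta / sd(X @ beta)``, so an
    unbiased per-voxel regression recovers ``(1 - f) * beta / sd(X @ beta)``.
    Amplitude-recovery error is therefore measured against this vector.
    """
    if not (0.0 <= f <= 1.0):
        raise InvalidParameterError("noise fraction f must lie in [0, 1]")
    amps = np.asarray(amplitudes, dtype=float).ravel()
    sd = (X.X @ amps).std()
    if sd == 0.0:
        raise InvalidInputError("activation time course is constant")
    return (1.0 - f) * amps / sd


def mix_timecourses(
    x_act: np.ndarray, x_null: np.ndarray, f: float
) -> np.ndarray:
    """Noise-fraction mixture ``(1 - f) x_act + f x_null`` for one voxel."""
    if not (0.0 <= f <= 1.0):
        raise InvalidParameterError("noise fraction f must lie in [0, 1]")
    x_act = np.asarray(x_act, dtype=float)
    x_null = np.asarray(x_null, dtype=float)
    if x_act.shape != x_null.shape:
        raise InvalidInputError("signal and noise series must share a length")
    return (1.0 - f) * x_act + f * x_null


def mix_pseudoreal(
    x_act: np.ndarray,
    noise: np.ndarray,
    active_mask: np.ndarray,
    f: float,
) -> np.ndarray:
    """Inject one activation time course into the active voxels of a slice.

    ``noise`` is ``(ny, nx, n)``; active voxels receive
    ``(1 - f) x_act + f x_null`` with their own noise series as x_null,
    all other voxels keep their noise unchanged.  The active-set labels are
    exact ground truth for ROC analysis.
    """
    if not (0.0 <= f <= 1.0):
        raise InvalidParameterError("noise fraction f must lie in [0, 1]")
    noise = np.asarray(noise, dtype=float)
    active = np.asarray(active_mask, dtype=bool)
    if active.shape != noise.shape[:-1]:
        raise InvalidInputError("active mask does not match the slice grid")
    out = noise.copy()
    out[active] = (1.0 - f) * np.asarray(x_act, dtype=float) + f * noise[active]
    return out


def peak_snr_percent(f: float) -> float:
    """Peak signal-to-noise ratio ``((1 - f)/f)^2`` as a percentage."""
    if not (0.0 < f <= 1.0):
        raise InvalidParameterError("f must lie in (0, 1]")
    return ((1.0 - f) / f) ** 2 * 100.0


def random_activation_shape(seed=None) -> NeighborhoodConfig:
    """Random center-containing activation shape of size 2-9 in a 3x3 grid.

    The size is uniform on {2, ..., 9}; the remaining members are drawn
    without replacement from the eight non-center offsets.
    """
    rng = _as_rng(seed)
    size = int(rng.integers(2, 10))
    others = [
        (dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)
    ]
    chosen = rng.choice(len(others), size=size - 1, replace=False)
    return NeighborhoodConfig(((0, 0),) + tuple(others[i] for i in chosen))


def shape_to_mask(shape: NeighborhoodConfig, grid: tuple[int, int] = (3, 3),
                  center: tuple[int, int] | None = None) -> np.ndarray:
    """Binary mask of an activation shape on a grid (center defaults to middle)."""
    mask = np.zeros(grid, dtype=bool)
    cy, cx = center if center is not None else (grid[0] // 2, grid[1] // 2)
    for dy, dx in shape.offsets:
        mask[cy + dy, cx + dx] = True
    return mask


def simulate_patch(
    X: DesignMatrix,
    f: float,
    amplitudes: np.ndarray,
    shape: NeighborhoodConfig,
    seed=None,
    spatial_fwhm: float = NOISE_FWHM_DEFAULT,
    ar_coeff: float = NOISE_AR_DEFAULT,
) -> tuple[np.ndarray, np.ndarray]:
    """One 3x3 activation patch: returns (data (3, 3, n), truth mask (3, 3))."""
    rng = _as_rng(seed)
    noise = synthetic_resting_noise(
        (3, 3), X.n, spatial_fwhm=spatial_fwhm, ar_coeff=ar_coeff, seed=rng
    )
    x_act = make_activation_timecourse(X, amplitudes)
    truth = shape_to_mask(shape)
    return mix_pseudoreal(x_act, noise, truth, f), truth


def simulate_pseudoreal_slice(
    X: DesignMatrix,
    f: float,
    slice_shape: tuple[int, int] = (24, 24),
    mode: str = "focal",
    n_clusters: int = 6,
    contrast: np.ndarray | None = None,
    seed=None,
    spatial_fwhm: float = NOISE_FWHM_DEFAULT,
    ar_coeff: float = NOISE_AR_DEFAULT,
) -> tuple[np.ndarray, np.ndarray]:
    """A whole pseudoreal slice with known truth labels.

    ``mode = "focal"`` scatters ``n_clusters`` random 2-9-voxel shapes on
    disjoint 3x3 sites (irregular, spatially localized activation, as in
    memory paradigms); ``mode = "extended"`` places one large disc of radius
    ~ a quarter of the slice (spatially extended activation, as in primary
    visual stimulation).  Each cluster gets its own random amplitude vector;
    when a ``contrast`` is given, amplitudes are redrawn until the contrast
    effect is positive so the directional statistic has a detectable sign.

    Returns ``(data (ny, nx, n), truth (ny, nx))``.
    """
    rng = _as_rng(seed)
    ny, nx = slice_shape
    noise = synthetic_resting_noise(
        (ny, nx), X.n, spatial_fwhm=spatial_fwhm, ar_coeff=ar_coeff, seed=rng
    )
    truth = np.zeros((ny, nx), dtype=bool)
    data = noise

    def draw_amplitudes() -> np.ndarray:
        for _ in range(200):
            amps = rng.uniform(0.0, 1.0, X.p)
            if contrast is None or float(np.asarray(contrast) @ amps) > 0.05:
                return amps
        raise InvalidParameterError("could not draw contrast-positive amplitudes")

    if mode == "focal":
        sites: list[tuple[int, int]] = []
        attempts = 0
        while len(sites) < n_clusters and attempts < 1000:
            attempts += 1
            cy = int(rng.integers(1, ny - 1))
            cx = int(rng.integers(1, nx - 1))
            if all(abs(cy - sy) > 3 or abs(cx - sx) > 3 for sy, sx in sites):
                sites.append((cy, cx))
        for cy, cx in sites:
            shape = random_activation_shape(rng)
            cluster = shape_to_mask(shape, grid=(ny, nx), center=(cy, cx))
            x_act = make_activation_timecourse(X, draw_amplitudes())
            data = mix_pseudoreal(x_act, data, cluster, f)
            truth |= cluster
    elif mode == "extended":
        cy, cx = ny / 2.0, nx / 2.0
        radius = min(ny, nx) / 4.0
        yy, xx = np.mgrid[0:ny, 0:nx]
        cluster = (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2
        x_act = make_activation_timecourse(X, draw_amplitudes())
        data = mix_pseudoreal(x_act, data, cluster, f)
        truth |= cluster
    else:
        raise InvalidParameterError(f"unknown mode {mode!r}")
    return data, truth
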