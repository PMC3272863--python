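"""Design-matrix construction for block-design fMRI experiments.

Regressors are built by convolving condition boxcars with the classic
two-gamma hemodynamic response function (HRF) on a fine time grid, sampling
at the repetition time TR, and column centering.  Two paradigms used
throughout the package ship as ready-made builders:

* :func:`visual_design` -- a flashing-checkerboard paradigm with a fixation
  (F) and a visual (V) regressor; 2 s stimulation blocks alternate with
  fixation blocks of random 2-10 s duration,
* :func:`memory_design` -- an episodic-memory paradigm with instruction (I),
  encoding (E), recognition (R) and control (C) regressors: a 16 s fixation
  lead-in, six 89 s cycles of 5 s instruction / 21 s encoding / 5 s
  instruction / 11 s control / 5 s instruction / 42 s recognition, and a
  16 s fixation tail, 283 volumes at TR = 2 s.

A discrete-cosine high-pass filter (:func:`highpass_filter`) removes drifts
with periods longer than a cutoff (default 150 s).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
from scipy.stats import gamma as _gamma_dist

from .cca import DesignMatrix, center_columns
from .errors import InvalidDesignError, InvalidInputError

#: default two-gamma HRF parameters, seconds
HRF_DEFAULTS = dict(
    peak_delay=6.0,
    undershoot_delay=16.0,
    peak_dispersion=1.0,
    undershoot_dispersion=1.0,
    peak_undershoot_ratio=6.0,
)


def double_gamma_hrf(
    t: np.ndarray,
    peak_delay: float = 6.0,
    undershoot_delay: float = 16.0,
    peak_dispersion: float = 1.0,
    undershoot_dispersion: float = 1.0,
    peak_undershoot_ratio: float = 6.0,
) -> np.ndarray:
    """Canonical two-gamma HRF evaluated at times ``t`` (seconds).

    Difference of two gamma densities with shape = delay / dispersion and
    scale = dispersion; the undershoot is divided by
    ``peak_undershoot_ratio``.  Not normalized -- callers scale the sampled
    kernel (builders use unit sum so a long block plateaus at 1).
    """
    t = np.asarray(t, dtype=float)
    peak = _gamma_dist.pdf(t, peak_delay / peak_dispersion, scale=peak_dispersion)
    under = _gamma_dist.pdf(
        t, undershoot_delay / undershoot_dispersion, scale=undershoot_dispersion
    )
    return peak - under / peak_undershoot_ratio


def _validate_blocks(name: str, onsets, durations, total: float):
    onsets = np.asarray(onsets, dtype=float)
    durations = np.broadcast_to(np.asarray(durations, dtype=float), onsets.shape)
    if onsets.size == 0:
        raise InvalidDesignError(f"condition {name!r} has no onsets")
    if np.any(onsets < 0.0) or np.any(onsets >= total):
        raise InvalidDesignError(
            f"condition {name!r} has onsets outside [0, {total:g})"
        )
    if np.any(durations <= 0.0):
        raise InvalidDesignError(f"condition {name!r} has nonpositive durations")
    order = np.argsort(onsets)
    ons, dur = onsets[order], durations[order]
    if np.any(ons[1:] < ons[:-1] + dur[:-1] - 1e-9):
        raise InvalidDesignError(f"condition {name!r} has overlapping blocks")
    return ons, dur


def build_design(
    conditions: Mapping[str, tuple[Sequence[float], Sequence[float] | float]],
    tr: float,
    n_scans: int,
    hrf_params: Mapping[str, float] | None = None,
    oversample: int = 16,
    hrf_length: float = 32.0,
) -> DesignMatrix:
    """Build a centered design matrix from condition onsets and durations.

    Parameters
    ----------
    conditions
        Mapping from condition name to ``(onsets, durations)`` in seconds;
        ``durations`` may be a scalar applied to all onsets.
    tr
        Repetition time in seconds.
    n_scans
        Number of volumes; regressors are sampled at ``t = i * tr``.
    hrf_params
        Overrides for :data:`HRF_DEFAULTS`.
    oversample
        Fine-grid factor for the boxcar/HRF convolution.
    hrf_length
        Kernel support in seconds.
    """
    if n_scans < 2:
        raise InvalidDesignError("need at least 2 scans")
    params = dict(HRF_DEFAULTS)
    params.update(hrf_params or {})
    dt = tr / oversample
    n_fine = n_scans * oversample
    total = n_scans * tr
    t_kernel = np.arange(0.0, hrf_length, dt)
    kernel = double_gamma_hrf(
        t_kernel,
        peak_delay=params["peak_delay"],
        undershoot_delay=params["undershoot_delay"],
        peak_dispersion=params["peak_dispersion"],
        undershoot_dispersion=params["undershoot_dispersion"],
        peak_undershoot_ratio=params["peak_undershoot_ratio"],
    )
    kernel = kernel / kernel.sum()  # long blocks plateau at 1
    cols, names = [], []
    for name, (onsets, durations) in conditions.items():
        ons, dur = _validate_blocks(name, onsets, durations, total)
        box = np.zeros(n_fine)
        for o, d in zip(ons, dur):
            i0 = int(round(o / dt))
            i1 = min(int(round((o + d) / dt)), n_fine)
            box[i0:i1] = 1.0
        reg = np.convolve(box, kernel)[:n_fine][::oversample]
        if np.ptp(reg) < 1e-12:
            raise InvalidDesignError(
                f"condition {name!r} yields a constant regressor"
            )
        cols.append(reg)
        names.append(name)
    X = center_columns(np.column_stack(cols))
    return DesignMatrix(X, tuple(names))


def memory_design(tr: float = 2.0, n_scans: int = 283) -> DesignMatrix:
    """Episodic-memory paradigm design (I, E, R, C), p = 4 regressors."""
    cycle = 89.0
    starts = 16.0 + cycle * np.arange(6)
    conditions = {
        "I": (np.sort(np.concatenate([starts, starts + 26, starts + 42])), 5.0),
        "E": (starts + 5.0, 21.0),
        "R": (starts + 47.0, 42.0),
        "C": (starts + 31.0, 11.0),
    }
    return build_design(conditions, tr=tr, n_scans=n_scans)


def visual_design(
    tr: float = 2.0, n_scans: int = 145, seed: int = 0
) -> DesignMatrix:
    """Flashing-checkerboard paradigm design (F, V).

    2 s checkerboard blocks alternate with fixation blocks whose durations
    are drawn uniformly from [2, 10] s; the sequence is reproducible from
    ``seed``.  The two regressors tile the run, so after centering they are
    strongly anticorrelated but remain linearly independent through the
    convolution edge effects.
    """
    rng = np.random.default_rng(seed)
    total = n_scans * tr
    f_on, f_dur, v_on = [], [], []
    t = 0.0
    while t < total - 2.0:
        d_fix = float(rng.uniform(2.0, 10.0))
        f_on.append(t)
        f_dur.append(d_fix)
        t += d_fix
        if t >= total:
            break
        v_on.append(t)
        t += 2.0
    conditions = {
        "F": (np.asarray(f_on), np.asarray(f_dur)),
        "V": (np.asarray(v_on), 2.0),
    }
    return build_design(conditions, tr=tr, n_scans=n_scans)


def highpass_filter(
    series: np.ndarray, tr: float, cutoff: float = 150.0
) -> np.ndarray:
    """Remove slow drifts by projecting out a discrete-cosine basis.

    Cosine components with period longer than ``cutoff`` seconds (plus the
    mean) are regressed out, mirroring the standard fMRI high-pass step.
    Accepts a single series or an ``n x V`` matrix of series.
    """
    x = np.asarray(series, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    n = x.shape[0]
    if n < 2:
        raise InvalidInputError("need at least 2 time points")
    if cutoff <= 0.0:
        raise InvalidInputError("cutoff period must be positive")
    n_comp = int(np.floor(2.0 * n * tr / cutoff))
    x = x - x.mean(axis=0, keepdims=True)
    if n_comp >= 1:
        i = np.arange(n)
        k = np.arange(1, n_comp + 1)
        basis = np.cos(np.pi * np.outer(2 * i + 1, k) / (2.0 * n))
        basis /= np.linalg.norm(basis, axis=0, keepdims=True)
        x = x - basis @ (basis.T @ x)
    return x[:, 0] if squeeze else x
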