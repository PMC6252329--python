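"""Comparator single-trial mining methods: PCA, SVD and MLR/MLRd regression.

These are the reference approaches the graph-based miner is benchmarked
against.  PCA keeps the leading components explaining a variance fraction,
reconstructs the trials from them and averages; SVD exposes individual
sample-domain singular time courses; MLR models each trial by least squares
on two regressors (the windowed average ERP and its temporal derivative);
MLRd replaces those with the three leading principal components of a
"variability matrix" built by shifting and time-compressing the average
ERP, which lets the fit absorb latency and morphology jitter.
"""

from __future__ import annotations

import numpy as np

from .core_io import TrialSet

__all__ = [
    "pca_baseline",
    "svd_baseline",
    "mlr_baseline",
    "mlrd_baseline",
    "variability_matrix",
    "DEFAULT_SHIFT_GRID",
    "DEFAULT_COMPRESS_GRID",
]

# grids spanning the MMN latency-jitter scale: shifts ±50 ms step 5 ms,
# compressions 0.8..1.2
DEFAULT_SHIFT_GRID = tuple(np.round(np.arange(-0.050, 0.0501, 0.005), 3))
DEFAULT_COMPRESS_GRID = (0.8, 0.9, 1.0, 1.1, 1.2)


def pca_baseline(ts: TrialSet, variance_threshold: float = 0.95):
    """Average of trials reconstructed from the leading principal components.

    Trials are centered (per sample, across trials); the smallest leading
    set of components whose cumulative explained variance exceeds the
    threshold is retained.  Returns ``(waveform, n_components, info)``
    where ``info`` carries the explained-variance fractions and the
    component time courses (rows), so individual components (e.g. the 4th
    or 5th) can be inspected.
    """
    if not 0 < variance_threshold <= 1:
        raise ValueError("variance_threshold must lie in (0, 1]")
    if ts.n_trials <= 2:
        raise ValueError("PCA baseline needs more than 2 trials")
    X = ts.data
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    total = var.sum()
    frac = var / total if total > 0 else np.zeros_like(var)
    cum = np.cumsum(frac)
    n_keep = int(np.searchsorted(cum, variance_threshold) + 1)
    n_keep = min(n_keep, len(s))
    if variance_threshold == 1.0:
        n_keep = len(s)
    recon = mean + (U[:, :n_keep] * s[:n_keep]) @ Vt[:n_keep]
    waveform = recon.mean(axis=0)
    info = {
        "explained_variance_ratio": frac,
        "components": Vt,  # sample-domain, one per row
        "scores": U * s,
    }
    return waveform, n_keep, info


def svd_baseline(ts: TrialSet, components) -> np.ndarray:
    """Selected sample-domain singular time courses (1-based indices).

    Each requested right singular vector is scaled by its singular value;
    multiple requests are averaged.
    """
    comps = [int(c) for c in np.atleast_1d(components)]
    U, s, Vt = np.linalg.svd(ts.data, full_matrices=False)
    rank = int(np.sum(s > s[0] * max(ts.data.shape) * np.finfo(float).eps))
    for c in comps:
        if not 1 <= c <= rank:
            raise ValueError(f"component {c} exceeds the matrix rank {rank}")
    series = np.vstack([s[c - 1] * Vt[c - 1] for c in comps])
    return series.mean(axis=0)


def _interval_mask(ts: TrialSet, interval) -> np.ndarray:
    t = ts.times
    if interval[0] < t[0] - 1e-12 or interval[1] > t[-1] + 1.0 / ts.sampling_rate + 1e-12:
        raise ValueError(f"interval {interval} outside the epoch [{t[0]}, {t[-1]}] s")
    mask = (t >= interval[0]) & (t < interval[1])
    if mask.sum() < 3:
        raise ValueError("interval covers fewer than 3 samples")
    return mask


def _fit_regressors(X: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Least-squares fit of each trial (row of X) on the design columns."""
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise np.linalg.LinAlgError(
            f"degenerate design: rank {rank} < {design.shape[1]} regressors"
        )
    coef, *_ = np.linalg.lstsq(design, X.T, rcond=None)
    return coef  # n_regressors x n_trials


def mlr_baseline(ts: TrialSet, interval=(0.0, 0.3)):
    """Multiple linear regression on the average ERP and its derivative.

    Within the post-stimulus interval, each trial is modeled by least
    squares on two regressors — the within-interval average ERP and its
    temporal derivative — and the fitted trials are grand-averaged.
    Returns ``(waveform, coefficients)``; the waveform is zero outside the
    modeled interval.
    """
    mask = _interval_mask(ts, interval)
    seg = ts.data[:, mask]
    avg = seg.mean(axis=0)
    deriv = np.gradient(avg)
    design = np.column_stack([avg, deriv])
    coef = _fit_regressors(seg, design)
    fitted = (design @ coef).T  # n_trials x window
    waveform = np.zeros(ts.n_samples)
    waveform[mask] = fitted.mean(axis=0)
    return waveform, coef


def variability_matrix(
    avg: np.ndarray,
    fs: float,
    shift_grid=DEFAULT_SHIFT_GRID,
    compress_grid=DEFAULT_COMPRESS_GRID,
) -> np.ndarray:
    """Stack of the average ERP shifted and time-compressed over the grids.

    One row per (shift, compression) pair — |shift_grid| x |compress_grid|
    rows in total; row order is immaterial downstream.  Compression scales
    the time axis about the window start, with linear interpolation and
    edge-value extrapolation.
    """
    shift_grid = list(shift_grid)
    compress_grid = list(compress_grid)
    if not shift_grid or not compress_grid:
        raise ValueError("shift and compression grids must be non-empty")
    n = avg.size
    t = np.arange(n) / fs
    rows = []
    for shift in shift_grid:
        for c in compress_grid:
            rows.append(np.interp((t - shift) / c, t, avg))
    return np.vstack(rows)


def mlrd_baseline(
    ts: TrialSet,
    interval=(0.0, 0.5),
    shift_grid=DEFAULT_SHIFT_GRID,
    compress_grid=DEFAULT_COMPRESS_GRID,
):
    """MLR with dispersion: regressors from a shifted/compressed basis.

    Step 1 builds the variability matrix of the windowed average ERP over
    the shift and compression grids; step 2 takes principal components of
    that (row-centered) stack; step 3 uses the three leading components as
    regressors; step 4 fits each trial by least squares and averages the
    fitted trials.  Returns ``(waveform, coefficients)``.
    """
    interval = (interval[0], min(interval[1], float(ts.times[-1]) + 1.0 / ts.sampling_rate))
    mask = _interval_mask(ts, interval)
    seg = ts.data[:, mask]
    avg = seg.mean(axis=0)
    vm = variability_matrix(avg, ts.sampling_rate, shift_grid, compress_grid)
    vc = vm - vm.mean(axis=0)
    U, s, Vt = np.linalg.svd(vc, full_matrices=False)
    tol = s[0] * max(vc.shape) * np.finfo(float).eps if s.size else 0.0
    rank = int(np.sum(s > tol))
    if rank < 3:
        raise np.linalg.LinAlgError(
            f"variability matrix has rank {rank} < 3; enlarge the shift or "
            "compression grid"
        )
    design = Vt[:3].T  # window x 3 regressors
    coef = _fit_regressors(seg, design)
    fitted = (design @ coef).T
    waveform = np.zeros(ts.n_samples)
    waveform[mask] = fitted.mean(axis=0)
    return waveform, coef
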