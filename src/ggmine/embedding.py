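"""Distance-correlation similarity between trials and its 2-D embedding.

The pairwise dependence between trials is measured with the sample distance
correlation (the biased V-statistic estimator): pairwise absolute-difference
matrices of each series are double-centered, and dCor is the normalized
inner product of the centered matrices.  Trials are tabulated in a distance
matrix ``DM[i, j] = 1 - dCor(trial_i, trial_j)`` — dCor is a similarity in
[0, 1], so ``1 - dCor`` is the canonical distance conversion — and embedded
in the plane by classical (Torgerson) multidimensional scaling.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass

import numpy as np

from .core_io import TrialSet

__all__ = [
    "TrialDistanceMatrix",
    "PointSet2D",
    "distance_correlation",
    "similarity_matrix",
    "mds_embed",
]


@dataclass(frozen=True)
class TrialDistanceMatrix:
    """Symmetric matrix of pairwise trial distances, entries in [0, 1]."""

    dm: np.ndarray
    metric: str = "1 - dCor"

    def __post_init__(self) -> None:
        m = np.asarray(self.dm, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(m) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        object.__setattr__(self, "dm", m)

    @property
    def n(self) -> int:
        return self.dm.shape[0]


@dataclass(frozen=True)
class PointSet2D:
    """2-D embedded coordinates of trials, one row per trial."""

    coords: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        c = np.asarray(self.coords, dtype=float)
        if c.ndim != 2 or c.shape[1] != 2:
            raise ValueError("coords must be an n x 2 matrix")
        if not np.all(np.isfinite(c)):
            raise ValueError("coords must be finite")
        object.__setattr__(self, "coords", c)

    @property
    def n(self) -> int:
        return self.coords.shape[0]


def _centered_dist(x: np.ndarray) -> np.ndarray:
    """Double-centered pairwise absolute-difference matrix of a 1-D series."""
    d = np.abs(x[:, None] - x[None, :])
    return d - d.mean(axis=0, keepdims=True) - d.mean(axis=1, keepdims=True) + d.mean()


def distance_correlation(x, y) -> float:
    """Sample distance correlation between two equal-length series.

    Returns a value in [0, 1]; 1 for any affine relation, 0 by convention
    when either series is constant (the estimator is 0/0 there).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 4:
        raise ValueError("need at least 4 samples for distance correlation")
    A, B = _centered_dist(x), _centered_dist(y)
    dvar_x = (A * A).mean()
    dvar_y = (B * B).mean()
    if dvar_x <= 0 or dvar_y <= 0:
        warnings.warn("constant series: distance correlation set to 0 by convention")
        return 0.0
    dcov2 = (A * B).mean()
    return float(np.sqrt(max(dcov2, 0.0) / np.sqrt(dvar_x * dvar_y)))


def similarity_matrix(ts: TrialSet) -> TrialDistanceMatrix:
    """Pairwise trial distance matrix ``1 - dCor`` over all trial pairs.

    All centered distance matrices are flattened and combined in a single
    matrix product, so the full n x n table costs one GEMM instead of
    n(n-1)/2 separate estimator calls.
    """
    X = ts.data
    n, m = X.shape
    flat = np.empty((n, m * m))
    for i in range(n):
        flat[i] = _centered_dist(X[i]).ravel()
    gram = (flat @ flat.T) / (m * m)  # gram[i, j] = dCov^2(i, j)
    dvar = np.diag(gram).copy()
    degenerate = dvar <= 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} constant trial(s): their distance "
            "correlations set to 0 by convention"
        )
    denom = np.sqrt(np.outer(dvar, dvar))
    with np.errstate(divide="ignore", invalid="ignore"):
        dcor = np.sqrt(np.clip(gram, 0.0, None) / denom)
    dcor[degenerate, :] = 0.0
    dcor[:, degenerate] = 0.0
    dcor = np.clip(dcor, 0.0, 1.0)
    dm = 1.0 - dcor
    np.fill_diagonal(dm, 0.0)
    dm = (dm + dm.T) / 2.0
    return TrialDistanceMatrix(dm=dm)


def mds_embed(dm: TrialDistanceMatrix, dim: int = 2) -> PointSet2D:
    """Classical (Torgerson) scaling of a distance matrix into the plane.

    The squared-distance matrix is double-centered, and coordinates are the
    two leading non-negative eigenpairs scaled by sqrt(eigenvalue).  The
    result is deterministic: each axis is flipped so that its coordinate of
    largest magnitude is positive (ties broken toward the lower point index,
    which ``argmax`` does by taking the first maximum).
    """
    if dim != 2:
        raise ValueError("the mining method is defined on the plane (dim=2)")
    D2 = dm.dm**2
    n = dm.n
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    B = (B + B.T) / 2.0
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    coords = np.zeros((n, 2))
    n_pos = int(np.sum(evals[:2] > 1e-12))
    if n_pos < 2:
        warnings.warn(
            f"degenerate embedding: only {n_pos} positive eigenvalue(s); "
            "remaining axis filled with zeros"
        )
    for j in range(min(2, n_pos) if n_pos else 0):
        coords[:, j] = evecs[:, j] * np.sqrt(evals[j])
    # axis-sign convention for reproducibility
    for j in range(2):
        col = coords[:, j]
        if col.any():
            i = int(np.argmax(np.abs(col)))
            if col[i] < 0:
                coords[:, j] = -col
    prov = hashlib.sha256(np.ascontiguousarray(dm.dm).tobytes()).hexdigest()[:16]
    return PointSet2D(coords=coords, provenance=prov)
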