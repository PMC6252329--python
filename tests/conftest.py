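"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive the geometric predicates and the
distance-correlation estimator from their definitions (plain loops over the
formulas), independently of the package's vectorized implementations.
"""

from __future__ import annotations

import numpy as np
import pytest

from ggmine import PipelineConfig, TrialSet

RTOL = 1e-9


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_trialset(rng):
    """10 random trials of 40 samples at 512 Hz."""
    return TrialSet(rng.standard_normal((10, 40)), sampling_rate=512.0)


@pytest.fixture
def nofilter_cfg():
    return PipelineConfig(filter_kind="none", baseline_window=None)


# ---------------------------------------------------------------- oracles


def brute_gabriel_edges(coords: np.ndarray) -> set:
    """O(n^3) Gabriel predicate straight from the empty-diametral-disk rule."""
    n = coords.shape[0]
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    edges = set()
    for p in range(n):
        for q in range(p + 1, n):
            blocked = False
            for k in range(n):
                if k in (p, q):
                    continue
                if d2[p, k] + d2[q, k] < d2[p, q] * (1 - RTOL):
                    blocked = True
                    break
            if not blocked:
                edges.add((p, q))
    return edges


def brute_rng_edges(coords: np.ndarray) -> set:
    """O(n^3) relative-neighborhood predicate from the empty-lune rule."""
    n = coords.shape[0]
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    edges = set()
    for p in range(n):
        for q in range(p + 1, n):
            blocked = False
            for k in range(n):
                if k in (p, q):
                    continue
                if max(d2[p, k], d2[q, k]) < d2[p, q] * (1 - RTOL):
                    blocked = True
                    break
            if not blocked:
                edges.add((p, q))
    return edges


def dcor_literal(x: np.ndarray, y: np.ndarray) -> float:
    """Literal double-centering distance-correlation formula (loops)."""
    n = len(x)
    a = np.abs(np.subtract.outer(x, x))
    b = np.abs(np.subtract.outer(y, y))

    def center(m):
        out = np.empty_like(m)
        row = m.mean(axis=1)
        col = m.mean(axis=0)
        tot = m.mean()
        for i in range(n):
            for j in range(n):
                out[i, j] = m[i, j] - row[i] - col[j] + tot
        return out

    A, B = center(a), center(b)
    dcov2 = (A * B).mean()
    dvarx = (A * A).mean()
    dvary = (B * B).mean()
    if dvarx <= 0 or dvary <= 0:
        return 0.0
    return float(np.sqrt(max(dcov2, 0.0) / np.sqrt(dvarx * dvary)))
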