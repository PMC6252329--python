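"""Zero-phase FIR/IIR band-pass filtering, DC removal and baseline correction.

Filters are applied forward-backward (``filtfilt``), which cancels phase
distortion and doubles the effective magnitude order; "order" throughout
refers to the design order before the forward-backward pass.  Epochs are
by default concatenated end-to-end, filtered once and re-split, which
suppresses per-epoch edge transients on short trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .core_io import TrialSet

__all__ = [
    "FilterSpec",
    "design_filter",
    "zero_phase_filter",
    "baseline_correct",
    "remove_dc",
    "FilterDesignError",
]


class FilterDesignError(ValueError):
    pass


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass filter specification.

    ``kind="fir"`` is a linear-phase windowed-sinc design whose tap count is
    ``order * 3 * round(fs / low_edge)`` (the common EEG convention in which
    "order" is a multiplier on a base length tied to the low cut-off);
    ``kind="iir"`` is a Butterworth band-pass of the given order.
    """

    kind: str
    order: int
    band: tuple[float, float]
    sampling_rate: float

    def __post_init__(self) -> None:
        kind = str(self.kind).lower()
        if kind not in ("fir", "iir"):
            raise FilterDesignError(f"unknown filter kind {self.kind!r}")
        object.__setattr__(self, "kind", kind)
        if self.order < 1:
            raise FilterDesignError("filter order must be >= 1")
        lo, hi = self.band
        nyq = self.sampling_rate / 2.0
        if not (0 < lo < hi < nyq):
            raise FilterDesignError(
                f"band {self.band} must satisfy 0 < low < high < Nyquist ({nyq} Hz)"
            )


def _fir_numtaps(spec: FilterSpec) -> int:
    n = spec.order * 3 * int(round(spec.sampling_rate / spec.band[0]))
    return n + 1 if n % 2 == 0 else n  # odd length -> symmetric type-I FIR


def design_filter(spec: FilterSpec) -> dict:
    """Design the filter; returns an opaque, reusable coefficient handle."""
    lo, hi = spec.band
    if spec.kind == "fir":
        numtaps = _fir_numtaps(spec)
        b = signal.firwin(
            numtaps, [lo, hi], pass_zero=False, fs=spec.sampling_rate
        )
        b = b - b.sum() / numtaps  # exact DC null (keeps tap symmetry)
        if not np.allclose(b, b[::-1]):
            raise FilterDesignError("FIR design lost tap symmetry")
        return {"kind": "fir", "b": b, "a": np.array([1.0]), "spec": spec}
    b, a = signal.butter(spec.order, [lo, hi], btype="bandpass", fs=spec.sampling_rate)
    if np.any(np.abs(np.roots(a)) >= 1.0):
        raise FilterDesignError("unstable IIR design (poles on/outside unit circle)")
    return {"kind": "iir", "b": b, "a": a, "spec": spec}


def _padlen(spec: FilterSpec, n: int) -> int:
    base = int(round(3 * max(1, spec.order) * spec.sampling_rate / spec.band[0]))
    return min(base, n - 1)


def _filtfilt(x: np.ndarray, coeffs: dict) -> np.ndarray:
    spec: FilterSpec = coeffs["spec"]
    pl = _padlen(spec, x.shape[-1])
    if coeffs["kind"] == "fir":
        if x.shape[-1] <= len(coeffs["b"]) // 2:
            raise FilterDesignError(
                f"signal of length {x.shape[-1]} too short for a "
                f"{len(coeffs['b'])}-tap FIR filter; concatenate trials or lower the order"
            )
        # forward-backward filtering with a symmetric FIR kernel is plain
        # convolution with the kernel's autocorrelation; FFT convolution is
        # orders of magnitude faster than lfilter for the long kernels the
        # tap-count convention produces
        b = coeffs["b"]
        kernel = signal.fftconvolve(b, b[::-1])
        padded = np.pad(x, pl, mode="reflect")
        out = signal.fftconvolve(padded, kernel, mode="same")
        return out[pl:-pl]
    return signal.filtfilt(coeffs["b"], coeffs["a"], x, padtype="even", padlen=pl)


def zero_phase_filter(
    ts: TrialSet, spec: FilterSpec, concatenate: bool = True
) -> TrialSet:
    """Forward-backward band-pass filter of every trial.

    With ``concatenate=True`` trials are joined end-to-end in acquisition
    order, filtered once and re-split, so the filter's startup transients
    fall only at the outer ends of the record.
    """
    if abs(spec.sampling_rate - ts.sampling_rate) > 1e-9:
        raise FilterDesignError("filter sampling rate does not match the trial set")
    coeffs = design_filter(spec)
    if concatenate:
        joined = ts.data.reshape(-1)
        filtered = _filtfilt(joined, coeffs)
        out = filtered.reshape(ts.data.shape)
    else:
        out = np.vstack([_filtfilt(row, coeffs) for row in ts.data])
    return ts.with_data(out)


def baseline_correct(ts: TrialSet, window: tuple[float, float]) -> TrialSet:
    """Subtract, per trial, the mean over the half-open time window [start, end)."""
    t = ts.times
    mask = (t >= window[0]) & (t < window[1])
    if not mask.any():
        raise ValueError(
            f"baseline window {window} does not intersect the epoch "
            f"[{t[0]:.4f}, {t[-1]:.4f}] s"
        )
    means = ts.data[:, mask].mean(axis=1, keepdims=True)
    return ts.with_data(ts.data - means)


def remove_dc(ts: TrialSet) -> TrialSet:
    """Subtract each trial's full-extent mean (zero-mean trials)."""
    return ts.with_data(ts.data - ts.data.mean(axis=1, keepdims=True))
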