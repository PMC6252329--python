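"""Peak amplitude/latency extraction, coefficient of variation, band power."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = ["PeakEstimate", "peak_estimate", "cv", "band_power", "DEFAULT_BANDS"]

# Seven canonical EEG bands within a 0.5-45 Hz band-pass (Hz).
DEFAULT_BANDS = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha1": (8.0, 10.0),
    "alpha2": (10.0, 13.0),
    "beta1": (13.0, 20.0),
    "beta2": (20.0, 30.0),
    "gamma": (30.0, 45.0),
}


@dataclass(frozen=True)
class PeakEstimate:
    """Global extremum of an averaged waveform within a search window."""

    amplitude: float
    latency: float  # seconds post-onset
    polarity: str
    window: tuple[float, float]


def peak_estimate(
    waveform,
    fs: float,
    onset_index: int = 0,
    window: tuple[float, float] = (0.0, 0.4),
    polarity: str = "negative",
) -> PeakEstimate:
    """Data-driven peak: the global extremum of the stated polarity.

    ``polarity="positive"`` takes the maximum, ``"negative"`` the minimum and
    ``"absolute"`` the sample of largest magnitude (signed amplitude
    returned).  Ties break toward the earliest latency.  The search window
    is half-open ``[start, end)`` in seconds relative to onset.
    """
    x = np.asarray(waveform, dtype=float).ravel()
    t = (np.arange(x.size) - onset_index) / fs
    mask = (t >= window[0]) & (t < window[1])
    if not mask.any():
        raise ValueError(f"window {window} outside the waveform extent")
    idx = np.flatnonzero(mask)
    seg = x[idx]
    if np.ptp(seg) == 0:
        warnings.warn("flat waveform in window: degenerate peak at earliest sample")
        best = 0
    elif polarity == "positive":
        best = int(np.argmax(seg))
    elif polarity == "negative":
        best = int(np.argmin(seg))
    elif polarity == "absolute":
        best = int(np.argmax(np.abs(seg)))
    else:
        raise ValueError(f"unknown polarity {polarity!r}")
    if best in (0, seg.size - 1) and np.ptp(seg) > 0:
        warnings.warn("extremum at a window edge; the window may clip the peak")
    i = idx[best]
    return PeakEstimate(
        amplitude=float(x[i]), latency=float(t[i]), polarity=polarity, window=window
    )


def cv(values, convention: str = "paper") -> float:
    """Coefficient of variation of a group of estimates.

    ``convention="paper"`` returns mean/std (the form the mining framework
    reports, the reciprocal of the textbook CV); ``"conventional"`` returns
    std/mean.  The std is the unbiased sample standard deviation.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size < 2:
        raise ValueError("need at least 2 values")
    m, s = v.mean(), v.std(ddof=1)
    if convention == "paper":
        num, den = m, s
    elif convention == "conventional":
        num, den = s, m
    else:
        raise ValueError(f"unknown convention {convention!r}")
    if den == 0:
        raise ZeroDivisionError("CV undefined: zero denominator")
    return float(num / den)


def band_power(waveform, fs: float, bands=None) -> dict:
    """Integrated periodogram power per frequency band.

    Bands are half-open ``[lo, hi)`` in Hz; a dict of band -> (lo, hi) or a
    list of (lo, hi) pairs is accepted.  Power is PSD x bin width summed
    over the band, so a full partition of (0, Nyquist] recovers the total
    signal power (Parseval).
    """
    x = np.asarray(waveform, dtype=float).ravel()
    if bands is None:
        bands = DEFAULT_BANDS
    items = bands.items() if isinstance(bands, dict) else list(enumerate(bands))
    nyq = fs / 2.0
    for _, (lo, hi) in items:
        if not (0 <= lo < hi <= nyq):
            raise ValueError(f"band ({lo}, {hi}) outside (0, Nyquist={nyq}]")
    f, pxx = signal.periodogram(x, fs=fs, window="boxcar", detrend=False)
    df = f[1] - f[0]
    out = {}
    items = bands.items() if isinstance(bands, dict) else list(enumerate(bands))
    for name, (lo, hi) in items:
        sel = (f >= lo) & (f < hi)
        if hi >= nyq:  # close the top band at Nyquist
            sel |= f == f[-1]
        out[name] = float(pxx[sel].sum() * df)
    return out
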