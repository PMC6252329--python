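"""Data model, file I/O and configuration shared by all pipeline stages.

Trial data are stored trial-major as delimited text (one epoch per row),
with a JSON sidecar carrying the sampling rate, stimulus-onset index and
labels.  Delimited text keeps fixtures diffable and language-agnostic.

Conventions used throughout the package:

* sample indices are 0-based;
* time 0 is the stimulus onset (``times[onset_index] == 0``);
* time windows are half-open ``[start, end)`` in seconds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

logger = logging.getLogger("ggmine")

__all__ = [
    "TrialSet",
    "PipelineConfig",
    "ResultRecord",
    "read_trialset",
    "write_trialset",
    "read_config",
    "TrialSetFormatError",
    "ConfigError",
]


class TrialSetFormatError(ValueError):
    """Raised when a trial matrix file violates the expected layout."""


class ConfigError(ValueError):
    """Raised when a pipeline configuration is invalid."""


@dataclass(frozen=True)
class TrialSet:
    """One condition's epochs: an ``n_trials x n_samples`` matrix plus timing.

    Parameters
    ----------
    data
        Real matrix, one trial (epoch) per row.
    sampling_rate
        Sampling rate in Hz.
    onset_index
        0-based sample index of the stimulus onset; ``times[onset_index] == 0``.
    condition, sensor, subject
        Free-form labels (e.g. ``"Dir-L/deviant"``, ``"FZ"``).
    """

    data: np.ndarray
    sampling_rate: float
    onset_index: int = 0
    condition: str = ""
    sensor: str = ""
    subject: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=float)
        if arr.ndim != 2:
            raise TrialSetFormatError("trial data must be a 2-D matrix")
        if arr.shape[0] < 2:
            raise TrialSetFormatError(
                f"need at least 2 trials, got {arr.shape[0]}"
            )
        if arr.shape[1] < 3:
            raise TrialSetFormatError(
                f"need at least 3 samples per trial, got {arr.shape[1]}"
            )
        if not np.all(np.isfinite(arr)):
            raise TrialSetFormatError("trial data contains non-finite values")
        if self.sampling_rate <= 0:
            raise TrialSetFormatError("sampling_rate must be positive")
        if not 0 <= self.onset_index < arr.shape[1]:
            raise TrialSetFormatError("onset_index outside the sample range")
        object.__setattr__(self, "data", arr)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Seconds per sample; 0 at the stimulus onset."""
        idx = np.arange(self.n_samples) - self.onset_index
        return idx / self.sampling_rate

    def with_data(self, data: np.ndarray) -> "TrialSet":
        """Copy of this set with the matrix replaced (metadata preserved)."""
        return dataclasses.replace(self, data=np.asarray(data, dtype=float))


# Defaults are the SNR-optimal settings of the mining pipeline: zero-phase
# FIR band-pass 0.5-45 Hz of design order 2 and hub degree threshold k = 4.
_DEFAULTS = {
    "filter_kind": "fir",
    "filter_order": 2,
    "band": (0.5, 45.0),
    "degree_k": 4,
    "baseline_window": None,
    "polarity": "negative",
    "post_stimulus_window": (0.0, 0.4),
    "concatenate": True,
    "snr_mode": "selected",
    "seed": 0,
}

_FILTER_KINDS = ("fir", "iir", "none")
_POLARITIES = ("positive", "negative", "absolute")
_SNR_MODES = ("selected", "all")


@dataclass(frozen=True)
class PipelineConfig:
    """Settings of the mining pipeline.

    ``filter_kind="none"`` skips band-pass filtering entirely (useful for
    already-filtered or synthetic band-limited data).  ``degree_k`` is the
    Gabriel-graph degree threshold used for hub selection.
    """

    filter_kind: str = _DEFAULTS["filter_kind"]
    filter_order: int = _DEFAULTS["filter_order"]
    band: tuple[float, float] = _DEFAULTS["band"]
    degree_k: int = _DEFAULTS["degree_k"]
    baseline_window: Optional[tuple[float, float]] = _DEFAULTS["baseline_window"]
    polarity: str = _DEFAULTS["polarity"]
    post_stimulus_window: tuple[float, float] = _DEFAULTS["post_stimulus_window"]
    concatenate: bool = _DEFAULTS["concatenate"]
    snr_mode: str = _DEFAULTS["snr_mode"]
    seed: int = _DEFAULTS["seed"]

    def __post_init__(self) -> None:
        kind = str(self.filter_kind).lower()
        if kind not in _FILTER_KINDS:
            raise ConfigError(
                f"unknown filter_kind {self.filter_kind!r}; expected one of {_FILTER_KINDS}"
            )
        object.__setattr__(self, "filter_kind", kind)
        if int(self.filter_order) < 1:
            raise ConfigError("filter_order must be >= 1")
        object.__setattr__(self, "filter_order", int(self.filter_order))
        lo, hi = (float(self.band[0]), float(self.band[1]))
        if not (0 < lo < hi):
            raise ConfigError(f"band must satisfy 0 < low < high, got {self.band}")
        object.__setattr__(self, "band", (lo, hi))
        if not 1 <= int(self.degree_k) <= 8:
            raise ConfigError("degree_k must lie in [1, 8]")
        object.__setattr__(self, "degree_k", int(self.degree_k))
        if self.baseline_window is not None:
            b0, b1 = map(float, self.baseline_window)
            if not b0 < b1:
                raise ConfigError("baseline_window start must precede end")
            object.__setattr__(self, "baseline_window", (b0, b1))
        if self.polarity not in _POLARITIES:
            raise ConfigError(f"polarity must be one of {_POLARITIES}")
        w0, w1 = map(float, self.post_stimulus_window)
        if not w0 < w1:
            raise ConfigError("post_stimulus_window start must precede end")
        object.__setattr__(self, "post_stimulus_window", (w0, w1))
        if self.snr_mode not in _SNR_MODES:
            raise ConfigError(f"snr_mode must be one of {_SNR_MODES}")
        object.__setattr__(self, "seed", int(self.seed))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["band"] = list(self.band)
        d["post_stimulus_window"] = list(self.post_stimulus_window)
        if self.baseline_window is not None:
            d["baseline_window"] = list(self.baseline_window)
        return d


@dataclass
class ResultRecord:
    """Outcome of a full mining run, with provenance for replay."""

    config: PipelineConfig
    selected: np.ndarray
    snr: float
    amplitude: float
    latency: float
    ge: float
    waveform: np.ndarray = field(repr=False, default=None)
    input_path: Optional[str] = None
    seed: int = 0
    version: str = "0.1.0"

    def __post_init__(self) -> None:
        sel = np.asarray(self.selected, dtype=int)
        if sel.size and (len(np.unique(sel)) != sel.size or sel.min() < 0):
            raise ValueError("selected trial indices must be unique and non-negative")
        self.selected = sel

    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "selected": self.selected.tolist(),
            "n_selected": int(self.selected.size),
            "snr": float(self.snr),
            "amplitude": float(self.amplitude),
            "latency": float(self.latency),
            "ge": float(self.ge),
            "waveform": None if self.waveform is None else list(map(float, self.waveform)),
            "input_path": self.input_path,
            "seed": int(self.seed),
            "version": self.version,
        }


def _sniff_delimiter(first_line: str) -> str:
    if "\t" in first_line:
        return "\t"
    if "," in first_line:
        return ","
    return None  # whitespace


def read_trialset(
    path,
    sampling_rate: Optional[float] = None,
    onset_index: Optional[int] = None,
    condition: str = "",
    sensor: str = "",
    subject: str = "",
) -> TrialSet:
    """Read a delimited trial matrix (one trial per row) plus its sidecar.

    Metadata given as arguments override values found in the ``.meta.json``
    sidecar written by :func:`write_trialset`.  The delimiter (comma, tab
    or whitespace) is auto-detected.
    """
    path = Path(path)
    meta = {}
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    with open(path) as fh:
        lines = [ln for ln in fh.read().splitlines() if ln.strip()]
    if not lines:
        raise TrialSetFormatError(f"{path}: empty file")
    delim = _sniff_delimiter(lines[0])
    rows = []
    width = None
    for r, ln in enumerate(lines):
        cells = ln.split(delim) if delim else ln.split()
        if width is None:
            width = len(cells)
        elif len(cells) != width:
            raise TrialSetFormatError(
                f"{path}: ragged rows — row {r} has {len(cells)} cells, expected {width}"
            )
        try:
            rows.append([float(c) for c in cells])
        except ValueError as exc:
            bad = next(i for i, c in enumerate(cells) if not _is_number(c))
            raise TrialSetFormatError(
                f"{path}: non-numeric cell at row {r}, column {bad}"
            ) from exc
    fs = sampling_rate if sampling_rate is not None else meta.get("sampling_rate")
    if fs is None:
        raise TrialSetFormatError(f"{path}: sampling_rate missing (no sidecar found)")
    onset = onset_index if onset_index is not None else meta.get("onset_index", 0)
    return TrialSet(
        data=np.array(rows, dtype=float),
        sampling_rate=float(fs),
        onset_index=int(onset),
        condition=condition or meta.get("condition", ""),
        sensor=sensor or meta.get("sensor", ""),
        subject=subject or meta.get("subject", ""),
    )


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def write_trialset(ts: TrialSet, path, delimiter: str = "\t") -> Path:
    """Write a trial set as delimited text plus a JSON metadata sidecar.

    Values are printed with 17 significant digits so a read-back round trip
    reproduces the matrix to double precision.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(path, ts.data, fmt="%.17g", delimiter=delimiter)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(
        json.dumps(
            {
                "sampling_rate": ts.sampling_rate,
                "onset_index": ts.onset_index,
                "condition": ts.condition,
                "sensor": ts.sensor,
                "subject": ts.subject,
                "n_trials": ts.n_trials,
                "n_samples": ts.n_samples,
            },
            indent=1,
        )
    )
    return path


def read_config(path) -> PipelineConfig:
    """Load a YAML/JSON key-value config file; absent keys take defaults."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a key/value document")
    unknown = set(raw) - set(_DEFAULTS)
    if unknown:
        raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
    merged = {**_DEFAULTS, **raw}
    if merged["band"] is not None:
        merged["band"] = tuple(merged["band"])
    if merged["baseline_window"] is not None:
        merged["baseline_window"] = tuple(merged["baseline_window"])
    merged["post_stimulus_window"] = tuple(merged["post_stimulus_window"])
    return PipelineConfig(**merged)


def file_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
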