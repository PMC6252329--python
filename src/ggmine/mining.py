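"""End-to-end single-trial mining: filter → DM → MDS → GG → hubs → average.

The chain is fully deterministic — no stage draws random numbers — so a
fixed input always yields the same selection and waveform.  SNR of a
selection is the power of the selected-trial average over the mean residual
power of the selected trials; the 24-cell settings optimizer scores each
(filter kind × order × degree k) combination by how often it attains the
per-cell maximum SNR.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import PipelineConfig, ResultRecord, TrialSet
from .embedding import mds_embed, similarity_matrix
from .estimation import peak_estimate
from .graphs import (
    EmptySelectionError,
    HubSelection,
    gabriel_graph,
    hub_variability_ge,
    select_hubs,
)
from .preprocess import FilterSpec, baseline_correct, zero_phase_filter

logger = logging.getLogger("ggmine")

__all__ = [
    "EvokedEstimate",
    "OptimizationResult",
    "preprocess_trials",
    "select_trials",
    "grand_average",
    "snr",
    "mine",
    "optimize_settings",
    "subsampling_curve",
]

SNR_CAP = 1e12


@dataclass(frozen=True)
class EvokedEstimate:
    """Averaged waveform of the selected trials with its SNR."""

    waveform: np.ndarray
    n_selected: int
    snr: float
    config: PipelineConfig


@dataclass(frozen=True)
class OptimizationResult:
    """SNR grid over the 24 settings combinations and the winning combo."""

    grid: pd.DataFrame  # columns: filter_kind, order, k, cell, snr
    winner: tuple  # (filter_kind, order, k)
    score: float  # percentage of cells where the winner attains the max
    scores: pd.DataFrame  # per-combo attainment percentage


def preprocess_trials(ts: TrialSet, cfg: PipelineConfig) -> TrialSet:
    """Apply the configured zero-phase band-pass and baseline correction."""
    out = ts
    if cfg.filter_kind != "none":
        spec = FilterSpec(cfg.filter_kind, cfg.filter_order, cfg.band, ts.sampling_rate)
        out = zero_phase_filter(out, spec, concatenate=cfg.concatenate)
    if cfg.baseline_window is not None:
        out = baseline_correct(out, cfg.baseline_window)
    return out


def select_trials(ts: TrialSet, cfg: PipelineConfig) -> HubSelection:
    """Representative-trial selection by Gabriel-graph hubness.

    Composition: zero-phase filter → baseline correction → distance-
    correlation DM → classical MDS to the plane → Gabriel graph → nodes of
    degree >= k.  Deterministic for fixed input.
    """
    pre = preprocess_trials(ts, cfg)
    dm = similarity_matrix(pre)
    points = mds_embed(dm)
    gg = gabriel_graph(points)
    return select_hubs(gg, cfg.degree_k)


def grand_average(ts: TrialSet, sel: HubSelection) -> EvokedEstimate:
    """Sample-wise arithmetic mean over the selected trials."""
    if sel.n_selected == 0:
        raise EmptySelectionError("cannot average an empty selection")
    wave = ts.data[sel.selected].mean(axis=0)
    value = snr(ts, sel) if sel.n_selected >= 2 else float("nan")
    return EvokedEstimate(
        waveform=wave, n_selected=sel.n_selected, snr=value, config=None
    )


def snr(ts: TrialSet, sel: HubSelection) -> float:
    """SNR of a selection: average power over mean residual power.

    P_signal is the mean squared value of the selected-trial average;
    P_noise the mean (over selected trials) of the mean squared residual
    (trial − average).  Identical trials give zero residual; the ratio is
    then capped at 1e12 with a warning.
    """
    if sel.n_selected < 2:
        raise ValueError("SNR undefined for fewer than 2 selected trials")
    X = ts.data[sel.selected]
    avg = X.mean(axis=0)
    p_signal = float(np.mean(avg**2))
    p_noise = float(np.mean((X - avg) ** 2))
    if p_noise == 0:
        warnings.warn("zero residual power: SNR capped")
        return SNR_CAP
    return min(p_signal / p_noise, SNR_CAP)


def all_trial_selection(ts: TrialSet) -> HubSelection:
    """The trivial selection of every trial (the plain grand average)."""
    return HubSelection(k=0, selected=np.arange(ts.n_trials),
                        degree_table=np.zeros(ts.n_trials, dtype=int))


def mine(ts: TrialSet, cfg: PipelineConfig, input_path=None) -> ResultRecord:
    """Run the whole pipeline and report selection, SNR, peak and GE."""
    pre = preprocess_trials(ts, cfg)
    dm = similarity_matrix(pre)
    points = mds_embed(dm)
    gg = gabriel_graph(points)
    sel = select_hubs(gg, cfg.degree_k)
    if cfg.snr_mode == "selected":
        snr_sel = snr(pre, sel) if sel.n_selected >= 2 else float("nan")
    else:
        snr_sel = snr_vs_average(pre, sel)
    est = pre.data[sel.selected].mean(axis=0)
    peak = peak_estimate(
        est, pre.sampling_rate, pre.onset_index,
        cfg.post_stimulus_window, cfg.polarity,
    )
    ge = hub_variability_ge(points, sel) if sel.n_selected >= 2 else float("nan")
    return ResultRecord(
        config=cfg,
        selected=sel.selected,
        snr=snr_sel,
        amplitude=peak.amplitude,
        latency=peak.latency,
        ge=ge,
        waveform=est,
        input_path=str(input_path) if input_path else None,
        seed=cfg.seed,
    )


def snr_vs_average(ts: TrialSet, sel: HubSelection) -> float:
    """Variant: all trials scored against the selected-trial average."""
    avg = ts.data[sel.selected].mean(axis=0)
    p_signal = float(np.mean(avg**2))
    p_noise = float(np.mean((ts.data - avg) ** 2))
    if p_noise == 0:
        warnings.warn("zero residual power: SNR capped")
        return SNR_CAP
    return min(p_signal / p_noise, SNR_CAP)


# ties favor FIR over IIR, lower order, higher k (stable reruns)
_COMBOS = [
    (fk, order, k)
    for fk in ("fir", "iir")
    for order in (1, 2, 3)
    for k in (1, 2, 3, 4)
]


def _combo_rank(combo) -> tuple:
    fk, order, k = combo
    return (0 if fk == "fir" else 1, order, -k)


def optimize_settings(collection: dict, base_cfg: PipelineConfig = None) -> OptimizationResult:
    """Score all 24 (filter kind × order × degree k) settings over cells.

    ``collection`` maps a (stimulus, sensor) cell label to its TrialSet.
    Each combo's score is the percentage of cells where it attains the
    cell's maximum SNR; the winner is the top-scoring combo with ties broken
    toward FIR, lower order, higher k.  Cells failing under every combo are
    excluded with a warning.
    """
    if not collection:
        raise ValueError("empty cell collection")
    base_cfg = base_cfg or PipelineConfig()
    rows = []
    for cell, ts in collection.items():
        any_ok = False
        for fk, order, k in _COMBOS:
            cfg = PipelineConfig(
                **{**base_cfg.to_dict(), "filter_kind": fk,
                   "filter_order": order, "degree_k": k}
            )
            try:
                sel = select_trials(ts, cfg)
                value = snr(preprocess_trials(ts, cfg), sel)
                any_ok = True
            except (EmptySelectionError, ValueError) as exc:
                logger.info("cell %s combo %s failed: %s", cell, (fk, order, k), exc)
                value = np.nan
            rows.append({"filter_kind": fk, "order": order, "k": k,
                         "cell": cell, "snr": value})
        if not any_ok:
            warnings.warn(f"cell {cell!r} failed under every combo; excluded")
            rows = [r for r in rows if r["cell"] != cell]
    grid = pd.DataFrame(rows)
    if grid.empty:
        raise ValueError("every cell failed under every combo")
    cells = grid["cell"].unique()
    n_cells = len(cells)
    wins = {c: 0 for c in _COMBOS}
    for cell in cells:
        sub = grid[grid["cell"] == cell]
        best = sub["snr"].max()
        for _, r in sub.iterrows():
            if np.isfinite(r["snr"]) and r["snr"] == best:
                wins[(r["filter_kind"], r["order"], r["k"])] += 1
    scores = pd.DataFrame(
        [{"filter_kind": fk, "order": o, "k": k,
          "score": 100.0 * w / n_cells}
         for (fk, o, k), w in wins.items()]
    )
    top = scores["score"].max()
    tied = [c for c in _COMBOS if 100.0 * wins[c] / n_cells == top]
    winner = min(tied, key=_combo_rank)
    if len(tied) > 1:
        logger.info("optimizer tie among %s; chose %s", tied, winner)
    return OptimizationResult(grid=grid, winner=winner, score=float(top), scores=scores)


def subsampling_curve(
    ts: TrialSet,
    cfg: PipelineConfig,
    fractions=None,
) -> pd.DataFrame:
    """Reliability curve: rerun the pipeline on the first ⌈f·n⌉ trials.

    Fractions default to 20%..100% in 5% steps (17 rows).  Truncation is in
    acquisition order (the leading trials), not random subsets.  Fractions
    yielding fewer than 4 trials are skipped with a note.
    """
    if fractions is None:
        fractions = np.round(np.arange(0.20, 1.0001, 0.05), 2)
    rows = []
    for f in fractions:
        n = int(np.ceil(f * ts.n_trials))
        if n < 4:
            logger.info("fraction %.2f yields %d < 4 trials; skipped", f, n)
            continue
        sub = ts.with_data(ts.data[:n])
        try:
            rec = mine(sub, cfg)
        except EmptySelectionError as exc:
            logger.info("fraction %.2f failed: %s", f, exc)
            continue
        rows.append({"fraction": float(f), "n_trials": n,
                     "n_selected": int(rec.selected.size),
                     "amplitude": rec.amplitude, "latency": rec.latency,
                     "snr": rec.snr})
    return pd.DataFrame(rows)
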