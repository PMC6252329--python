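# Methods

This note records the modeling choices, conventions and numerical details
behind `ggmine`, and what its synthetic validation does and does not show.

## Pipeline model and assumptions

The miner treats each epoch as a point in a similarity space and assumes
that trials carrying the stimulus-locked response form the *dense core* of
that space, while artifacts and outlier brain states sit at its periphery.
Three ingredients encode that assumption:

* **Distance correlation** as the pairwise dependence measure.  dCor is
  zero (in population) only under independence and is invariant to shifts
  and rescalings of either series, so amplitude-scaled copies of the same
  waveform are maximally similar.  The sample estimator is the biased
  V-statistic (double-centered absolute-difference matrices; dCor² is the
  normalized inner product).  A constant trial has zero distance variance;
  the estimator is 0/0 there and is defined as dCor = 0 (distance 1) with
  a warning, since constant epochs are degenerate artifacts.  The distance
  is DM = 1 − dCor, which maps the similarity in [0, 1] onto a distance in
  [0, 1]; this conversion is a design choice of the package and shapes
  everything downstream.
* **Classical MDS** (Torgerson scaling) rather than an iterative
  stress-minimizing variant: double-center −½ D², take the two leading
  non-negative eigenpairs, scale eigenvectors by √eigenvalue.  It is
  deterministic and reproducible; axis signs are fixed by flipping each
  axis so its largest-magnitude coordinate is positive (ties toward the
  lower point index).  If fewer than two positive eigenvalues exist the
  missing axis is a zero column (with a warning).
* **Gabriel-graph hubness** as the representativeness criterion.  The GG
  predicate d²(p,q) < d²(p,k) + d²(q,k) (empty open diametral disk) is
  evaluated with a relative tolerance of 1e-9 on squared distances;
  points exactly on the boundary circle do **not** block an edge, which
  keeps right-angle configurations stable under floating-point noise.
  Exact duplicate points (identical trials) are collapsed to one node
  before construction — the predicate is undefined on coincident points —
  and every duplicate inherits its representative's hub status afterward.
  GG is computed by filtering Delaunay candidate edges (valid because
  GG ⊆ DT), an O(|DT|·n) scan instead of O(n³); the brute-force predicate
  is kept in the test suite as an independent oracle.  All-collinear point
  sets, where the Delaunay triangulation is undefined, fall back to
  brute-force candidates (and the DT accessor falls back to a path graph).

The chain filter → baseline → DM → MDS → GG → hubs → average contains no
randomness: a fixed input always produces the same selection.

## Filtering

"Order" always means the design order before the forward–backward pass
(which cancels phase and squares the magnitude response).  The FIR design
is a windowed-sinc linear-phase band-pass with tap count
`order × 3 × round(fs / low_edge)` (+1 to keep symmetry), mirroring the
common EEG convention in which the grid label "order" is a multiplier on a
base length tied to the low cut-off.  Two numerical details:

* the mean tap is subtracted after design, which places an exact null at
  DC; a constant input is then annihilated to machine precision rather
  than to the window's sidelobe level (~5e-6 after squaring);
* forward–backward application of a symmetric FIR kernel equals a single
  convolution with the kernel's autocorrelation, implemented with FFT
  convolution after reflection padding of length
  `3 × max(1, order) × fs / low_edge` (capped at signal length − 1).  This
  is mathematically identical to `filtfilt` (verified to 1e-15) and two
  to three orders of magnitude faster for the multi-thousand-tap kernels
  the convention produces.

The IIR path is a Butterworth band-pass through `scipy.signal.filtfilt`
with the same padding rule.  Trials are by default concatenated
end-to-end, filtered once and re-split, so startup transients fall only at
the outer ends of the record; per-trial filtering is available but rejects
epochs shorter than half the FIR kernel.

Because the paradigm's epochs contain no pre-stimulus segment, the default
baseline window, when baseline correction is requested, is the first 25 ms
of the epoch (the least stimulus-driven samples); the window is a config
knob, half-open `[start, end)` in seconds, 0 at stimulus onset.

## SNR, peaks, variability, reliability

* **SNR** of a selection: P_signal = mean square of the selected-trial
  average; P_noise = mean over selected trials of the mean squared
  residual (trial − average); the ratio is capped at 1e12 when the
  residual is exactly zero.  A variant scoring *all* trials against the
  selected-trial average is available (`snr_mode="all"`); the default is
  selected-only.
* **Peak**: global extremum of the requested polarity in a half-open
  search window, ties toward the earliest latency.  Polarity is a required
  user choice (MMN difference waves are negative; standards positive), not
  inferred from the data.
* **Variability (GE)**: pairwise Euclidean distances among hub
  coordinates, normalized by the maximum (ŵ = d/d_max) and inverted into
  functional weights w = 1 − ŵ; each pair with w > 0 gets an edge of
  length 1/w, the d_max pair(s) get no direct edge, and GE is computed
  over shortest paths.  This inversion keeps GE in [0, 1] (the literal
  reciprocal of normalized distance would force GE ≥ 1) and makes GE
  scale-invariant; two hubs give GE = 0 by construction and coincident
  hubs define GE = 1.
* **Reliability (CV)**: reported, following the framework the package
  implements, as group mean / group std ("paper" convention, the
  reciprocal of the textbook CV, giving values of order 2–10 for typical
  amplitude/latency tables); the conventional std/mean form is selectable,
  and the two are exact reciprocals.
* **Band power**: integrated one-sided periodogram (boxcar window, no
  detrending) over seven default bands — delta 0.5–4, theta 4–8, alpha1
  8–10, alpha2 10–13, beta1 13–20, beta2 20–30, gamma 30–45 Hz — chosen to
  tile the default filter passband; a full partition of (0, Nyquist]
  recovers total power (Parseval).

The 24-cell settings optimizer scores each (filter kind × order ∈ {1,2,3}
× k ∈ {1,2,3,4}) combination by the percentage of (stimulus, sensor) cells
in which it attains the cell's maximum SNR; ties break toward FIR, lower
order, higher k so reruns are stable.  The subsampling reliability curve
truncates to the *first* ⌈f·n⌉ trials (acquisition order, not random
subsets) for f = 20%…100% in 5% steps (17 rows).

## Synthetic-data generator

Each simulated dataset emulates one subject's MMN epochs: 128 trials × 205
samples at 512 Hz (400 ms post-onset, no pre-stimulus segment).  A trial is
`a·template(t − δ) + noise`:

* **Template**: a negative Gaussian deflection, center 150 ms, FWHM 60 ms,
  unit depth — a parametric stand-in for an empirical MMN difference
  waveform, so the generator is self-contained; any user waveform can be
  substituted.
* **Amplitude** a: lognormal with natural-scale mean 1 and sd 1.2
  (back-solved to log-scale parameters), truncated to (0.2, 5.0) by
  rejection — the truncation bounds stand in for the range observed in
  real data.
* **Latency** δ: zero-mean Gaussian, default sd 150 ms from the exposed
  grid {150, 160, 170} ms, with draws clipped so the shifted peak center
  stays at least half a FWHM inside the epoch; a configuration whose clip
  range is empty is rejected.
* **Noise**: a stationary AR(5) process (default coefficients from poles
  at 0.97 and complex pairs near 10 Hz and 25 Hz, giving a 1/f-like
  spectrum with a weak alpha resonance, qualitatively matching baseline
  EEG); coefficients can instead be fitted to any background series by
  Yule-Walker, with non-stationary fits shrunk toward white.  Noise is
  scaled so the realized SNR — template mean-square over noise variance —
  matches the target (0.5, 1 or 2; ∞ yields noise-free data).  AR order
  selection by AIC uses AIC(p) = n·ln(σ̂²_p) + 2p with Yule-Walker
  innovation variances on the full series, so candidate orders are scored
  on a common sample.
* **Scenarios**: "common" draws one (a, δ) per dataset (all trials share
  the same peak); "independent" draws per trial.

Everything is reproducible from the config seed.

**What the simulator does not emulate**: multichannel spatially correlated
noise (single-sensor design), habituation or drift across the session,
non-Gaussian artifacts (blinks, muscle), and reference-scheme effects.
Passing recovery tests therefore demonstrates the pipeline's behavior
under amplitude/latency jitter in stationary autoregressive noise, not
robustness to real-world artifacts.

## Recovery experiment and known limitations

The recovery experiment generates datasets per (SNR × scenario) cell, runs
the pipeline (by default without the band-pass — the synthetic trials are
band-limited by construction and the noise-free limit should be exact),
and compares the hub-average peak against the dataset's ground-truth mean
amplitude and latency.  Scaled-down runs use 5 datasets per cell to stay
desk-sized; the methods-level findings:

* In the common scenario and the noise-free limit, recovery is exact up to
  the sample grid (latency error 0 samples, amplitude relative error
  < 1e-6 when the peak is grid-aligned).
* At the default 150 ms latency jitter the *independent* scenario's
  amplitude error is dominated by an irreducible smearing bias: averaging
  templates whose latencies are spread across most of the epoch flattens
  the peak regardless of noise level, so the error does not shrink as SNR
  grows — additive noise can even push the smeared peak *toward* the true
  depth.  Median errors across a handful of datasets are additionally
  quantized (latencies live on a 1.95 ms grid) and noisy; monotone
  error-vs-SNR orderings should only be expected when jitter is small
  relative to the template width and the per-cell dataset count is large.
* Hub selection at k = 4 typically retains ≈ half of 128 embedded trials
  (a planar GG has mean degree ≈ 4); its median SNR advantage over the
  all-trial average on synthetic data is real but small, because the
  synthetic trials — unlike typical empirical epochs — contain no outlier
  artifact trials for the selection to discard.

## Degenerate inputs and tie-breaks (summary)

Identical trials → zero distance matrix → all points at the origin → one
collapsed node → every trial selected.  Empty hub set at threshold k →
error suggesting k − 1.  Flat waveform in a peak window → warning, earliest
sample returned.  Disconnected node pairs contribute 0 to GE (1/∞
convention).  Peak ties → earliest latency.  Optimizer ties → FIR, lower
order, higher k.  MDS axis signs → largest-magnitude coordinate positive.
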