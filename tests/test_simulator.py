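import numpy as np
import pytest
from scipy import signal

from ggmine import (
    SimulationConfig,
    default_template,
    fit_ar_noise,
    generate_trials,
    select_order_aic,
)
from ggmine.simulator import DEFAULT_AR_COEFFS, _draw_amplitudes, _shift_bounds


def ar_series(coeffs, n, seed=0):
    r = np.random.default_rng(seed)
    e = r.standard_normal(n + 1000)
    return signal.lfilter([1.0], np.r_[1.0, -np.asarray(coeffs)], e)[1000:]


class TestARFit:
    def test_white_noise_coefficients_near_zero(self):
        x = np.random.default_rng(1).standard_normal(10_000)
        coeffs, _ = fit_ar_noise(x, order=5)
        assert np.max(np.abs(coeffs)) < 0.05

    def test_recovers_known_coefficients(self):
        true = np.array([0.5, -0.2, 0.1, 0.05, -0.05])
        x = ar_series(true, 50_000, seed=2)
        coeffs, _ = fit_ar_noise(x, order=5)
        assert np.max(np.abs(coeffs - true)) < 0.02

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            fit_ar_noise(np.ones(1000))

    def test_default_noise_process_is_stationary(self):
        roots = np.roots(np.r_[1.0, -np.asarray(DEFAULT_AR_COEFFS)])
        assert np.all(np.abs(roots) < 1.0)


class TestOrderSelection:
    def test_ar2_data_selects_low_order(self):
        hits = 0
        for seed in range(10):
            x = ar_series([0.6, -0.3], 20_000, seed=seed)
            if select_order_aic(x, 10) in (2, 3):
                hits += 1
        assert hits >= 8

    def test_max_order_one_returns_one(self):
        x = np.random.default_rng(0).standard_normal(1000)
        assert select_order_aic(x, 1) == 1


class TestGenerate:
    def test_same_seed_bitwise_identical(self):
        a, _ = generate_trials(SimulationConfig(seed=9))
        b, _ = generate_trials(SimulationConfig(seed=9))
        np.testing.assert_array_equal(a.data, b.data)

    def test_dimensions_and_metadata(self):
        ts, truth = generate_trials(SimulationConfig(seed=1))
        assert ts.data.shape == (128, 205)
        assert ts.sampling_rate == 512.0
        assert truth.amplitudes.shape == (128,)
        assert truth.latency_shifts.shape == (128,)

    @pytest.mark.parametrize("target", [0.5, 1.0, 2.0])
    def test_realized_snr_hits_target(self, target):
        _, truth = generate_trials(SimulationConfig(seed=4, snr_target=target))
        assert truth.realized_snr == pytest.approx(target, rel=0.10)

    def test_noise_variance_ratios_across_snr_levels(self):
        variances = {}
        for target in (0.5, 1.0, 2.0):
            cfg = SimulationConfig(seed=6, snr_target=target, latency_sd=0.0)
            ts, truth = generate_trials(cfg)
            clean = truth.amplitudes[:, None] * truth.template
            variances[target] = np.var(ts.data - clean)
        assert variances[0.5] / variances[2.0] == pytest.approx(4.0, rel=0.10)
        assert variances[0.5] / variances[1.0] == pytest.approx(2.0, rel=0.10)

    def test_amplitude_law_truncated_lognormal(self):
        r = np.random.default_rng(0)
        cfg = SimulationConfig()
        a = _draw_amplitudes(r, cfg, 20_000)
        assert a.min() > 0.2 and a.max() < 5.0
        # natural-scale mean of the untruncated law is 1; truncation biases it only mildly
        assert np.mean(a) == pytest.approx(1.0, abs=0.15)

    def test_common_scenario_shares_draws(self):
        _, truth = generate_trials(SimulationConfig(seed=2, scenario="common"))
        assert np.ptp(truth.amplitudes) == 0
        assert np.ptp(truth.latency_shifts) == 0

    def test_shifts_respect_epoch_bounds(self):
        cfg = SimulationConfig(seed=8, latency_sd=0.5)
        _, truth = generate_trials(cfg)
        lo, hi = _shift_bounds(cfg)
        assert truth.latency_shifts.min() >= lo
        assert truth.latency_shifts.max() <= hi

    def test_averaging_recovers_template_at_high_snr(self):
        cfg = SimulationConfig(seed=3, snr_target=2.0, latency_sd=0.0, scenario="independent")
        ts, truth = generate_trials(cfg)
        avg = ts.data.mean(axis=0)
        corr = np.corrcoef(avg, truth.template)[0, 1]
        assert corr > 0.95

    def test_impossible_shift_config_rejected(self):
        with pytest.raises(ValueError, match="shift"):
            _shift_bounds(SimulationConfig(n_samples=30, sampling_rate=512.0))


def test_template_shape():
    tpl = default_template()
    t = np.arange(205) / 512.0
    assert tpl.min() == pytest.approx(-1.0, abs=1e-3)  # peak center off the sample grid
    assert t[np.argmin(tpl)] == pytest.approx(0.150, abs=1 / 512.0)
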