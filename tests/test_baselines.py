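import numpy as np
import pytest

from ggmine import (
    TrialSet,
    default_template,
    mlr_baseline,
    mlrd_baseline,
    pca_baseline,
    svd_baseline,
    variability_matrix,
)

FS = 512.0


def rank1_trials(rng, n=20, n_samples=205, spread=0.5):
    tpl = default_template(n_samples, FS)
    a = 1.0 + spread * rng.uniform(size=n)
    return TrialSet(a[:, None] * tpl, FS), tpl, a


def cosine(u, v):
    return np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))


class TestPCA:
    def test_rank1_single_component_exact(self, rng):
        ts, tpl, _ = rank1_trials(rng)
        wave, n_comp, info = pca_baseline(ts)
        assert n_comp == 1
        recon_err = np.max(np.abs(wave - ts.data.mean(axis=0)))
        assert recon_err < 1e-9
        assert abs(cosine(wave, tpl)) > 0.999

    def test_threshold_one_reconstructs_input_mean(self, rng):
        ts = TrialSet(rng.standard_normal((10, 50)), FS)
        wave, n_comp, _ = pca_baseline(ts, variance_threshold=1.0)
        np.testing.assert_allclose(wave, ts.data.mean(axis=0), atol=1e-9)

    def test_explained_variance_sums_to_one(self, rng):
        ts = TrialSet(rng.standard_normal((12, 40)), FS)
        _, _, info = pca_baseline(ts)
        assert np.sum(info["explained_variance_ratio"]) == pytest.approx(1.0, abs=1e-9)

    def test_bad_threshold_rejected(self, rng):
        ts = TrialSet(rng.standard_normal((5, 10)), FS)
        with pytest.raises(ValueError):
            pca_baseline(ts, variance_threshold=1.5)


class TestSVD:
    def test_rank1_first_component_is_template(self, rng):
        ts, tpl, _ = rank1_trials(rng)
        series = svd_baseline(ts, [1])
        assert abs(cosine(series, tpl)) > 0.999

    def test_component_beyond_rank_rejected(self, rng):
        tpl = default_template(60, FS)
        base = np.vstack([tpl, np.roll(tpl, 5), np.roll(tpl, -5)])
        data = np.repeat(base, 4, axis=0)  # rank 3
        with pytest.raises(ValueError, match="rank"):
            svd_baseline(TrialSet(data, FS), [4, 5])

    def test_multiple_components_are_averaged(self, rng):
        ts = TrialSet(rng.standard_normal((8, 30)), FS)
        combined = svd_baseline(ts, [1, 2])
        single = np.vstack([svd_baseline(ts, [c]) for c in (1, 2)])
        np.testing.assert_allclose(combined, single.mean(axis=0), atol=1e-12)


class TestMLR:
    def test_recovers_scales_on_rank1_data(self, rng):
        ts, tpl, a = rank1_trials(rng)
        wave, coef = mlr_baseline(ts, interval=(0.0, 0.3))
        # first regressor is the mean ERP = mean(a) * template
        recovered = coef[0] * np.mean(a)
        np.testing.assert_allclose(recovered, a, atol=1e-9)
        t = np.arange(205) / FS
        mask = (t >= 0) & (t < 0.3)
        np.testing.assert_allclose(wave[mask], np.mean(a) * tpl[mask], atol=1e-9)

    def test_orthogonal_noise_projected_out(self, rng):
        tpl = default_template(205, FS)
        t = np.arange(205) / FS
        mask = (t >= 0) & (t < 0.3)
        design = np.column_stack([tpl[mask], np.gradient(tpl[mask])])
        q, _ = np.linalg.qr(design)
        noise = rng.standard_normal((15, mask.sum()))
        noise -= noise @ q @ q.T  # orthogonal to the regressor span
        noise -= noise.mean(axis=0)  # keep the average ERP (regressor source) exact
        data = np.tile(tpl, (15, 1))
        data[:, mask] += noise
        wave, _ = mlr_baseline(TrialSet(data, FS), interval=(0.0, 0.3))
        np.testing.assert_allclose(wave[mask], tpl[mask], atol=1e-6)

    def test_interval_outside_epoch_rejected(self, rng):
        ts = TrialSet(rng.standard_normal((5, 205)), FS)
        with pytest.raises(ValueError, match="interval"):
            mlr_baseline(ts, interval=(0.0, 1.0))


class TestMLRd:
    def test_variability_matrix_row_count(self):
        avg = default_template(205, FS)
        vm = variability_matrix(avg, FS, shift_grid=[-0.01, 0.0, 0.01],
                                compress_grid=[0.9, 1.0])
        assert vm.shape == (6, 205)

    def test_recovers_mean_shift_of_jittered_templates(self, rng):
        tpl = default_template(205, FS)
        t = np.arange(205) / FS
        shifts = np.array([-0.02, -0.01, 0.0, 0.01, 0.02] * 4)
        sigma = 0.060 / (2 * np.sqrt(2 * np.log(2)))
        data = -np.exp(-((t[None] - 0.15 - shifts[:, None]) ** 2) / (2 * sigma**2))
        wave, _ = mlrd_baseline(TrialSet(data, FS), interval=(0.0, 0.4))
        lat = t[np.argmin(wave)]
        assert lat == pytest.approx(0.15 + shifts.mean(), abs=2 / FS)

    def test_identity_grids_rank_deficient(self, rng):
        ts, _, _ = rank1_trials(rng)
        with pytest.raises(np.linalg.LinAlgError, match="rank"):
            mlrd_baseline(ts, shift_grid=[0.0], compress_grid=[1.0])
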