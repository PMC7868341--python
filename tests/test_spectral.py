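import numpy as np
import pytest
from scipy import stats

from phasestim import EEGRecording, band_energy_curve, band_erd, car_reference, ersp
from phasestim.spectral import ALPHA_BAND, BETA_BAND

FS = 1000.0


def alpha_trials(n_trials, seed, task_gain=1.0, noise=0.02, n_samples=11000,
                 env=None):
    """Alpha epochs whose envelope is ``task_gain`` during 5-9 s."""
    rng = np.random.default_rng(seed)
    t = np.arange(n_samples) / FS
    trials = []
    for _ in range(n_trials):
        e = np.ones(n_samples)
        if env is not None:
            e = env.copy()
        else:
            e[5000:9000] = task_gain
        x = e * np.sin(2 * np.pi * 10 * t + rng.uniform(-np.pi, np.pi))
        trials.append(x + noise * rng.standard_normal(n_samples))
    return np.array(trials)


class TestERSP:
    def test_stationary_noise_near_zero(self):
        rng = np.random.default_rng(0)
        emap = ersp(rng.standard_normal((50, 11000)), FS)
        assert abs(band_erd(emap, ALPHA_BAND, (5.0, 9.0))) < 1.0
        assert abs(band_erd(emap, BETA_BAND, (5.0, 9.0))) < 1.0

    def test_amplitude_halving_gives_minus_6db(self):
        emap = ersp(alpha_trials(40, seed=1, task_gain=0.5), FS)
        val = band_erd(emap, (9.5, 10.5), (5.5, 8.5))
        assert val == pytest.approx(10 * np.log10(0.25), abs=1.0)

    def test_single_trial_degenerate_average(self):
        trials = alpha_trials(1, seed=2)
        a = ersp(trials, FS)
        b = ersp(np.vstack([trials, trials]), FS)
        np.testing.assert_allclose(a.values, b.values, atol=1e-10)

    def test_baseline_rows_zero_mean(self):
        emap = ersp(alpha_trials(5, seed=3), FS)
        cols = (emap.times >= 3.0) & (emap.times <= 4.0)
        base = emap.values[:, cols].mean(axis=1)
        assert np.abs(base).max() < 1e-6

    def test_linearity_in_linear_power(self):
        # concatenating trial sets averages their linear-power maps
        t1 = alpha_trials(4, seed=4)
        t2 = alpha_trials(6, seed=5)
        p1 = 10 ** (ersp(t1, FS, baseline=None).values / 10)
        p2 = 10 ** (ersp(t2, FS, baseline=None).values / 10)
        p12 = 10 ** (ersp(np.vstack([t1, t2]), FS, baseline=None).values / 10)
        np.testing.assert_allclose(p12, (4 * p1 + 6 * p2) / 10, rtol=1e-8)

    def test_frequency_gain_invariance(self):
        # a per-frequency gain (smooth relative to the 200 ms window's
        # bandwidth, so rows scale deterministically) cancels in the baseline
        # normalization
        rng = np.random.default_rng(6)
        trials = rng.standard_normal((8, 11000))
        spec = np.fft.rfft(trials, axis=1)
        f = np.fft.rfftfreq(trials.shape[1], 1 / FS)
        gained = np.fft.irfft(spec * (1.0 + 0.5 * np.exp(-((f - 30) / 40) ** 2)),
                              n=trials.shape[1], axis=1)
        a = ersp(trials, FS)
        b = ersp(gained, FS)
        interior = (a.times > 0.5) & (a.times < 10.5)
        np.testing.assert_allclose(
            a.values[:, interior], b.values[:, interior], atol=0.3
        )

    def test_short_epoch_raises(self):
        with pytest.raises(ValueError):
            ersp(np.zeros((2, 50)), FS)


class TestBandERD:
    def make_map(self, fill):
        emap = ersp(alpha_trials(2, seed=7), FS)
        emap.values = np.full_like(emap.values, fill)
        return emap

    def test_zero_map(self):
        assert band_erd(self.make_map(0.0), ALPHA_BAND, (5, 9)) == 0.0

    def test_uniform_map(self):
        assert band_erd(self.make_map(-3.0), ALPHA_BAND, (5, 9)) == -3.0

    def test_alpha_erd_beta_quiet(self):
        # broadband floor high enough that beta rows are noise- (not alpha-
        # leakage-) dominated
        emap = ersp(alpha_trials(30, seed=8, task_gain=np.sqrt(0.5), noise=0.5),
                    FS)
        assert band_erd(emap, ALPHA_BAND, (5.5, 8.5)) < -1.0
        assert abs(band_erd(emap, BETA_BAND, (5.5, 8.5))) < 1.0

    def test_empty_selection(self):
        emap = ersp(alpha_trials(2, seed=9), FS)
        with pytest.raises(ValueError):
            band_erd(emap, (100.0, 120.0), (5, 9))


class TestBandEnergyCurve:
    def test_flat_for_stationary_input(self):
        rng = np.random.default_rng(1)
        curve = band_energy_curve(rng.standard_normal((60, 11000)), FS)
        assert np.all(np.abs(np.diff(curve.times) - 0.2) < 1e-9)
        assert curve.values.std() / curve.values.mean() < 0.05

    def test_ramping_erd_is_monotone(self):
        env = np.ones(11000)
        env[5000:9000] = np.linspace(1.0, 0.3, 4000)  # deepening suppression
        trials = alpha_trials(40, seed=2, env=env, noise=0.05)
        curve = band_energy_curve(trials, FS)
        sel = (curve.times >= 5.5) & (curve.times <= 8.5)
        rho = stats.spearmanr(curve.times[sel], curve.values[sel]).statistic
        assert rho < -0.9

    def test_rest_curve_near_baseline(self):
        trials = alpha_trials(40, seed=3, task_gain=1.0)
        curve = band_energy_curve(trials, FS)
        base = curve.values[(curve.times >= 3.0) & (curve.times <= 4.0)].mean()
        task = curve.values[(curve.times >= 5.0) & (curve.times <= 9.0)]
        assert np.all(np.abs(task - base) / base < 0.10)

    def test_partition_additivity(self):
        rng = np.random.default_rng(4)
        trials = rng.standard_normal((10, 11000))
        full = band_energy_curve(trials, FS, band=(8.0, 30.0))
        parts = sum(
            band_energy_curve(trials, FS, band=b).values
            for b in [(8.0, 14.0), (14.0, 22.0), (22.0, 30.0)]
        )
        np.testing.assert_allclose(parts, full.values, rtol=0.02)

    def test_empty_band_raises(self):
        with pytest.raises(ValueError):
            band_energy_curve(np.zeros((2, 3000)), FS, band=(8.3, 8.7))


class TestCAR:
    def test_antisymmetric_pair_unchanged(self):
        x = np.sin(np.linspace(0, 10, 500))
        rec = EEGRecording(np.vstack([x, -x]), FS, ["C3", "C4"])
        out = car_reference(rec)
        np.testing.assert_allclose(out.data, rec.data, atol=1e-12)

    def test_common_mode_rejection(self):
        rng = np.random.default_rng(5)
        base = rng.standard_normal((4, 300))
        rec0 = EEGRecording(base, FS, ["C3", "C4", "Cz", "Pz"])
        rec1 = EEGRecording(base + 7.5, FS, ["C3", "C4", "Cz", "Pz"])
        np.testing.assert_allclose(
            car_reference(rec1).data, car_reference(rec0).data, atol=1e-12
        )

    def test_output_channel_mean_zero(self):
        rng = np.random.default_rng(6)
        rec = EEGRecording(
            rng.standard_normal((27, 1000)), FS,
            [f"ch{i}" if i > 1 else ("C3", "C4")[i] for i in range(27)],
        )
        out = car_reference(rec)
        assert np.abs(out.data.mean(axis=0)).max() < 1e-12

    def test_single_channel_raises(self):
        rec = EEGRecording(np.zeros((1, 100)), FS, ["C3"])
        with pytest.raises(ValueError):
            car_reference(rec)
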