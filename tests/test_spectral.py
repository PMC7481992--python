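import numpy as np
import pytest

import hemiconn as hc
from hemiconn.exceptions import ConfigError, DataError
from hemiconn.spectral import (
    DEFAULT_BANDS,
    area_band_power,
    condition_eeg,
    multitaper_band_power,
    multitaper_psd,
    regress_out_eog,
)


def sine(freq, fs, duration, phase=0.0):
    t = np.arange(int(duration * fs)) / fs
    return np.sin(2 * np.pi * freq * t + phase)


class TestConditionEEG:
    def test_resampling_preserves_spectral_peak(self):
        x = sine(10.0, 250.0, 10.0)[None, :]
        y = condition_eeg(x, fs_in=250.0)
        assert y.shape[1] == 5000
        f, psd = multitaper_psd(y, fs=500.0)
        peak = f[np.argmax(psd[0])]
        assert abs(peak - 10.0) < 0.5

    def test_linear_trend_removed(self):
        # conditioning is linear, so the trend's footprint is the difference
        # between conditioning the signal with and without it
        rng = np.random.default_rng(0)
        n = 30000
        t = np.arange(n)
        noise = rng.standard_normal(n)
        with_trend = condition_eeg((0.05 * t + noise)[None, :], fs_in=500.0)
        without = condition_eeg(noise[None, :], fs_in=500.0)
        core = slice(n // 10, -n // 10)  # away from filter edge transients
        footprint = np.abs(with_trend[0, core] - without[0, core]).max()
        assert footprint < 1e-9 * (0.05 * n)  # vanishes relative to the trend span

    def test_dc_only_becomes_zero(self):
        x = np.full((2, 2000), 3.7)
        y = condition_eeg(x, fs_in=500.0)
        assert np.allclose(y, 0.0, atol=1e-8)

    def test_too_short_input(self):
        with pytest.raises(DataError, match="2 s"):
            condition_eeg(np.zeros((1, 100)), fs_in=500.0)

    def test_low_sampling_rate(self):
        with pytest.raises(DataError, match="60 Hz"):
            condition_eeg(np.zeros((1, 1000)), fs_in=50.0)

    def test_non_finite_samples(self):
        x = np.zeros((1, 2000))
        x[0, 5] = np.nan
        with pytest.raises(DataError, match="non-finite"):
            condition_eeg(x, fs_in=500.0)


class TestEOGRegression:
    def test_residual_uncorrelated_with_eog(self):
        rng = np.random.default_rng(1)
        eog = rng.standard_normal((2, 4000))
        eeg = 0.8 * eog[0] + rng.standard_normal(4000)
        out = regress_out_eog(eeg[None, :], eog)
        for k in range(2):
            assert abs(np.corrcoef(out[0], eog[k])[0, 1]) < 1e-10

    def test_orthogonal_eog_leaves_signal(self):
        n = 4000
        eeg = sine(10.0, 500.0, 8.0)[None, :]
        eog = sine(1.0, 500.0, 8.0)[None, :]  # orthogonal over full periods
        out = regress_out_eog(eeg, eog)
        assert np.allclose(out, eeg - eeg.mean(), atol=1e-8)

    def test_exact_artifact_removed(self):
        eog = np.random.default_rng(2).standard_normal((1, 3000))
        out = regress_out_eog(eog.copy(), eog)
        assert np.allclose(out, 0.0, atol=1e-10)

    def test_constant_eog_dropped_with_warning(self):
        rng = np.random.default_rng(3)
        eeg = rng.standard_normal((2, 1000))
        eog = np.vstack([np.ones(1000), rng.standard_normal(1000)])
        with pytest.warns(UserWarning, match="constant EOG"):
            out = regress_out_eog(eeg, eog)
        assert out.shape == eeg.shape

    def test_sample_count_mismatch(self):
        with pytest.raises(DataError, match="sample counts"):
            regress_out_eog(np.zeros((1, 100)), np.zeros((2, 99)))


class TestMultitaperBandPower:
    def test_pure_alpha_concentration(self):
        rng = np.random.default_rng(4)
        x = (sine(10.0, 500.0, 30.0) + 0.01 * rng.standard_normal(15000))[None, :]
        table = multitaper_band_power(x, fs=500.0)
        rel = dict(zip(table.band_names, table.relative[0]))
        assert rel["alpha"] > 0.9
        for other in ("delta", "theta", "beta"):
            assert rel[other] < 0.05

    def test_6hz_sine_lands_in_theta(self):
        x = sine(6.0, 500.0, 20.0)[None, :]
        table = multitaper_band_power(x, fs=500.0)
        assert table.band_names[int(np.argmax(table.relative[0]))] == "theta"

    def test_white_noise_band_power_tracks_bandwidth(self):
        # flat PSD: relative power of band b over [0.5, 45] is (hi-lo)/44.5
        rng = np.random.default_rng(5)
        x = rng.standard_normal((1, 150000))
        table = multitaper_band_power(x, fs=500.0)
        for b, rel in zip(table.bands, table.relative[0]):
            expected = (b.hi - b.lo) / 44.5
            assert rel == pytest.approx(expected, rel=0.10)

    def test_parseval_total_power(self):
        # unit-variance white signal: integral of the PSD over [0, fs/2]
        # approximates the variance
        rng = np.random.default_rng(6)
        x = rng.standard_normal((1, 150000))
        f, psd = multitaper_psd(x, fs=500.0)
        total = np.trapezoid(psd[0], f)
        assert total == pytest.approx(1.0, rel=0.10)

    def test_relative_power_amplitude_invariant(self, small_subject):
        x = small_subject.eeg[:4]
        t1 = multitaper_band_power(x, fs=500.0)
        t2 = multitaper_band_power(1000.0 * x, fs=500.0)
        assert np.allclose(t1.relative, t2.relative, atol=1e-12)

    def test_band_sum_bounded_by_one(self, small_subject):
        table = multitaper_band_power(small_subject.eeg, fs=500.0)
        assert np.all(table.relative >= 0)
        assert np.all(table.relative.sum(axis=1) <= 1.0 + 1e-9)

    def test_band_above_nyquist_rejected(self):
        band = hc.BandDefinition("hf", 40.0, 300.0)
        with pytest.raises(ConfigError, match="Nyquist"):
            multitaper_band_power(np.zeros((1, 2000)), fs=500.0, bands=[band])

    def test_band_requires_lo_below_hi(self):
        with pytest.raises(ConfigError):
            hc.BandDefinition("bad", 10.0, 10.0)


class TestAreaBandPower:
    def _table(self, relative):
        bands = DEFAULT_BANDS
        rel = np.asarray(relative, dtype=float)
        return hc.BandPowerTable(bands, rel.copy(), rel, np.ones(rel.shape[0]))

    def test_identical_channels_pass_through(self, eeg_scheme):
        rel = np.tile([0.2, 0.2, 0.4, 0.1], (30, 1))
        out = area_band_power(self._table(rel), eeg_scheme)
        assert np.allclose(out.to_numpy(dtype=float), rel[0], atol=1e-12)

    def test_three_channel_mean(self, eeg_scheme):
        rel = np.tile([0.1, 0.1, 0.3, 0.1], (30, 1))
        # boost alpha of the first frontal-right channel
        idx = eeg_scheme.index("FR1")
        rel[idx, 2] = 0.9
        out = area_band_power(self._table(rel), eeg_scheme)
        assert out.loc[("R", "frontal"), "alpha"] == pytest.approx((0.9 + 0.3 + 0.3) / 3)
        assert out.loc[("L", "frontal"), "alpha"] == pytest.approx(0.3)

    def test_channel_count_mismatch(self, eeg_scheme):
        rel = np.zeros((29, 4))
        with pytest.raises(DataError, match="channels"):
            area_band_power(self._table(rel), eeg_scheme)
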