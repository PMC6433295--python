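"""Spectrum, filter and instantaneous-frequency contracts against closed forms."""

import numpy as np
import pytest

from pafpipe import (
    amplitude_spectrum,
    bandpass_plateau,
    condition_contrast_series,
    instantaneous_frequency,
    mirror_pad,
    peak_alpha,
    select_channels_by_alpha,
    trim_mirror,
)
from pafpipe.simulate import POSTERIOR_CHANNELS, SimConfig, generate_subject_epochs
from pafpipe.spectral import Spectrum, median_window_samples, plateau_gain
from conftest import make_epochs, sinusoid_epochs

FS = 160.0


def _instfreq(epochs, **kw):
    return instantaneous_frequency(bandpass_plateau(epochs), **kw)


class TestAmplitudeSpectrum:
    def test_pure_tone_peaks_at_its_bin(self):
        ep = sinusoid_epochs(10.0, dur_s=0.8)
        spec = amplitude_spectrum(ep, (-800, 0))
        assert spec.freqs[np.argmax(spec.amplitude[0])] == pytest.approx(10.0,
                                                                         abs=1.25)

    def test_linearity_across_channels(self):
        ep = sinusoid_epochs(10.0, n_channels=2, dur_s=0.8)
        ep.data[:, 1, :] *= 2.0
        spec = amplitude_spectrum(ep, (-800, 0))
        m = spec.band_mean((8, 13))
        assert m[1] == pytest.approx(2 * m[0], rel=1e-9)

    def test_white_noise_is_flat(self):
        rng = np.random.default_rng(0)
        ep = make_epochs(rng.standard_normal((200, 1, 128)))
        spec = amplitude_spectrum(ep, (-800, 0))
        alpha = spec.amplitude[0, (spec.freqs >= 8) & (spec.freqs <= 13)]
        broad = spec.amplitude[0]
        se = broad.std(ddof=1) / np.sqrt(len(alpha))
        assert abs(alpha.mean() - broad.mean()) < 3 * se

    def test_window_validation(self):
        ep = sinusoid_epochs(10.0, dur_s=0.8)
        with pytest.raises(ValueError, match="outside epoch"):
            amplitude_spectrum(ep, (-900, 0))
        with pytest.raises(ValueError, match="two cycles"):
            amplitude_spectrum(ep, (-300, 0), freq_range=(5, 30))


class TestPeakAlpha:
    def _spec(self, amps, freqs=None):
        freqs = freqs if freqs is not None else np.arange(5.0, 30.5, 0.5)
        return Spectrum(np.atleast_2d(amps), freqs, ["a"], (-800.0, 0.0))

    def test_recovers_generating_peak(self):
        cfg = SimConfig(n_trials_per_condition=30, n_channels=8, snr=20.0,
                        subject_peak_freq=10.5, freq_offset_gm=0.0,
                        freq_jitter_sd=0.0, seed=0)
        ep = generate_subject_epochs(cfg, 0)
        spec = amplitude_spectrum(ep, (-800, 0))
        bin_hz = FS / ep.crop(-800, 0).n_samples
        assert peak_alpha(spec, channel_subset=POSTERIOR_CHANNELS) == \
            pytest.approx(10.5, abs=bin_hz)

    def test_tie_goes_to_lowest_frequency(self):
        freqs = np.arange(5.0, 30.5, 0.5)
        amps = np.ones_like(freqs)
        amps[freqs == 9.0] = 2.0
        amps[freqs == 12.0] = 2.0
        assert peak_alpha(self._spec(amps)) == 9.0

    def test_band_limited_result(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            f = peak_alpha(self._spec(rng.random(51)))
            assert 8.0 <= f <= 13.0

    def test_monotone_band_warns(self):
        freqs = np.arange(5.0, 30.5, 0.5)
        with pytest.warns(UserWarning, match="no interior alpha peak"):
            peak_alpha(self._spec(freqs * 1.0))  # increasing through the band


class TestChannelSelection:
    def _spec(self, n_ch=10, alpha_boost=None):
        freqs = np.arange(5.0, 30.5, 0.5)
        amps = np.ones((n_ch, len(freqs)))
        if alpha_boost:
            for ch, g in alpha_boost.items():
                amps[ch, (freqs >= 8) & (freqs <= 13)] *= g
        return Spectrum(amps, freqs, [f"c{i}" for i in range(n_ch)],
                        (-800.0, 0.0))

    def test_strongest_first(self):
        spec = self._spec(alpha_boost={3: 3.0, 5: 1.5})
        assert select_channels_by_alpha(spec, 2) == ["c3", "c5"]

    def test_k_equals_n(self):
        spec = self._spec(4, alpha_boost={2: 2.0})
        assert select_channels_by_alpha(spec, 4)[0] == "c2"
        assert len(select_channels_by_alpha(spec, 4)) == 4

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            select_channels_by_alpha(self._spec(4), 0)
        with pytest.raises(ValueError):
            select_channels_by_alpha(self._spec(4), 9)

    def test_synthetic_topography_selects_posterior(self):
        cfg = SimConfig(n_trials_per_condition=20, n_channels=32, snr=3.0,
                        seed=6)
        ep = generate_subject_epochs(cfg, 0)
        spec = amplitude_spectrum(ep, (-800, 0))
        top = select_channels_by_alpha(spec, 4)
        assert set(top) <= set(POSTERIOR_CHANNELS)


class TestMirrorPad:
    def test_definitional_reversal(self):
        ep = make_epochs(np.arange(3.0)[None, None, :], t0=-800)
        out = mirror_pad(ep)
        assert np.array_equal(out.data[0, 0], [0, 1, 2, 2, 1, 0])
        assert out.data[0, 0, 2] == out.data[0, 0, 3]  # continuous junction

    def test_requires_prestimulus_only(self):
        ep = sinusoid_epochs(10.0, t0=-400, dur_s=0.8)  # extends past 0
        with pytest.raises(ValueError, match="prestimulus"):
            mirror_pad(ep)

    def test_trim_restores_original(self):
        ep = sinusoid_epochs(10.0, t0=-2000, dur_s=2.0)
        back = trim_mirror(mirror_pad(ep))
        assert np.array_equal(back.data, ep.data)
        assert np.array_equal(back.times, ep.times)

    def test_interior_estimates_agree_with_unpadded(self):
        # a cosine even about the reflection axis (sample N - 1/2) continues
        # smoothly through the junction: padding must then be transparent
        dur, f = 4.0, 10.0
        phase = np.pi / 2 - 2 * np.pi * f * (dur - 0.5 / FS)
        ep = sinusoid_epochs(f, t0=-4000, dur_s=dur, phase=phase)
        f_plain = _instfreq(ep).frequency[0]
        f_pad = _instfreq(mirror_pad(ep)).frequency[0, :ep.n_samples]
        interior = slice(80, ep.n_samples - 80)  # 500 ms off both ends
        assert np.nanmax(np.abs(f_plain[interior] - f_pad[interior])
                         / f_plain[interior]) < 1e-6

    def test_interior_accuracy_with_generic_phase(self):
        # a generic junction has a derivative kink whose analytic-signal
        # ripple leaks inward; the interior must still be accurate to 0.1 Hz
        ep = sinusoid_epochs(10.0, t0=-4000, dur_s=4.0, phase=1.0)
        f_pad = _instfreq(mirror_pad(ep)).frequency[0, :ep.n_samples]
        interior = slice(80, ep.n_samples - 80)
        assert np.nanmax(np.abs(f_pad[interior] - 10.0)) < 0.1


class TestPlateauBandpass:
    def test_frequency_response_contract(self):
        # unit gain across the band, >= 20 dB rejection beyond the transitions
        freqs = np.fft.rfftfreq(512, 1 / FS)
        g = plateau_gain(freqs)
        passband = (freqs >= 8) & (freqs <= 13)
        stop = (freqs <= 8 * 0.85 - 1e-9) | (freqs >= 13 * 1.15 + 1e-9)
        assert np.all(np.abs(g[passband] - 1) <= 0.01)
        assert np.all(g[stop] <= 10 ** (-20 / 20))

    def test_in_band_tone_preserved(self):
        ep = sinusoid_epochs(10.0, dur_s=2.0)
        out = bandpass_plateau(ep)
        ratio = out.data.std() / ep.data.std()
        assert ratio == pytest.approx(1.0, abs=0.01)

    def test_out_of_band_tone_rejected(self):
        ep = sinusoid_epochs(3.0, dur_s=2.0)
        out = bandpass_plateau(ep)
        assert out.data.std() < 0.1 * ep.data.std()

    def test_zero_phase_no_lag(self):
        ep = sinusoid_epochs(10.0, dur_s=2.0)
        out = bandpass_plateau(ep)
        x, y = ep.data[0, 0], out.data[0, 0]
        lags = np.arange(-10, 11)
        xc = [np.corrcoef(x[10:-10], y[10 + l:len(y) - 10 + l])[0, 1]
              for l in lags]
        assert lags[int(np.argmax(xc))] == 0

    def test_impulse_response_symmetric(self):
        data = np.zeros((1, 1, 257))
        data[0, 0, 128] = 1.0
        out = bandpass_plateau(make_epochs(data, t0=-800))
        h = out.data[0, 0]
        assert np.allclose(h, h[::-1], atol=1e-12)

    def test_symmetric_input_stays_symmetric(self):
        rng = np.random.default_rng(0)
        half = rng.standard_normal(64)
        x = np.concatenate([half, half[::-1]])
        out = bandpass_plateau(make_epochs(x[None, None, :], t0=-800))
        assert np.allclose(out.data[0, 0], out.data[0, 0, ::-1], atol=1e-12)

    def test_band_above_nyquist_rejected(self):
        ep = sinusoid_epochs(10.0, fs=25.0, dur_s=2.0)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_plateau(ep, band=(8.0, 13.0))


class TestInstantaneousFrequency:
    def test_constant_tone_exact(self):
        ep = sinusoid_epochs(10.0, dur_s=2.0)
        series = _instfreq(ep)
        interior = series.interior_mask()
        assert np.nanmax(np.abs(series.frequency[0, interior] - 10.0)) < 0.01

    def test_chirp_tracked(self):
        t = np.arange(0, 2.0, 1 / FS)
        f0, f1 = 8.0, 13.0
        x = np.sin(2 * np.pi * (f0 * t + (f1 - f0) / (2 * 2.0) * t**2))
        true_f = f0 + (f1 - f0) * t / 2.0
        series = _instfreq(make_epochs(x[None, None, :], t0=-2000))
        interior = series.interior_mask()
        rmse = np.sqrt(np.nanmean(
            (series.frequency[0, interior] - true_f[interior]) ** 2))
        assert rmse < 0.3

    def test_median_cascade_suppresses_noise(self):
        rng = np.random.default_rng(3)
        t = np.arange(0, 2.0, 1 / FS)
        x = np.sin(2 * np.pi * 10 * t) + 0.2 * rng.standard_normal(len(t))
        ep = make_epochs(x[None, None, :], t0=-2000)
        filt = bandpass_plateau(ep)
        raw_phase = np.unwrap(np.angle(
            __import__("scipy.signal", fromlist=["hilbert"]).hilbert(
                filt.data[0, 0])))
        raw = np.diff(raw_phase) * FS / (2 * np.pi)
        series = instantaneous_frequency(filt)
        interior = series.interior_mask()
        assert raw[interior[:-1]].std() > series.frequency[0, interior].std()
        assert series.frequency[0, interior].std() < 0.2

    def test_amplitude_invariance(self):
        ep = sinusoid_epochs(10.4, n_trials=3, dur_s=2.0)
        scales = np.array([1.0, 7.3, 0.002])[:, None, None]
        scaled = make_epochs(ep.data * scales, t0=-2000)
        f1 = _instfreq(ep).frequency
        f2 = _instfreq(scaled).frequency
        assert np.nanmax(np.abs(f1 - f2) / np.abs(f1)) < 1e-9

    def test_band_limited_estimates_stay_near_band(self):
        rng = np.random.default_rng(7)
        ep = make_epochs(rng.standard_normal((5, 1, 320)), t0=-2000)
        series = _instfreq(ep)
        interior = series.interior_mask()
        f = series.frequency[:, interior]
        assert np.nanmin(f) >= 7.0 and np.nanmax(f) <= 14.0

    def test_zero_amplitude_marked_missing(self):
        ep = make_epochs(np.zeros((1, 1, 320)), t0=-2000)
        series = instantaneous_frequency(ep)
        assert np.isnan(series.frequency).all()

    def test_median_windows_odd_and_bounded(self):
        ks = median_window_samples(FS)
        assert len(ks) == 10
        assert all(k % 2 == 1 and k >= 3 for k in ks)
        assert ks[-1] == 65  # 400 ms at 160 Hz, rounded odd

    def test_power_is_squared_amplitude(self):
        ep = sinusoid_epochs(10.0, amplitude=2.0, dur_s=2.0)
        series = _instfreq(ep)
        assert np.allclose(series.power, series.amplitude**2)
        interior = series.interior_mask()
        assert np.median(series.amplitude[0, interior]) == pytest.approx(2.0,
                                                                         rel=0.02)


class TestConditionContrast:
    def _series(self, seed=0, offset=0.0, n=30):
        cfg = SimConfig(n_trials_per_condition=n, n_channels=8, snr=20.0,
                        freq_offset_gm=offset, freq_jitter_sd=0.05, seed=seed)
        ep = generate_subject_epochs(cfg, 0)
        pre = ep.crop(-800, 0).pick_channels(["Oz"])
        series = instantaneous_frequency(bandpass_plateau(mirror_pad(pre)))
        return series, ep.trials["percept"].to_numpy()

    def test_relabeling_identical_trials_gives_zero(self):
        series, _ = self._series()
        half = np.array(["GM", "EM"] * (series.frequency.shape[0] // 2))
        series.frequency = np.tile(series.frequency[:1], (len(half), 1))
        con = condition_contrast_series(series, half)
        assert np.allclose(con.difference, 0.0)

    def test_generator_offset_recovered(self):
        series, percepts = self._series(seed=1, offset=0.3)
        con = condition_contrast_series(series, percepts)
        sel = (con.times >= -600) & (con.times <= -200)
        assert 0.2 <= con.difference[sel].mean() <= 0.4

    def test_power_difference_null_for_equal_amplitudes(self):
        series, percepts = self._series(seed=2, offset=0.0)
        con = condition_contrast_series(series, percepts, measure="power")
        sel = (con.times >= -600) & (con.times <= -200)
        rel = abs(con.difference[sel].mean()) / con.mean_a[sel].mean()
        assert rel < 0.1

    def test_absent_label_rejected(self):
        series, percepts = self._series()
        with pytest.raises(ValueError, match="absent"):
            condition_contrast_series(series, np.array(["EM"] * len(percepts)))
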