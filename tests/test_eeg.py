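"""Spectral pipeline: filters, Welch PSD, band power, spectrogram."""

import numpy as np
import pytest
from scipy import signal

import periseizure as ps
from periseizure.errors import PeriSeizureError, SamplingRateError, WindowError

from conftest import make_tone

FS = 1000.0


def tone_recording(freq, amp=100.0, duration=30.0, fs=FS):
    return ps.EEGRecording(make_tone(freq, amp, fs, duration), fs)


class TestPreprocess:
    def test_dc_passes_unchanged(self):
        rec = ps.EEGRecording(np.full(int(30 * FS), 42.0), FS)
        out = ps.preprocess(rec)
        assert np.max(np.abs(out.samples - 42.0)) < 1e-6

    @pytest.mark.parametrize(
        "freq,min_att_db",
        [(50.0, 20.0), (150.0, 25.0)],
        ids=["notch_50hz", "lowpass_150hz"],
    )
    def test_tone_attenuation_meets_analytic_response(self, freq, min_att_db):
        """Steady-state attenuation matches the filters' frequency response."""
        rec = tone_recording(freq)
        out = ps.preprocess(rec).samples
        mid = slice(int(5 * FS), int(25 * FS))  # trim filtfilt edge transients
        rms_in = np.sqrt(np.mean(rec.samples[mid] ** 2))
        rms_out = np.sqrt(np.mean(out[mid] ** 2))
        measured_db = 20 * np.log10(rms_in / rms_out)
        assert measured_db >= min_att_db

        # independent oracle: |H_lp * H_notch|^2 (filtfilt squares the magnitude)
        sos = signal.butter(4, 100.0, btype="low", fs=FS, output="sos")
        _, h_lp = signal.sosfreqz(sos, worN=[freq], fs=FS)
        b, a = signal.iirnotch(50.0, 30.0, fs=FS)
        _, h_n = signal.freqz(b, a, worN=[freq], fs=FS)
        analytic_db = -20 * np.log10(np.abs(h_lp[0] * h_n[0]) ** 2)
        assert measured_db >= min(analytic_db - 1.0, 60.0)

    def test_low_sampling_rate_rejected(self):
        rec = ps.EEGRecording(np.zeros(1000), fs=200.0)
        with pytest.raises(SamplingRateError):
            ps.preprocess(rec)

    def test_idempotent_on_band_limited_signal(self):
        rec = tone_recording(20.0, duration=10.0)
        once = ps.preprocess(rec)
        twice = ps.preprocess(once)
        mid = slice(int(2 * FS), int(8 * FS))
        rms = np.sqrt(np.mean(once.samples[mid] ** 2))
        assert np.max(np.abs(twice.samples[mid] - once.samples[mid])) < 0.02 * rms

    def test_preserves_length_fs_events(self):
        rec = ps.EEGRecording(
            np.random.default_rng(0).normal(size=3000),
            FS,
            events=[(1.0, "stimulation", 20.0)],
        )
        out = ps.preprocess(rec)
        assert len(out.samples) == len(rec.samples)
        assert out.fs == rec.fs and out.events == rec.events


class TestWelchPSD:
    def test_white_noise_flat_at_variance_density(self, rng):
        sigma = 2.0
        rec = ps.EEGRecording(rng.normal(0, sigma, int(120 * FS)), FS)
        est = ps.welch_psd(rec, (0.0, 120.0))
        expected = sigma**2 / (FS / 2)
        inner = (est.frequencies > 5) & (est.frequencies < FS / 2 - 5)
        assert est.psd[inner].mean() == pytest.approx(expected, rel=0.05)

    def test_parseval_total_power_equals_variance(self, rng):
        rec = ps.EEGRecording(rng.normal(0, 3.0, int(30 * FS)), FS)
        est = ps.welch_psd(rec, (0.0, 30.0))
        total = np.trapezoid(est.psd, est.frequencies)
        assert total == pytest.approx(np.var(rec.samples), rel=0.05)

    def test_tone_power_concentrated_at_its_frequency(self):
        est = ps.welch_psd(tone_recording(10.0), (0.0, 30.0))
        total = np.trapezoid(est.psd, est.frequencies)
        assert total == pytest.approx(100.0**2 / 2, rel=0.05)
        peak = est.frequencies[np.argmax(est.psd)]
        assert peak == pytest.approx(10.0, abs=1.0)

    def test_zero_signal_zero_psd(self):
        est = ps.welch_psd(ps.EEGRecording(np.zeros(int(5 * FS)), FS), (0.0, 5.0))
        assert np.all(est.psd == 0.0)

    def test_matches_scipy_welch(self, rng):
        x = rng.normal(0, 2.0, int(30 * FS))
        est = ps.welch_psd(ps.EEGRecording(x, FS), (0.0, 30.0))
        f_ref, p_ref = signal.welch(
            x, fs=FS, window="hann", nperseg=int(FS), noverlap=0, detrend=False
        )
        np.testing.assert_allclose(est.frequencies, f_ref)
        np.testing.assert_allclose(est.psd, p_ref, rtol=1e-10, atol=1e-15)

    def test_epoch_count_is_floor_of_window_length(self, rng):
        rec = ps.EEGRecording(rng.normal(size=int(10 * FS)), FS)
        assert ps.welch_psd(rec, (0.0, 9.7)).epoch_count == 9

    def test_short_window_rejected(self):
        rec = ps.EEGRecording(np.zeros(int(5 * FS)), FS)
        with pytest.raises(WindowError):
            ps.welch_psd(rec, (0.0, 0.5))
        with pytest.raises(WindowError):
            ps.welch_psd(rec, (0.0, 6.0))


class TestBandPower:
    def test_tone_in_band_parseval(self):
        est = ps.welch_psd(ps.preprocess(tone_recording(10.0)), (0.0, 30.0))
        bp = ps.band_power(est, (4.0, 14.0))
        assert bp.band_power == pytest.approx(5000.0, rel=0.05)

    def test_tone_outside_band_leaks_under_one_percent(self):
        est = ps.welch_psd(ps.preprocess(tone_recording(20.0)), (0.0, 30.0))
        total = np.trapezoid(est.psd, est.frequencies)
        assert ps.band_power(est, (4.0, 14.0)).band_power <= 0.01 * total

    def test_linear_in_psd_scale(self, rng):
        est = ps.welch_psd(ps.EEGRecording(rng.normal(size=int(10 * FS)), FS), (0, 10))
        scaled = ps.SpectralEstimate(
            est.frequencies, 3.5 * est.psd, est.epoch_count, est.band, est.window
        )
        assert ps.band_power(scaled).band_power == pytest.approx(
            3.5 * ps.band_power(est).band_power, rel=1e-12
        )

    def test_additive_over_adjacent_subbands_and_monotone(self, rng):
        est = ps.welch_psd(ps.EEGRecording(rng.normal(size=int(20 * FS)), FS), (0, 20))
        whole = ps.band_power(est, (4.0, 14.0)).band_power
        left = ps.band_power(est, (4.0, 9.0)).band_power
        right = ps.band_power(est, (9.0, 14.0)).band_power
        assert left + right == pytest.approx(whole, rel=1e-9)
        assert ps.band_power(est, (4.0, 20.0)).band_power >= whole

    def test_band_outside_grid_rejected(self, rng):
        est = ps.welch_psd(ps.EEGRecording(rng.normal(size=int(5 * FS)), FS), (0, 5))
        with pytest.raises(PeriSeizureError):
            ps.band_power(est, (4.0, 600.0))


class TestSeizurePower:
    def test_quadratic_in_afterdischarge_amplitude(self, noise_free_cfg):
        """Doubling the after-discharge amplitude quadruples band power."""
        from dataclasses import replace

        cfgs = [
            replace(
                noise_free_cfg,
                latent_pre=lp,
                latent_during=0.0,
                beta_pre=1.0,
                duration_gain_s=0.0,  # equal durations: only amplitude differs
            )
            for lp in (0.25, 1.0)
        ]
        # amplitude = scale * (0.5 + latent): 0.75 vs 1.5 -> power ratio 4
        powers = []
        for cfg in cfgs:
            sess = ps.generate_session(cfg, seed=5)
            assert sess.truth.true_duration == cfg.duration_base_s
            powers.append(ps.seizure_power(sess.eeg, cfg.induction_time).band_power)
        assert powers[1] / powers[0] == pytest.approx(4.0, rel=0.10)

    def test_no_afterdischarge_gives_baseline_power(self, noise_free_cfg):
        from dataclasses import replace

        cfg = replace(
            noise_free_cfg, latent_pre=0.0, latent_during=0.0, ad_base=0.0
        )
        sess = ps.generate_session(cfg, seed=1)
        assert sess.truth.true_duration == 0.0
        bp = ps.seizure_power(sess.eeg, cfg.induction_time)
        assert bp.band_power < 1.0  # noise-free baseline: essentially zero

    def test_deterministic(self, rng):
        rec = ps.EEGRecording(rng.normal(size=int(240 * FS)), FS)
        a = ps.seizure_power(rec, 100.0).band_power
        b = ps.seizure_power(rec, 100.0).band_power
        assert a == b

    def test_window_beyond_recording_rejected(self):
        rec = ps.EEGRecording(np.zeros(int(40 * FS)), FS)
        with pytest.raises(WindowError):
            ps.seizure_power(rec, 20.0)


class TestSpectrogram:
    def test_column_average_reproduces_welch(self, rng):
        rec = ps.EEGRecording(rng.normal(size=int(20 * FS)), FS)
        sg = ps.spectrogram(rec, (0.0, 20.0))
        est = ps.welch_psd(rec, (0.0, 20.0))
        np.testing.assert_allclose(sg.power.mean(axis=1), est.psd, rtol=1e-9)

    def test_stationary_noise_columns_agree(self, rng):
        rec = ps.EEGRecording(rng.normal(0, 2.0, int(60 * FS)), FS)
        sg = ps.spectrogram(rec, (0.0, 60.0))
        col_power = np.trapezoid(sg.power, sg.frequencies, axis=0)
        assert col_power.std() / col_power.mean() < 0.25
        np.testing.assert_allclose(col_power.mean(), 4.0, rtol=0.1)

    def test_transient_tone_elevates_only_its_epochs(self):
        x = np.zeros(int(30 * FS))
        t = np.arange(len(x)) / FS
        on = (t >= 10.0) & (t < 20.0)
        x[on] = 50 * np.sin(2 * np.pi * 10 * t[on])
        sg = ps.spectrogram(ps.EEGRecording(x, FS), (0.0, 30.0))
        band = (sg.frequencies >= 4) & (sg.frequencies <= 14)
        env = np.trapezoid(sg.power[band], sg.frequencies[band], axis=0)
        assert env[10:20].min() > 100 * max(env[:10].max(), env[20:].max(), 1e-12)
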