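"""Bench protocols: averaged periodogram, linearity, sine fits, fidelity."""

import numpy as np
import pytest

import biodac as bd
from biodac.characterize import MINUS_3DB


class TestBartlettPsd:
    def test_five_ten_second_recordings_give_fifty_windows(self):
        recs = [bd.gaussian_noise(1.0, 10.0, 1000.0, seed=k) for k in range(5)]
        report = bd.noise_floor_report(recs, window_seconds=1.0)
        assert report.results["n_windows"] == 50

    def test_parseval_white_noise(self):
        sigma = 2.4e-6
        recs = [bd.gaussian_noise(sigma, 10.0, 30_000.0, seed=k) for k in range(5)]
        freqs, asd = bd.bartlett_psd(recs, 1.0)
        integrated = np.trapezoid(asd**2, freqs)
        variance = np.var(np.concatenate([r.samples for r in recs]))
        assert integrated == pytest.approx(variance, rel=0.05)

    def test_sine_peak_at_nearest_grid_frequency(self):
        f0 = 123.4
        recs = [bd.tone(f0, 1.0, 10.0, 1000.0)]
        freqs, asd = bd.bartlett_psd(recs, 1.0)
        peak_f = freqs[np.argmax(asd)]
        assert abs(peak_f - f0) <= freqs[1] - freqs[0]

    def test_too_short_recording_raises(self):
        recs = [bd.tone(10.0, 1.0, 0.5, 1000.0)]
        with pytest.raises(bd.ProtocolError):
            bd.bartlett_psd(recs, window_seconds=1.0)


class TestRmsNoise:
    def test_zero_and_unit_sine(self):
        silent = [bd.Waveform(np.zeros(1000), 1000.0)] * 3
        assert bd.rms_noise(silent) == (0.0, 0.0)
        sines = [bd.tone(10.0, 1.0, 1.0, 1000.0)] * 4
        mean, std = bd.rms_noise(sines)
        assert mean == pytest.approx(1 / np.sqrt(2), rel=1e-3)
        assert std == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_recordings_recover_sigma(self):
        sigma = 2.4e-6
        recs = [bd.gaussian_noise(sigma, 10.0, 30_000.0, seed=k) for k in range(5)]
        mean, std = bd.rms_noise(recs)
        stderr = sigma / np.sqrt(2 * 10 * 30_000)
        assert abs(mean - sigma) < 3 * stderr * np.sqrt(5)


class TestLinearity:
    FS = 48_000.0

    def _stimulus_with(self, modify=None):
        r = bd.ramp((-1.0, 1.0), 0.01, self.FS)
        x = r.samples.copy()
        if modify is not None:
            x = modify(x)
        gap = np.zeros(int(self.FS))
        parts = [gap]
        for _ in range(10):
            parts += [x, gap]
        return bd.Waveform(np.concatenate(parts), self.FS, "normalized")

    def test_ideal_ramp_perfectly_linear(self):
        res = bd.linearity_analysis(self._stimulus_with(), n_ramps=10)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)
        assert np.abs(res.normalized_residuals).max() < 1e-6

    def test_injected_step_recovered_from_residuals(self):
        # a step in the tail of the ramp is barely absorbed by the line fit,
        # so the peak normalized residual reads the step height in slope units
        h = 0.05

        def inject(x):
            x = x.copy()
            x[int(0.99 * len(x)):] += h
            return x

        res = bd.linearity_analysis(self._stimulus_with(inject), n_ramps=10)
        recovered = np.abs(res.normalized_residuals).max() * res.slope
        assert recovered == pytest.approx(h, rel=0.10)

    def test_simulated_chain_droop_negligible(self):
        # 0.01 s ramp against a 1 Hz corner: 100:1 timescale separation
        dac = bd.DacSpec(sample_rate=self.FS, highpass_corner=1.0)
        stim = bd.linearity_protocol(dac, sample_rate=self.FS)
        rec = bd.simulate_playback(
            stim, dac, bd.DividerSetting(1e6, 2000.0), noise_on=False
        )
        res = bd.linearity_analysis(rec, n_ramps=10)
        assert res.r_squared > 0.999

    def test_silent_recording_raises(self):
        wave = bd.Waveform(np.zeros(1000), 1000.0)
        with pytest.raises(bd.ProtocolError):
            bd.linearity_analysis(wave)


class TestFreqResponseProtocol:
    def test_two_tones_are_the_endpoints(self):
        _, schedule = bd.freq_response_protocol(
            n_tones=2, sample_rate=48_000.0
        )
        assert [e.frequency for e in schedule] == pytest.approx([0.1, 10_000.0])

    def test_tone_duration_is_five_periods(self):
        _, schedule = bd.freq_response_protocol(sample_rate=48_000.0)
        for entry in schedule:
            assert entry.end - entry.start == pytest.approx(
                5.0 / entry.frequency, abs=2 / 48_000.0
            )

    def test_schedule_strictly_increasing_no_overlap(self):
        _, schedule = bd.freq_response_protocol(sample_rate=48_000.0)
        for a, b in zip(schedule, schedule[1:]):
            assert b.start > a.end


class TestFitSine:
    def test_exact_sine_recovered(self):
        wave = bd.tone(37.0, 0.8, 1.0, 10_000.0, phase=0.6)
        fit = bd.fit_sine(wave, 37.0)
        assert fit.amplitude == pytest.approx(0.8, rel=1e-6)
        assert fit.phase == pytest.approx(0.6, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)
        assert not fit.excluded

    def test_white_noise_excluded_by_gate(self):
        wave = bd.gaussian_noise(1.0, 1.0, 10_000.0, seed=21)
        fit = bd.fit_sine(wave, 37.0)
        assert fit.r_squared < 0.1
        assert fit.excluded

    def test_noisy_sine_amplitude_within_2_percent(self):
        # amplitude SNR 20 dB
        rng = np.random.default_rng(8)
        wave = bd.tone(37.0, 1.0, 2.0, 10_000.0)
        noisy = wave.with_samples(
            wave.samples + rng.normal(0, 0.1, len(wave))
        )
        fit = bd.fit_sine(noisy, 37.0)
        assert fit.amplitude == pytest.approx(1.0, rel=0.02)

    def test_offset_does_not_bias_amplitude(self):
        wave = bd.tone(10.0, 1.0, 2.0, 5_000.0)
        shifted = wave.with_samples(wave.samples + 5.0)
        fit = bd.fit_sine(shifted, 10.0)
        assert fit.amplitude == pytest.approx(1.0, rel=1e-6)
        assert fit.offset == pytest.approx(5.0, rel=1e-6)


class TestMinus3db:
    def test_analytic_single_pole_interpolation(self):
        corner = 1.0
        freqs = np.logspace(-1, 4, 40)
        mags = 20 * np.log10(freqs / np.hypot(freqs, corner))
        found = bd.minus3db_frequency(freqs, mags)
        assert found == pytest.approx(corner, rel=0.02)

    def test_all_above_threshold_not_found(self):
        freqs = np.array([10.0, 100.0, 1000.0])
        mags = np.array([-1.0, -0.5, 0.0])
        assert bd.minus3db_frequency(freqs, mags) is None

    def test_exact_grid_point_returned(self):
        freqs = np.array([0.5, 1.0, 2.0])
        mags = np.array([-7.0, MINUS_3DB, -1.0])
        assert bd.minus3db_frequency(freqs, mags) == pytest.approx(1.0)


class TestPhaseUncertainty:
    def test_printed_example(self):
        assert bd.phase_uncertainty(100.0, 30_000.0) == pytest.approx(1.2)

    def test_full_rate_is_full_circle_and_linear_growth(self):
        assert bd.phase_uncertainty(30_000.0, 30_000.0) == 360.0
        assert bd.phase_uncertainty(200.0, 30_000.0) == pytest.approx(
            2 * bd.phase_uncertainty(100.0, 30_000.0)
        )


class TestChainFrequencyResponse:
    def test_corner_recovered_within_5_percent(self, chain_frequency_response):
        resp = chain_frequency_response
        corner = bd.minus3db_frequency(resp.frequencies, resp.magnitudes_db)
        assert corner == pytest.approx(1.0, rel=0.05)

    def test_rolloff_slope_is_first_order(self, chain_frequency_response):
        # asymptotic stopband slope, measured well below the 1 Hz corner
        slope = bd.rolloff_slope_db_per_decade(
            chain_frequency_response, below=0.2
        )
        assert slope == pytest.approx(20.0, abs=1.0)

    def test_no_tone_excluded_on_noiseless_chain(self, chain_frequency_response):
        assert chain_frequency_response.excluded_frequencies.size == 0
        assert np.all(chain_frequency_response.r_squared >= 0.95)


class TestFidelity:
    def test_identical_signals(self):
        sig = bd.gaussian_noise(1.0, 2.0, 1000.0, seed=1)
        fid = bd.fidelity_metrics(sig, sig)
        assert fid.correlation == pytest.approx(1.0)
        assert fid.rmse == 0.0
        assert fid.lag == 0

    def test_known_integer_shift_recovered(self):
        sig = bd.gaussian_noise(1.0, 2.0, 1000.0, seed=1)
        shifted = bd.Waveform(
            np.concatenate([np.zeros(37), sig.samples]), 1000.0
        )
        fid = bd.fidelity_metrics(sig, shifted)
        assert fid.lag == 37
        assert fid.correlation == pytest.approx(1.0)

    def test_scaling_changes_rmse_not_correlation(self):
        sig = bd.gaussian_noise(1.0, 2.0, 1000.0, seed=2)
        scaled = sig.with_samples(sig.samples * 3.0)
        fid = bd.fidelity_metrics(sig, scaled)
        assert fid.correlation == pytest.approx(1.0)
        assert fid.rmse > 0

    def test_rate_mismatch_rejected(self):
        a = bd.gaussian_noise(1.0, 1.0, 1000.0, seed=0)
        b = bd.gaussian_noise(1.0, 1.0, 2000.0, seed=0)
        with pytest.raises(bd.ProtocolError):
            bd.fidelity_metrics(a, b)

    def test_short_overlap_rejected(self):
        sig = bd.gaussian_noise(1.0, 2.0, 1000.0, seed=3)
        tail = bd.Waveform(sig.samples[-300:], 1000.0)
        with pytest.raises(bd.ProtocolError):
            bd.fidelity_metrics(sig, tail)


def test_report_json_round_trip(tmp_path):
    import json

    recs = [bd.gaussian_noise(1.0, 2.0, 1000.0, seed=k) for k in range(2)]
    report = bd.noise_floor_report(recs)
    path = tmp_path / "report.json"
    report.to_json(path)
    loaded = json.loads(path.read_text())
    assert loaded["protocol"] == "noise_floor"
    assert loaded["results"]["rms_mean_v"] == pytest.approx(1.0, rel=0.05)
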