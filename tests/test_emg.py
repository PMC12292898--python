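import numpy as np
import pytest

from gaitscore.core import SchemaError
from gaitscore.emg import (
    ETFFTensor,
    build_etff,
    build_ftf,
    envelope,
    preprocess_emg,
    scale_frequencies,
    stance_energy_spread,
    warp_to_cycle,
)

FS = 1000.0


def _tone(freq, dur=4.0, amp=1.0, fs=FS):
    t = np.arange(int(dur * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


class TestPreprocess:
    def test_stopband_attenuation_at_5hz(self):
        x = _tone(5.0)
        y = preprocess_emg(x, FS)
        # compare RMS before normalization would hide gain; use filter only
        from scipy.signal import butter, sosfiltfilt

        sos = butter(4, (20, 450), btype="bandpass", fs=FS, output="sos")
        filt = sosfiltfilt(sos, x)
        mid = slice(500, 3500)
        atten_db = 20 * np.log10(np.std(filt[mid]) / np.std(x[mid]))
        assert atten_db <= -40

    def test_passband_gain_and_normalization(self):
        x = _tone(100.0)
        from scipy.signal import butter, sosfiltfilt

        sos = butter(4, (20, 450), btype="bandpass", fs=FS, output="sos")
        filt = sosfiltfilt(sos, x)
        mid = slice(500, 3500)
        assert np.abs(filt[mid]).max() == pytest.approx(1.0, rel=0.05)
        eps = preprocess_emg(x, FS)
        assert np.abs(eps[mid]).max() == pytest.approx(1.0, rel=0.05)

    def test_zero_signal_stays_zero(self):
        np.testing.assert_array_equal(preprocess_emg(np.zeros(4000), FS),
                                      np.zeros(4000))

    def test_nyquist_guard(self):
        with pytest.raises(SchemaError):
            preprocess_emg(np.zeros(1000), 800.0)


class TestEnvelope:
    def test_zero_in_zero_out(self):
        np.testing.assert_array_equal(envelope(np.zeros(2000), FS),
                                      np.zeros(2000))

    def test_sinusoid_envelope_is_amplitude(self):
        x = _tone(100.0, amp=2.5)
        env = envelope(x, FS)
        mid = slice(500, 3500)
        assert np.all(np.abs(env[mid] - 2.5) / 2.5 < 0.02)

    def test_sign_flip_invariance(self):
        x = _tone(80.0) * np.linspace(0.2, 1.0, 4000)
        np.testing.assert_allclose(envelope(-x, FS), envelope(x, FS), atol=1e-12)

    def test_am_modulator_recovery(self):
        t = np.arange(4000) / FS
        m = np.sin(np.pi * t / 4.0)  # slow half-sine over the record
        x = m * _tone(120.0)
        env = envelope(x, FS)
        mid = slice(400, 3600)
        rms_err = np.sqrt(np.mean((env[mid] - m[mid]) ** 2))
        assert rms_err / np.sqrt(np.mean(m[mid] ** 2)) < 0.05


class TestWarp:
    def test_constant_series(self):
        out = warp_to_cycle(np.full(500, 3.3), 10, 400)
        assert out.shape == (97,)
        np.testing.assert_allclose(out, 3.3)

    def test_linear_ramp_exact(self):
        ramp = np.linspace(0.0, 5.0, 1200)
        out = warp_to_cycle(ramp, 100, 1103)
        assert out[0] == pytest.approx(ramp[100], abs=1e-9)
        assert out[-1] == pytest.approx(ramp[1103], abs=1e-9)
        assert len(out) == 97
        np.testing.assert_allclose(np.diff(out), np.diff(out)[0], atol=1e-9)

    def test_out_of_range_cycle(self):
        with pytest.raises(SchemaError):
            warp_to_cycle(np.zeros(100), 50, 200)


class TestFeatureTensors:
    def test_ftf_contract_and_identical_cycles(self, clean_subject):
        trial, truth = clean_subject
        hs = truth.events[0]["left"]["hs"]
        cycles = [(a, (a + b) // 2, b) for a, b in zip(hs[:-1], hs[1:])]
        both = {"left": cycles, "right": cycles}
        ftf = build_ftf(trial, both)
        assert ftf.values.shape == (4, 97)
        assert np.all(ftf.values >= 0) and np.all(ftf.values <= 1)
        np.testing.assert_allclose(ftf.values.max(axis=1), 1.0)
        # averaging a single cycle equals that cycle's normalized envelope
        one = build_ftf(trial, {"left": cycles[:1], "right": cycles[:1]})
        assert one.values.shape == (4, 97)

    def test_ftf_amplitude_scale_invariance(self, clean_subject):
        import copy

        trial, truth = clean_subject
        hs = truth.events[0]["left"]["hs"]
        cycles = [(a, (a + b) // 2, b) for a, b in zip(hs[:-1], hs[1:])]
        both = {"left": cycles, "right": cycles}
        base = build_ftf(trial, both).values
        scaled_trial = copy.deepcopy(trial)
        scaled_trial.emg = trial.emg * 7.5
        scaled = build_ftf(scaled_trial, both).values
        np.testing.assert_allclose(scaled, base, atol=1e-9)

    def test_ga_symmetry_decreases_with_severity(self):
        from gaitscore.pipeline import extract_trial_features
        from gaitscore.synthetic import generate_subject

        corrs = {}
        for lvl in (0, 2):
            trials, _ = generate_subject(lvl, seed=11, n_trials=1)
            ftf = extract_trial_features(trials[0])["ftf"]
            corrs[lvl] = np.corrcoef(ftf[2], ftf[3])[0, 1]
        assert corrs[0] > 0.9
        assert corrs[2] < corrs[0]

    def test_etff_peak_frequency_for_tone(self, clean_subject):
        """A pure 100 Hz tone puts the max-energy scale within 10% of 100 Hz."""
        import copy

        trial, truth = clean_subject
        tone_trial = copy.deepcopy(trial)
        t = np.arange(trial.emg.shape[0]) / trial.config.fs_emg
        tone_trial.emg = np.tile(np.sin(2 * np.pi * 100.0 * t)[:, None], (1, 4))
        hs = truth.events[0]["left"]["hs"]
        cycles = [(a, (a + b) // 2, b) for a, b in zip(hs[:-1], hs[1:])]
        etff = build_etff(tone_trial, {"left": cycles, "right": cycles})
        assert etff.values.shape == (100, 97, 4)
        row_energy = etff.values[:, :, 0].sum(axis=1)
        peak_freq = etff.scale_freqs[np.argmax(row_energy)]
        assert abs(peak_freq - 100.0) / 100.0 < 0.10

    def test_etff_white_noise_columns_roughly_uniform(self, clean_subject):
        import copy

        trial, truth = clean_subject
        rng = np.random.default_rng(0)
        white = copy.deepcopy(trial)
        white.emg = rng.standard_normal(trial.emg.shape)
        hs = truth.events[0]["left"]["hs"]
        cycles = [(a, (a + b) // 2, b) for a, b in zip(hs[:-1], hs[1:])]
        etff = build_etff(white, {"left": cycles, "right": cycles})
        col = etff.values[:, :, 0].sum(axis=0)
        assert col.std() / col.mean() < 0.3

    def test_stance_energy_spread_increases_with_severity(self):
        from gaitscore.pipeline import extract_trial_features
        from gaitscore.synthetic import generate_subject

        spreads = {}
        for lvl in (0, 2):
            trials, _ = generate_subject(lvl, seed=11, n_trials=1)
            f = extract_trial_features(trials[0])
            et = ETFFTensor(values=f["etff"], scale_freqs=f["scale_freqs"])
            spreads[lvl] = stance_energy_spread(et)
        assert spreads[2] > spreads[0]

    def test_scale_frequencies_span(self):
        freqs, scales = scale_frequencies(1000.0)
        assert len(freqs) == 100
        assert freqs[0] == pytest.approx(500.0)
        assert freqs[-1] == pytest.approx(10.0)
        assert np.all(np.diff(freqs) < 0)
        assert np.all(np.diff(scales) > 0)
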