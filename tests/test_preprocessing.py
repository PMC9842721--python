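"""Preprocessing chain: gammatone envelopes, filtering, splits, windows."""

import numpy as np
import pytest

from vlaai.containers import EnvelopeSeries, MultichannelRecording, SplitSpec
from vlaai.preprocessing import (
    apply_normalization,
    erb_space,
    fit_normalization,
    gammatone_envelope,
    highpass_eeg,
    invert_normalization,
    make_windows,
    preprocess_recording,
    rereference_common_average,
    resample_signal,
    split_recording,
)


class TestGammatoneEnvelope:
    def test_endpoints_of_erb_spacing(self):
        centers = erb_space(50.0, 5000.0, 28)
        assert centers.shape == (28,)
        assert centers[0] == pytest.approx(50.0)
        assert centers[-1] == pytest.approx(5000.0)
        assert np.all(np.diff(centers) > 0)

    def test_zero_waveform_gives_zero_envelope(self):
        env = gammatone_envelope(np.zeros(4000), 16000.0)
        assert np.all(env.samples == 0)
        assert env.fs == 16000.0

    def test_positive_homogeneity_of_degree_0p6(self, rng):
        x = rng.standard_normal(8000)
        e1 = gammatone_envelope(x, 16000.0).samples
        e2 = gammatone_envelope(2.5 * x, 16000.0).samples
        np.testing.assert_allclose(e2, 2.5**0.6 * e1, rtol=1e-6, atol=1e-12)

    def test_pure_tone_envelope_steady_after_downsampling(self):
        # A 1 kHz tone has a constant envelope; the raw subband magnitudes
        # ripple at 2 kHz, so steadiness is assessed at the 64 Hz working
        # rate where that ripple is filtered out.
        fs = 16000.0
        t = np.arange(int(2 * fs)) / fs
        env = gammatone_envelope(np.sin(2 * np.pi * 1000 * t), fs)
        env64 = resample_signal(resample_signal(env.samples, fs, 1024.0), 1024.0, 64.0)
        steady = env64[13:-13]  # skip 200 ms of onset/edge transients
        assert steady.std() / steady.mean() < 0.05

    def test_rejects_stereo_and_low_rate(self):
        with pytest.raises(ValueError, match="mono"):
            gammatone_envelope(np.zeros((2, 100)), 16000.0)
        with pytest.raises(ValueError, match="[Ss]ampling rate"):
            gammatone_envelope(np.zeros(100), 8000.0)


class TestHighpass:
    def test_dc_channel_removed(self):
        rec = MultichannelRecording(np.full((2, 640), 7.0), 64.0)
        out = highpass_eeg(rec)
        assert out.samples.shape == rec.samples.shape
        assert np.abs(out.samples[:, 64:-64]).max() < 1e-3 * 7.0

    def test_passband_sinusoid_preserved_zero_phase(self):
        fs = 64.0
        x = np.sin(2 * np.pi * 10 * np.arange(int(30 * fs)) / fs)
        out = highpass_eeg(MultichannelRecording(x[None, :], fs)).samples[0]
        seg = slice(128, -128)
        assert out[seg].std() == pytest.approx(x[seg].std(), rel=0.01)
        cc = np.correlate(out[seg], x[seg], "full")
        assert np.argmax(cc) == len(x[seg]) - 1  # peak at lag 0

    def test_empty_or_slow_recording_rejected(self):
        with pytest.raises(ValueError):
            highpass_eeg(MultichannelRecording(np.empty((1, 0)), 64.0))
        with pytest.raises(ValueError):
            highpass_eeg(MultichannelRecording(np.zeros((1, 100)), 1.0))


class TestResample:
    def test_length_arithmetic(self):
        assert resample_signal(np.zeros(8192), 8192.0, 64.0).shape == (64,)

    def test_constant_stays_constant(self):
        out = resample_signal(np.ones(8192), 8192.0, 64.0)
        np.testing.assert_allclose(out, 1.0, atol=1e-9)

    def test_slow_sinusoid_against_closed_form(self):
        s = np.sin(2 * np.pi * np.arange(8192) / 8192)
        out = resample_signal(s, 8192.0, 64.0)
        ref = np.sin(2 * np.pi * np.arange(64) / 64)
        assert np.corrcoef(out, ref)[0, 1] > 0.999

    def test_upsampling_rejected(self):
        with pytest.raises(ValueError):
            resample_signal(np.zeros(100), 64.0, 128.0)


class TestCommonAverage:
    def test_opposite_channels_unchanged(self):
        x = np.vstack([np.ones(50), -np.ones(50)])
        out = rereference_common_average(MultichannelRecording(x, 64.0))
        np.testing.assert_allclose(out.samples, x)

    def test_channel_mean_zero_after(self, rng):
        rec = MultichannelRecording(rng.standard_normal((8, 200)), 64.0)
        out = rereference_common_average(rec)
        assert np.abs(out.samples.mean(axis=0)).max() < 1e-10

    def test_identical_channels_become_zero(self, rng):
        row = rng.standard_normal(100)
        out = rereference_common_average(MultichannelRecording(np.tile(row, (4, 1)), 64.0))
        np.testing.assert_allclose(out.samples, 0.0, atol=1e-12)

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError):
            rereference_common_average(MultichannelRecording(np.zeros((1, 10)), 64.0))


class TestSplit:
    def _pair(self, rng, n=1000):
        return (
            MultichannelRecording(rng.standard_normal((3, n)), 64.0),
            EnvelopeSeries(rng.random(n), 64.0),
        )

    def test_80_10_10_sizes_and_middle_location(self, rng):
        eeg, env = self._pair(rng)
        sp = split_recording(eeg, env)
        assert sp["train"].envelope.shape[0] == 800
        assert sp["val"].envelope.shape[0] == 100
        assert sp["test"].envelope.shape[0] == 100
        assert sp["val"].start == 400
        assert sp["test"].start == 500

    def test_splits_partition_the_recording(self, rng):
        eeg, env = self._pair(rng, 997)
        sp = split_recording(eeg, env)
        lead = sp["train"].envelope[: sp["val"].start]
        tail = sp["train"].envelope[sp["val"].start :]
        rebuilt = np.concatenate([lead, sp["val"].envelope, sp["test"].envelope, tail])
        np.testing.assert_array_equal(rebuilt, env.samples)

    def test_invalid_fractions_rejected(self):
        with pytest.raises(ValueError):
            SplitSpec(0.5, 0.5, 0.5)

    def test_too_short_recording_rejected(self, rng):
        eeg, env = self._pair(rng, 8)
        with pytest.raises(ValueError, match="short"):
            split_recording(eeg, env)


class TestNormalization:
    def test_standardizes_training_channel(self, rng):
        x = 5.0 + 2.0 * rng.standard_normal((1, 5000))
        stats = fit_normalization(x)
        z = apply_normalization(stats, x)
        assert abs(z.mean()) < 1e-8
        assert z.std() == pytest.approx(1.0, abs=1e-6)

    def test_variance_scaling_variant(self, rng):
        x = rng.standard_normal((2, 1000)) * 3.0
        stats = fit_normalization(x, scale_kind="variance")
        z = apply_normalization(stats, x)
        assert z[0].std() == pytest.approx(1 / x[0].std(), rel=1e-6)

    def test_constant_channel_rejected_by_name(self):
        x = np.vstack([np.random.default_rng(0).standard_normal(100), np.ones(100)])
        with pytest.raises(ValueError, match="1"):
            fit_normalization(x)

    def test_train_stats_leave_shifted_val_mean_nonzero(self):
        # drifting signal: the validation segment has a different mean, and
        # applying train-fitted statistics must not hide that
        t = np.linspace(0, 1, 2000)
        drift = t * 4.0
        stats = fit_normalization(drift[None, :1000])
        val = apply_normalization(stats, drift[None, 1000:])
        assert abs(val.mean()) > 0.5

    def test_apply_then_invert_is_identity(self, rng):
        x = rng.standard_normal((3, 500)) * 2 + 1
        stats = fit_normalization(x)
        np.testing.assert_allclose(invert_normalization(stats, apply_normalization(stats, x)), x)


class TestWindows:
    @pytest.mark.parametrize(
        "dur_s, window_s, overlap, expected",
        [(60, 5.0, 0.8, 56), (5, 5.0, 0.8, 1), (10, 5.0, 0.0, 2)],
    )
    def test_window_counts(self, rng, dur_s, window_s, overlap, expected):
        n = int(dur_s * 64)
        w = make_windows(rng.standard_normal((2, n)), rng.random(n), 64.0, window_s, overlap)
        assert w.n_windows == expected
        assert w.window_samples == int(window_s * 64)

    def test_short_recording_flagged_empty(self, rng):
        w = make_windows(rng.standard_normal((2, 100)), rng.random(100), 64.0)
        assert w.too_short and w.n_windows == 0

    def test_windows_are_aligned_views_of_the_source(self, rng):
        eeg = rng.standard_normal((2, 640))
        env = rng.random(640)
        w = make_windows(eeg, env, 64.0, 5.0, 0.8)
        for i, s in enumerate(w.start_samples):
            np.testing.assert_array_equal(w.envelope[i], env[s : s + 320])
            np.testing.assert_array_equal(w.eeg[i], eeg[:, s : s + 320].T)


class TestFullPipeline:
    def test_time_alignment_preserved_end_to_end(self, rng):
        # an envelope embedded in one EEG channel at lag 0 must still be
        # maximally correlated at lag 0 after the whole chain
        from vlaai.simulate import generate_envelope_like

        env = generate_envelope_like(60, 64, seed=3).samples
        eeg = rng.standard_normal((4, env.size))
        eeg[0] += 5 * (env - env.mean()) / env.std()
        pre = preprocess_recording(
            MultichannelRecording(eeg, 64.0, subject_id="s", stimulus_id="x"),
            EnvelopeSeries(env, 64.0),
        )
        e = pre.train.eeg[:, :, 0].ravel()
        v = pre.train.envelope.ravel()
        lags = np.arange(-3, 4)
        cc = [np.corrcoef(np.roll(e, lag), v)[0, 1] for lag in lags]
        assert lags[int(np.argmax(cc))] == 0

    def test_audio_waveform_input_end_to_end(self, rng):
        fs_audio = 16000.0
        audio = rng.standard_normal(int(12 * fs_audio))
        eeg = MultichannelRecording(rng.standard_normal((3, int(12 * 512))), 512.0)
        pre = preprocess_recording(eeg, audio, audio_fs=fs_audio)
        assert pre.fs == 64.0
        assert pre.train.n_windows > 0
        # normalized training data: per-channel mean ~0, std ~1
        flat = pre.train.eeg.reshape(-1, 3)
        assert np.abs(flat.mean(axis=0)).max() < 0.5
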