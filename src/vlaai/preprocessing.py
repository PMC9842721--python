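"""Raw audio/EEG to aligned, normalized 64 Hz decoder inputs.

The canonical chain, mirroring common practice in auditory-EEG decoding:

1. speech waveform -> gammatone envelope (28 ERB-spaced subbands, 50 Hz-5 kHz,
   4th-order filters; per-sample absolute value, power-law compression with
   exponent 0.6, mean over subbands);
2. EEG -> zero-phase 1st-order Butterworth high-pass at 0.5 Hz;
3. both -> anti-aliased downsampling to 1024 Hz, then 64 Hz;
4. EEG -> common-average re-reference;
5. split into train (80%) / validation (10%) / test (10%), with validation
   and test taken from the middle of the recording;
6. per-channel normalization with statistics fitted on the training split;
7. slicing into 5 s windows with 80% overlap.

:func:`preprocess_recording` drives the full chain; the individual steps are
plain functions usable on their own.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import scipy.signal

from .containers import (
    EnvelopeSeries,
    MultichannelRecording,
    NormalizationStats,
    SplitSpec,
    WindowPairSet,
)

__all__ = [
    "erb_space",
    "gammatone_subbands",
    "gammatone_envelope",
    "highpass_eeg",
    "resample_signal",
    "rereference_common_average",
    "split_recording",
    "fit_normalization",
    "apply_normalization",
    "invert_normalization",
    "make_windows",
    "preprocess_recording",
    "PreprocessedRecording",
]

#: Glasberg & Moore ERB-rate scale constants.
_ERB_Q = 21.4
_ERB_MIN_BW = 0.00437


def erb_space(f_low: float, f_high: float, n: int) -> np.ndarray:
    """``n`` center frequencies equally spaced on the ERB-rate scale.

    Both endpoints are included.  Uses the Glasberg & Moore ERB-rate mapping
    ``erb(f) = 21.4 * log10(1 + 0.00437 f)``.
    """
    if not (0 < f_low < f_high):
        raise ValueError("need 0 < f_low < f_high")
    if n < 2:
        raise ValueError("need at least two filters")
    erb = lambda f: _ERB_Q * np.log10(1.0 + _ERB_MIN_BW * f)
    erb_inv = lambda e: (10 ** (e / _ERB_Q) - 1.0) / _ERB_MIN_BW
    return erb_inv(np.linspace(erb(f_low), erb(f_high), n))


def gammatone_subbands(
    audio: np.ndarray,
    fs: float,
    n_filters: int = 28,
    f_low: float = 50.0,
    f_high: float = 5000.0,
) -> MultichannelRecording:
    """Filter a mono waveform through an ERB-spaced gammatone filterbank.

    Returns the raw subband signals (one channel per filter) at the input
    sampling rate.  Filters are the standard 4th-order gammatone IIR
    approximations.
    """
    audio = np.asarray(audio, dtype=np.float64)
    if audio.ndim != 1:
        raise ValueError(f"audio must be mono (1-D), got shape {audio.shape}")
    if fs < 2 * f_high:
        raise ValueError(
            f"sampling rate {fs} Hz too low to represent the {f_high} Hz "
            f"top center frequency (need >= {2 * f_high} Hz)"
        )
    centers = erb_space(f_low, f_high, n_filters)
    sub = np.empty((n_filters, audio.shape[0]))
    for i, fc in enumerate(centers):
        b, a = scipy.signal.gammatone(fc, "iir", fs=fs)
        # the direct polynomial form is numerically fragile for low
        # center-frequency/sampling-rate ratios; run as cascaded biquads
        sos = scipy.signal.tf2sos(b, a)
        sub[i] = scipy.signal.sosfilt(sos, audio)
    labels = [f"GT{fc:.0f}Hz" for fc in centers]
    return MultichannelRecording(sub, fs, channel_labels=labels)


def gammatone_envelope(
    audio: np.ndarray,
    fs: float,
    n_filters: int = 28,
    f_low: float = 50.0,
    f_high: float = 5000.0,
    compression: float = 0.6,
    stimulus_id: str = "",
) -> EnvelopeSeries:
    """Gammatone speech envelope: |subband|^compression averaged over bands.

    The output keeps the input sampling rate; downsample separately with
    :func:`resample_signal`.
    """
    sub = gammatone_subbands(audio, fs, n_filters, f_low, f_high)
    env = np.mean(np.abs(sub.samples) ** compression, axis=0)
    return EnvelopeSeries(env, fs, stimulus_id=stimulus_id)


def highpass_eeg(
    rec: MultichannelRecording, cutoff_hz: float = 0.5, order: int = 1
) -> MultichannelRecording:
    """Zero-phase Butterworth high-pass, applied forward and backward.

    The default is a 1st-order filter at 0.5 Hz; filtfilt doubles the
    effective order and cancels the phase response.
    """
    if rec.fs <= 1.0:
        raise ValueError(f"sampling rate {rec.fs} Hz too low for a {cutoff_hz} Hz high-pass")
    if rec.n_samples == 0:
        raise ValueError("cannot filter an empty recording")
    sos = scipy.signal.butter(order, cutoff_hz, btype="highpass", fs=rec.fs, output="sos")
    filtered = scipy.signal.sosfiltfilt(sos, rec.samples, axis=1)
    return rec.with_samples(filtered)


def resample_signal(samples: np.ndarray, fs: float, target_fs: float) -> np.ndarray:
    """Anti-aliased downsampling with a polyphase FIR (Kaiser window).

    Output length is ``round(n * target_fs / fs)``.  Works on 1-D signals or
    ``(n_channels, n_samples)`` arrays (resampled along the last axis).
    """
    if target_fs >= fs:
        raise ValueError(f"target rate {target_fs} must be below the input rate {fs}")
    from fractions import Fraction

    frac = Fraction(target_fs / fs).limit_denominator(10000)
    up, down = frac.numerator, frac.denominator
    return scipy.signal.resample_poly(
        np.asarray(samples, dtype=np.float64),
        up,
        down,
        axis=-1,
        window=("kaiser", 5.0),
        padtype="line",
    )


def rereference_common_average(rec: MultichannelRecording) -> MultichannelRecording:
    """Subtract the instantaneous mean across channels from every channel."""
    if rec.n_channels < 2:
        raise ValueError("common-average referencing needs at least two channels")
    return rec.with_samples(rec.samples - rec.samples.mean(axis=0, keepdims=True))


@dataclass
class _Split:
    eeg: np.ndarray          # (n_channels, n)
    envelope: np.ndarray     # (n,)
    start: int               # index of first sample in the source recording


def split_recording(
    eeg: MultichannelRecording,
    envelope: EnvelopeSeries,
    spec: SplitSpec = SplitSpec(),
) -> dict[str, _Split]:
    """Cut an aligned (EEG, envelope) pair into train/val/test segments.

    Validation and test are contiguous segments in the middle of the
    recording; the training set is the leading plus trailing remainder.
    Fractions are honored to within one sample and every sample is assigned
    to exactly one split.
    """
    if eeg.fs != envelope.fs:
        raise ValueError("EEG and envelope sampling rates differ")
    n = eeg.n_samples
    if n != envelope.n_samples:
        raise ValueError(f"EEG has {n} samples but envelope has {envelope.n_samples}")
    if n < 10:
        raise ValueError(f"recording of {n} samples is too short to split")
    n_val = int(round(spec.val_fraction * n))
    n_test = int(round(spec.test_fraction * n))
    n_train = n - n_val - n_test
    lead = n_train // 2
    # layout: [train lead | val | test | train tail]
    bounds = {
        "train_lead": (0, lead),
        "val": (lead, lead + n_val),
        "test": (lead + n_val, lead + n_val + n_test),
        "train_tail": (lead + n_val + n_test, n),
    }
    x, e = eeg.samples, envelope.samples

    def seg(a: int, b: int) -> _Split:
        return _Split(x[:, a:b], e[a:b], a)

    lo, hi = bounds["train_lead"], bounds["train_tail"]
    train = _Split(
        np.concatenate([x[:, lo[0]:lo[1]], x[:, hi[0]:hi[1]]], axis=1),
        np.concatenate([e[lo[0]:lo[1]], e[hi[0]:hi[1]]]),
        0,
    )
    return {
        "train": train,
        "val": seg(*bounds["val"]),
        "test": seg(*bounds["test"]),
    }


def fit_normalization(
    train_eeg: np.ndarray,
    train_env: np.ndarray | None = None,
    scale_kind: str = "std",
) -> NormalizationStats:
    """Fit per-channel mean/scale on training data only.

    ``train_eeg`` is ``(n_channels, n)``; if ``train_env`` is given it is
    appended as an extra (last) channel so envelope normalization shares the
    same statistics container.
    """
    x = np.asarray(train_eeg, dtype=np.float64)
    if x.ndim == 1:
        x = x[None, :]
    rows = [x]
    if train_env is not None:
        rows.append(np.asarray(train_env, dtype=np.float64)[None, :])
    x = np.concatenate(rows, axis=0)
    mean = x.mean(axis=1)
    std = x.std(axis=1)
    zero = np.flatnonzero(std == 0)
    if zero.size:
        raise ValueError(f"zero-variance channel(s) {zero.tolist()}: cannot normalize")
    scale = std if scale_kind == "std" else std**2
    return NormalizationStats(mean, scale, scale_kind)


def apply_normalization(stats: NormalizationStats, samples: np.ndarray) -> np.ndarray:
    """``(x - mean) / scale`` per channel; 1-D input uses the single stat row."""
    x = np.asarray(samples, dtype=np.float64)
    if x.ndim == 1:
        if stats.mean.shape[0] != 1:
            raise ValueError("1-D data but stats carry more than one channel")
        return (x - stats.mean[0]) / stats.scale[0]
    if x.shape[0] != stats.mean.shape[0]:
        raise ValueError(
            f"data has {x.shape[0]} channels but stats have {stats.mean.shape[0]}"
        )
    return (x - stats.mean[:, None]) / stats.scale[:, None]


def invert_normalization(stats: NormalizationStats, samples: np.ndarray) -> np.ndarray:
    x = np.asarray(samples, dtype=np.float64)
    if x.ndim == 1:
        return x * stats.scale[0] + stats.mean[0]
    return x * stats.scale[:, None] + stats.mean[:, None]


def make_windows(
    eeg: np.ndarray,
    envelope: np.ndarray,
    fs: float,
    window_s: float = 5.0,
    overlap: float = 0.8,
    subject_id: str = "",
    stimulus_id: str = "",
    start_offset: int = 0,
) -> WindowPairSet:
    """Slice aligned signals into fixed-length overlapping window pairs.

    hop = window * (1 - overlap); the trailing remainder that does not fill a
    full window is discarded.  A recording shorter than one window yields an
    empty set flagged ``too_short``.
    """
    eeg = np.asarray(eeg, dtype=np.float64)
    if eeg.ndim == 1:
        eeg = eeg[None, :]
    envelope = np.asarray(envelope, dtype=np.float64).ravel()
    n = envelope.shape[0]
    if eeg.shape[1] != n:
        raise ValueError("EEG and envelope lengths differ")
    if not (0 <= overlap < 1):
        raise ValueError(f"overlap must be in [0, 1), got {overlap}")
    wlen = int(round(window_s * fs))
    hop = int(round(wlen * (1.0 - overlap)))
    if hop < 1:
        raise ValueError("window overlap leaves a hop below one sample")
    if n < wlen:
        return WindowPairSet(
            eeg=np.empty((0, wlen, eeg.shape[0])),
            envelope=np.empty((0, wlen)),
            fs=fs,
            too_short=True,
        )
    n_windows = (n - wlen) // hop + 1
    starts = np.arange(n_windows) * hop
    idx = starts[:, None] + np.arange(wlen)[None, :]
    return WindowPairSet(
        eeg=np.transpose(eeg[:, idx], (1, 2, 0)),
        envelope=envelope[idx],
        fs=fs,
        start_samples=starts + start_offset,
        subject_ids=[subject_id] * n_windows,
        stimulus_ids=[stimulus_id] * n_windows,
    )


@dataclass
class PreprocessedRecording:
    """Everything the training/evaluation stages need for one recording."""

    train: WindowPairSet
    val: WindowPairSet
    test: WindowPairSet
    eeg_stats: NormalizationStats
    env_stats: NormalizationStats
    fs: float
    subject_id: str = ""
    stimulus_id: str = ""


def preprocess_recording(
    eeg: MultichannelRecording,
    audio: np.ndarray | EnvelopeSeries,
    audio_fs: float | None = None,
    target_fs: float = 64.0,
    intermediate_fs: float = 1024.0,
    split: SplitSpec = SplitSpec(),
    window_s: float = 5.0,
    overlap: float = 0.8,
    scale_kind: str = "std",
    artifact_removal: Callable[[MultichannelRecording], MultichannelRecording] | None = None,
) -> PreprocessedRecording:
    """Full preprocessing chain for one (EEG, stimulus) pair.

    ``audio`` may be a raw waveform (with ``audio_fs``) from which the
    gammatone envelope is computed, or an already-extracted
    :class:`EnvelopeSeries`.  ``artifact_removal`` is an optional hook (e.g. an
    eyeblink-removal routine) applied to the EEG at the intermediate rate.
    Signals are trimmed to their common length after resampling.
    """
    if isinstance(audio, EnvelopeSeries):
        env = audio
    else:
        if audio_fs is None:
            raise ValueError("audio_fs is required for waveform input")
        env = gammatone_envelope(audio, audio_fs, stimulus_id=eeg.stimulus_id)

    eeg = highpass_eeg(eeg)

    def two_stage(sig: np.ndarray, fs: float) -> np.ndarray:
        if fs > intermediate_fs:
            sig = resample_signal(sig, fs, intermediate_fs)
            fs = intermediate_fs
        if fs > target_fs:
            sig = resample_signal(sig, fs, target_fs)
        return sig

    eeg_mid_fs = min(eeg.fs, intermediate_fs)
    eeg_mid = eeg.with_samples(
        resample_signal(eeg.samples, eeg.fs, intermediate_fs)
        if eeg.fs > intermediate_fs
        else eeg.samples,
        fs=eeg_mid_fs,
    )
    if artifact_removal is not None:
        eeg_mid = artifact_removal(eeg_mid)
    eeg_64 = eeg_mid.with_samples(
        resample_signal(eeg_mid.samples, eeg_mid.fs, target_fs)
        if eeg_mid.fs > target_fs
        else eeg_mid.samples,
        fs=target_fs,
    )
    eeg_64 = rereference_common_average(eeg_64)

    env_64 = env.samples if env.fs <= target_fs else two_stage(env.samples, env.fs)
    n = min(eeg_64.n_samples, env_64.shape[0])
    eeg_64 = eeg_64.with_samples(eeg_64.samples[:, :n])
    env_64 = env_64[:n]

    splits = split_recording(eeg_64, EnvelopeSeries(env_64, target_fs), split)
    eeg_stats = fit_normalization(splits["train"].eeg, scale_kind=scale_kind)
    env_stats = fit_normalization(splits["train"].envelope[None, :], scale_kind=scale_kind)

    out: dict[str, WindowPairSet] = {}
    for name, seg in splits.items():
        out[name] = make_windows(
            apply_normalization(eeg_stats, seg.eeg),
            apply_normalization(env_stats, seg.envelope[None, :])[0],
            target_fs,
            window_s=window_s,
            overlap=overlap,
            subject_id=eeg.subject_id,
            stimulus_id=eeg.stimulus_id,
            start_offset=seg.start,
        )
    return PreprocessedRecording(
        train=out["train"],
        val=out["val"],
        test=out["test"],
        eeg_stats=eeg_stats,
        env_stats=env_stats,
        fs=target_fs,
        subject_id=eeg.subject_id,
        stimulus_id=eeg.stimulus_id,
    )
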