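"""Synthetic paired (envelope, EEG) data with controlled encoding and SNR.

The simulator emulates the statistical structure that envelope decoders
assume: each EEG channel is a lagged linear response to the stimulus
envelope (a per-channel temporal response function, TRF, over lags
0-500 ms), optionally passed through a mild static nonlinearity, plus
additive noise at a controlled signal-to-noise ratio.  Per-subject
variation is modelled as a relative perturbation of the shared TRFs.

SNR convention: ``snr_db`` is the *in-band* SNR — the ratio of the signal
variance to the noise variance that falls inside the envelope's modulation
band (below ``envelope_cutoff_hz``).  Out-of-band noise is (in principle)
removable by linear filtering, so with this convention the best achievable
linear reconstruction correlation for white noise and linear encoding has
the closed form ``r = sqrt(snr / (1 + snr))`` with ``snr`` the linear power
ratio, independent of the noise bandwidth.

This is deliberately *not* biophysically realistic EEG: there is no volume
conduction, no alpha rhythm, no artifacts.  It provides ground truth for
recovery tests and a controlled stage on which decoder comparisons have
known expected outcomes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import scipy.signal

from .containers import EnvelopeSeries, MultichannelRecording, SplitSpec
from .preprocessing import (
    PreprocessedRecording,
    apply_normalization,
    fit_normalization,
    make_windows,
    split_recording,
)

__all__ = [
    "SimulationSpec",
    "generate_envelope_like",
    "make_trf",
    "simulate_subject",
    "prepare_subject",
    "make_dataset",
]


@dataclass
class SimulationSpec:
    """Parameters of one simulated dataset.

    ``nonlinearity`` is one of ``"none"``, ``"compressive_power"`` (the
    standardized envelope raised to ``nonlinearity_param``) or
    ``"saturating_tanh"`` (``tanh(g * standardized envelope)`` with gain
    ``g = nonlinearity_param``).  ``trf_kind`` selects smooth damped-cosine
    response kernels (``"smooth"``) or single-impulse kernels at random
    channel-specific lags (``"lagged_impulses"``).
    """

    n_subjects: int = 3
    duration_s: float = 120.0
    fs: float = 64.0
    n_channels: int = 64
    trf_lags_s: float = 0.5
    snr_db: float = 0.0
    subject_jitter: float = 0.2
    nonlinearity: str = "none"
    nonlinearity_param: float = 1.0
    noise_kind: str = "white"
    envelope_cutoff_hz: float | None = 5.0
    trf_kind: str = "smooth"
    split: SplitSpec = field(default_factory=SplitSpec)
    window_s: float = 5.0
    overlap: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.duration_s <= 10:
            raise ValueError("duration_s must exceed 10 s")
        if not (0 <= self.subject_jitter < 1):
            raise ValueError("subject_jitter must be in [0, 1)")
        if np.isnan(self.snr_db):
            raise ValueError("snr_db must not be NaN")
        if self.nonlinearity not in ("none", "compressive_power", "saturating_tanh"):
            raise ValueError(f"unknown nonlinearity {self.nonlinearity!r}")
        if self.noise_kind not in ("white", "pink"):
            raise ValueError(f"unknown noise_kind {self.noise_kind!r}")
        if self.trf_kind not in ("smooth", "lagged_impulses"):
            raise ValueError(f"unknown trf_kind {self.trf_kind!r}")

    @property
    def n_lags(self) -> int:
        return int(round(self.trf_lags_s * self.fs))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["split"] = [self.split.train_fraction, self.split.val_fraction, self.split.test_fraction]
        return d


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


def _band_filter_sos(fs: float, cutoff_hz: float):
    return scipy.signal.butter(8, cutoff_hz, btype="lowpass", fs=fs, output="sos")


def generate_envelope_like(
    duration_s: float,
    fs: float = 64.0,
    seed: int = 0,
    cutoff_hz: float | None = 5.0,
    stimulus_id: str = "",
) -> EnvelopeSeries:
    """Nonnegative, temporally smooth envelope surrogate.

    Low-pass-filtered rectified white noise: nonnegative, with its
    modulation energy concentrated below ``cutoff_hz`` (well under the 10 Hz
    that dominates real speech envelopes).  Deterministic given ``seed``.

    ``cutoff_hz=None`` skips the low-pass stage and returns the rectified
    noise itself — a spectrally flat surrogate.  Real envelopes are not
    flat; this regime exists because a flat stimulus spectrum is what makes
    decoder-weight recovery identifiable in parameter-recovery tests.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    n = int(round(duration_s * fs))
    rng = np.random.default_rng(seed)
    raw = np.abs(rng.standard_normal(n))
    if cutoff_hz is None:
        return EnvelopeSeries(raw, fs, stimulus_id=stimulus_id)
    sos = _band_filter_sos(fs, cutoff_hz)
    env = scipy.signal.sosfiltfilt(sos, raw)
    return EnvelopeSeries(np.clip(env, 0.0, None), fs, stimulus_id=stimulus_id)


def make_trf(
    rng: np.random.Generator,
    n_channels: int,
    n_lags: int,
    fs: float,
    kind: str = "smooth",
) -> np.ndarray:
    """Random per-channel response kernels, shape ``(n_channels, n_lags)``.

    ``smooth``: damped-cosine kernels with channel-specific latency,
    width, frequency and signed amplitude — a caricature of real temporal
    response functions.  ``lagged_impulses``: a single impulse per channel
    at a random lag, making the encoding an exactly invertible lagged
    mixture (useful for recovery tests).
    """
    t = np.arange(n_lags) / fs
    trf = np.zeros((n_channels, n_lags))
    if kind == "smooth":
        for c in range(n_channels):
            amp = rng.uniform(0.5, 1.5) * rng.choice([-1.0, 1.0])
            mu = rng.uniform(0.06, 0.30)
            sigma = rng.uniform(0.03, 0.08)
            freq = rng.uniform(1.0, 6.0)
            phase = rng.uniform(0, 2 * np.pi)
            trf[c] = amp * np.exp(-0.5 * ((t - mu) / sigma) ** 2) * np.cos(
                2 * np.pi * freq * (t - mu) + phase
            )
    elif kind == "lagged_impulses":
        lags = rng.integers(0, n_lags, size=n_channels)
        amps = rng.uniform(0.5, 1.5, size=n_channels) * rng.choice([-1.0, 1.0], size=n_channels)
        trf[np.arange(n_channels), lags] = amps
    else:
        raise ValueError(f"unknown TRF kind {kind!r}")
    return trf


def _apply_nonlinearity(env: np.ndarray, kind: str, param: float) -> np.ndarray:
    if kind == "none":
        return env
    if kind == "compressive_power":
        # envelopes are nonnegative; compress relative to their scale
        return (env / env.std()) ** param
    if kind == "saturating_tanh":
        # saturate around the operating point: the raw envelope has a large
        # positive offset that would otherwise pin tanh in saturation
        z = (env - env.mean()) / env.std()
        return np.tanh(param * z)
    raise ValueError(kind)


def _noise(rng: np.random.Generator, shape, kind: str) -> np.ndarray:
    white = rng.standard_normal(shape)
    if kind == "white":
        return white
    # pink: 1/f amplitude shaping in the frequency domain
    n = shape[-1]
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    spec = np.fft.rfft(white, axis=-1) * scale
    pink = np.fft.irfft(spec, n=n, axis=-1)
    return pink / pink.std(axis=-1, keepdims=True)


def base_trf(spec: SimulationSpec) -> np.ndarray:
    """The population-level TRFs shared (up to jitter) by all subjects."""
    return make_trf(_rng(spec.seed, 999), spec.n_channels, spec.n_lags, spec.fs, spec.trf_kind)


def subject_trf(spec: SimulationSpec, subject_index: int) -> np.ndarray:
    """Subject-specific TRFs: base TRFs plus a smooth relative perturbation."""
    trf = base_trf(spec)
    if spec.subject_jitter == 0:
        return trf
    rng = _rng(spec.seed, 1000, subject_index)
    pert = make_trf(rng, spec.n_channels, spec.n_lags, spec.fs, "smooth")
    scale = np.sqrt((trf**2).mean(axis=1, keepdims=True))
    pscale = np.sqrt((pert**2).mean(axis=1, keepdims=True))
    return trf + spec.subject_jitter * scale * pert / pscale


def simulate_subject(
    spec: SimulationSpec, subject_index: int
) -> tuple[MultichannelRecording, EnvelopeSeries, np.ndarray]:
    """Simulate one subject's paired (EEG, envelope) recording.

    EEG channel ``c`` is ``TRF_c * f(envelope) + noise`` with the noise
    scaled to the spec's in-band SNR (see the module docstring).  Returns
    the recording, the (clean) envelope that is the decoding target, and
    the subject's ground-truth TRF matrix ``(n_channels, n_lags)``.
    """
    env = generate_envelope_like(
        spec.duration_s,
        spec.fs,
        seed=_rng(spec.seed, 0, subject_index).integers(2**31),
        cutoff_hz=spec.envelope_cutoff_hz,
        stimulus_id=f"stim{subject_index:02d}",
    )
    trf = subject_trf(spec, subject_index)
    driven = _apply_nonlinearity(env.samples, spec.nonlinearity, spec.nonlinearity_param)
    n = env.n_samples
    sig = scipy.signal.fftconvolve(trf, driven[None, :], axes=1)[:, :n]

    if np.isfinite(spec.snr_db):
        snr_lin = 10.0 ** (spec.snr_db / 10.0)
        noise = _noise(_rng(spec.seed, 2000, subject_index), sig.shape, spec.noise_kind)
        # in-band variance of the unit noise defines the SNR normalization
        if spec.envelope_cutoff_hz is None:
            inband_var = noise.var(axis=-1, keepdims=True)
        else:
            sos = _band_filter_sos(spec.fs, spec.envelope_cutoff_hz)
            inband = scipy.signal.sosfiltfilt(sos, noise, axis=-1)
            inband_var = inband.var(axis=-1, keepdims=True)
        sig_var = sig.var(axis=-1, keepdims=True)
        noise *= np.sqrt(sig_var / (snr_lin * inband_var))
        samples = sig + noise
    else:
        samples = sig
    rec = MultichannelRecording(
        samples,
        spec.fs,
        subject_id=f"sub{subject_index:02d}",
        stimulus_id=env.stimulus_id,
    )
    return rec, env, trf


def prepare_subject(
    spec: SimulationSpec, subject_index: int
) -> tuple[PreprocessedRecording, np.ndarray]:
    """Simulate one subject and run the split/normalize/window stages."""
    rec, env, trf = simulate_subject(spec, subject_index)
    splits = split_recording(rec, env, spec.split)
    eeg_stats = fit_normalization(splits["train"].eeg)
    env_stats = fit_normalization(splits["train"].envelope[None, :])
    sets = {}
    for name, seg in splits.items():
        sets[name] = make_windows(
            apply_normalization(eeg_stats, seg.eeg),
            apply_normalization(env_stats, seg.envelope[None, :])[0],
            spec.fs,
            window_s=spec.window_s,
            overlap=spec.overlap,
            subject_id=rec.subject_id,
            stimulus_id=rec.stimulus_id,
            start_offset=seg.start,
        )
    pre = PreprocessedRecording(
        train=sets["train"],
        val=sets["val"],
        test=sets["test"],
        eeg_stats=eeg_stats,
        env_stats=env_stats,
        fs=spec.fs,
        subject_id=rec.subject_id,
        stimulus_id=rec.stimulus_id,
    )
    return pre, trf


def make_dataset(spec: SimulationSpec, out_dir: str | Path | None = None) -> dict:
    """Simulate every subject; optionally write the on-disk container.

    Returns a manifest dictionary (and, under ``"subjects"``, the in-memory
    :class:`PreprocessedRecording` per subject when no ``out_dir`` is
    given).  On disk, each subject becomes one compressed-array file plus a
    shared JSON manifest; regeneration with the same spec is byte-stable.
    """
    from . import io as vio

    manifest = {
        "spec": spec.to_dict(),
        "subjects": {},
    }
    mem = {}
    for i in range(spec.n_subjects):
        pre, trf = prepare_subject(spec, i)
        entry = {
            "subject_id": pre.subject_id,
            "stimulus_id": pre.stimulus_id,
            "duration_s": spec.duration_s,
            "n_windows": {
                "train": pre.train.n_windows,
                "val": pre.val.n_windows,
                "test": pre.test.n_windows,
            },
        }
        if out_dir is not None:
            path = Path(out_dir) / f"{pre.subject_id}.npz"
            vio.write_preprocessed(path, pre, extra={"trf": trf})
            entry["file"] = path.name
        else:
            mem[pre.subject_id] = (pre, trf)
        manifest["subjects"][pre.subject_id] = entry
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    else:
        manifest["data"] = mem
    return manifest
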