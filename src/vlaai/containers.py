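"""Core in-memory containers shared across the pipeline.

All time-series containers store ``float64`` arrays with an explicit sampling
rate.  EEG-like data is ``(n_channels, n_samples)``; stimulus envelopes are
one-dimensional.  Windowed training data lives in :class:`WindowPairSet`,
whose arrays are ``(n_windows, window_samples, ...)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = [
    "MultichannelRecording",
    "EnvelopeSeries",
    "SplitSpec",
    "NormalizationStats",
    "WindowPairSet",
    "SubjectScore",
]


@dataclass
class MultichannelRecording:
    """A channels-by-time signal (EEG, or gammatone subbands).

    Parameters
    ----------
    samples
        Array of shape ``(n_channels, n_samples)``.
    fs
        Sampling rate in Hz, strictly positive.
    channel_labels
        One label per channel.
    subject_id, stimulus_id
        Free-form identifiers used to group evaluation scores.
    """

    samples: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)
    subject_id: str = ""
    stimulus_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2:
            raise ValueError(
                f"samples must be 2-D (n_channels, n_samples), got shape "
                f"{self.samples.shape}"
            )
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("recording contains non-finite samples")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.n_channels < 1:
            raise ValueError("recording must have at least one channel")
        if not self.channel_labels:
            self.channel_labels = [f"CH{i:03d}" for i in range(self.n_channels)]
        if len(self.channel_labels) != self.n_channels:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.n_channels} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def with_samples(self, samples: np.ndarray, fs: float | None = None) -> "MultichannelRecording":
        """Copy of this recording with new sample data (labels/ids kept)."""
        out = replace(self, samples=samples)
        if fs is not None:
            out.fs = fs
        return out


@dataclass
class EnvelopeSeries:
    """Single-channel stimulus envelope time series."""

    samples: np.ndarray
    fs: float
    stimulus_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64).ravel()
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("envelope contains non-finite samples")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True)
class SplitSpec:
    """Train/validation/test fractions of a recording.

    The validation and test segments are cut from the middle of the recording
    (recordings tend to carry artifacts at their edges); the training set is
    the concatenation of the leading and trailing remainder.
    """

    train_fraction: float = 0.8
    val_fraction: float = 0.1
    test_fraction: float = 0.1

    def __post_init__(self) -> None:
        fracs = (self.train_fraction, self.val_fraction, self.test_fraction)
        if any(f <= 0 for f in fracs):
            raise ValueError(f"all split fractions must be positive, got {fracs}")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {sum(fracs)}")


@dataclass
class NormalizationStats:
    """Per-channel centering and scaling parameters, fitted on training data.

    ``scale_kind`` selects what the per-channel data is divided by: ``"std"``
    (unit variance after scaling, the default) or ``"variance"``.
    """

    mean: np.ndarray
    scale: np.ndarray
    scale_kind: str = "std"

    def __post_init__(self) -> None:
        self.mean = np.atleast_1d(np.asarray(self.mean, dtype=np.float64))
        self.scale = np.atleast_1d(np.asarray(self.scale, dtype=np.float64))
        if self.scale_kind not in ("std", "variance"):
            raise ValueError(f"scale_kind must be 'std' or 'variance', got {self.scale_kind!r}")
        if self.mean.shape != self.scale.shape:
            raise ValueError("mean and scale must have matching shapes")
        if np.any(self.scale <= 0):
            bad = np.flatnonzero(self.scale <= 0)
            raise ValueError(f"non-positive scale for channel(s) {bad.tolist()}")


@dataclass
class WindowPairSet:
    """Aligned fixed-length (EEG window, envelope window) pairs.

    Attributes
    ----------
    eeg
        ``(n_windows, window_samples, n_channels)``.
    envelope
        ``(n_windows, window_samples)``.
    fs
        Sampling rate of the windows in Hz.
    start_samples
        Start index of each window in its source recording.
    subject_ids, stimulus_ids
        Per-window provenance labels (length ``n_windows``).
    too_short
        True when the source recording was shorter than one window and the
        set is consequently empty.
    """

    eeg: np.ndarray
    envelope: np.ndarray
    fs: float
    start_samples: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    subject_ids: list[str] = field(default_factory=list)
    stimulus_ids: list[str] = field(default_factory=list)
    too_short: bool = False

    def __post_init__(self) -> None:
        self.eeg = np.asarray(self.eeg, dtype=np.float64)
        self.envelope = np.asarray(self.envelope, dtype=np.float64)
        if self.eeg.ndim != 3 or self.envelope.ndim != 2:
            raise ValueError("eeg must be 3-D and envelope 2-D")
        if self.eeg.shape[:2] != self.envelope.shape:
            raise ValueError(
                f"window shapes disagree: eeg {self.eeg.shape}, envelope {self.envelope.shape}"
            )
        n = self.n_windows
        if len(self.start_samples) == 0:
            self.start_samples = np.zeros(n, dtype=int)
        self.start_samples = np.asarray(self.start_samples, dtype=int)
        if not self.subject_ids:
            self.subject_ids = [""] * n
        if not self.stimulus_ids:
            self.stimulus_ids = [""] * n

    @property
    def n_windows(self) -> int:
        return self.eeg.shape[0]

    @property
    def window_samples(self) -> int:
        return self.eeg.shape[1]

    @property
    def n_channels(self) -> int:
        return self.eeg.shape[2]

    def subset(self, idx) -> "WindowPairSet":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return WindowPairSet(
            eeg=self.eeg[idx],
            envelope=self.envelope[idx],
            fs=self.fs,
            start_samples=self.start_samples[idx],
            subject_ids=[self.subject_ids[i] for i in idx],
            stimulus_ids=[self.stimulus_ids[i] for i in idx],
        )

    @staticmethod
    def concatenate(sets: list["WindowPairSet"]) -> "WindowPairSet":
        sets = [s for s in sets if s.n_windows > 0]
        if not sets:
            raise ValueError("nothing to concatenate")
        fs = sets[0].fs
        if any(s.fs != fs for s in sets):
            raise ValueError("window sets have mismatched sampling rates")
        return WindowPairSet(
            eeg=np.concatenate([s.eeg for s in sets], axis=0),
            envelope=np.concatenate([s.envelope for s in sets], axis=0),
            fs=fs,
            start_samples=np.concatenate([s.start_samples for s in sets]),
            subject_ids=sum((s.subject_ids for s in sets), []),
            stimulus_ids=sum((s.stimulus_ids for s in sets), []),
        )


@dataclass
class SubjectScore:
    """Per-subject reconstruction correlations.

    ``per_stimulus`` maps stimulus id to the mean window correlation for that
    stimulus; ``score`` is the mean over stimuli.  ``n_excluded`` counts
    windows whose correlation was undefined (zero-variance prediction) and
    were dropped from the averages.
    """

    subject_id: str
    per_stimulus: Mapping[str, float]
    score: float
    n_excluded: int = 0
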