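import numpy as np
import pytest

from vlaai.containers import WindowPairSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def linear_window_set(
    rng: np.random.Generator,
    n_windows: int = 40,
    T: int = 320,
    n_channels: int = 4,
    n_lags: int = 8,
    noise: float = 0.0,
    fs: float = 64.0,
    subject_id: str = "sub00",
    stimulus_id: str = "stim00",
) -> tuple[WindowPairSet, np.ndarray]:
    """Windows where the envelope is an exact lagged linear readout of EEG.

    Returns the window set and the generating decoder weights
    ``(n_lags, n_channels)`` — the system is constructed backward (envelope
    from EEG), so those weights are identifiable by regression.
    """
    w = rng.standard_normal((n_lags, n_channels))
    eeg = rng.standard_normal((n_windows, T, n_channels))
    env = np.zeros((n_windows, T))
    for j in range(n_lags):
        env[:, : T - j] += eeg[:, j:, :] @ w[j]
    if noise:
        env += noise * rng.standard_normal(env.shape)
    return (
        WindowPairSet(
            eeg=eeg,
            envelope=env,
            fs=fs,
            start_samples=np.arange(n_windows) * T,
            subject_ids=[subject_id] * n_windows,
            stimulus_ids=[stimulus_id] * n_windows,
        ),
        w,
    )


@pytest.fixture
def linear_windows(rng):
    return linear_window_set(rng)
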