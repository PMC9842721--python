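"""Linear stimulus-reconstruction baselines.

Two variants of the classic backward model:

* a **subject-independent linear decoder** (500 ms integration window)
  trained by gradient descent on the negative-Pearson loss, exactly like the
  neural decoder, so the two are compared under identical training criteria;
* a **subject-specific ridge decoder** (250 ms integration window) solved in
  closed form over the lag-expanded design matrix, with a Laplacian
  (second-difference over lags) regularization matrix and the ridge strength
  selected on validation loss from a log-spaced grid.

Lag convention: the backward model reconstructs the envelope at time ``t``
from EEG samples ``t .. t + L - 1`` — the neural response *follows* the
stimulus, so stimulus reconstruction integrates post-stimulus EEG.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from . import nn
from .containers import WindowPairSet
from .model import DecoderModel

__all__ = [
    "LinearDecoderConfig",
    "LinearDecoderModel",
    "build_linear_decoder",
    "train_linear_si",
    "fit_ridge_decoder",
    "laplacian_penalty",
]


@dataclass
class LinearDecoderConfig:
    """Configuration shared by both linear decoder variants.

    ``integration_window_ms`` is converted to ``round(ms * fs / 1000)`` lags
    at build time.  ``ridge_grid`` is only used by the ridge variant.
    """

    integration_window_ms: float = 500.0
    ridge_grid: np.ndarray = field(default_factory=lambda: np.logspace(-7, 7, 15))
    laplacian_regularization: bool = True

    def __post_init__(self):
        if self.integration_window_ms <= 0:
            raise ValueError("integration window must be positive")
        g = np.asarray(self.ridge_grid, dtype=np.float64)
        if np.any(g <= 0) or np.any(np.diff(g) <= 0):
            raise ValueError("ridge grid must be strictly positive and increasing")
        self.ridge_grid = g

    def n_lags(self, fs: float) -> int:
        return int(round(self.integration_window_ms * fs / 1000.0))


class LinearDecoderModel(DecoderModel):
    """``env[t] = sum_{c,j} w[j,c] * eeg[t+j, c] + bias`` for lags ``j < L``.

    Implemented as a single valid convolution whose input is end-padded with
    ``L - 1`` zeros, so the output length equals the input length (tail
    predictions use partially zero-padded context).
    """

    def __init__(self, n_channels: int, n_lags: int, fs: float, seed: int = 0, dtype=np.float64):
        if n_lags < 1:
            raise ValueError("need at least one lag")
        self.n_channels = n_channels
        self.n_lags = n_lags
        self.fs = fs
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        self._conv = nn.Conv1d(
            n_channels, 1, n_lags, rng, pad_end=n_lags - 1, dtype=dtype, name="linear_decoder"
        )
        self.ridge_lambda: float | None = None  # set when fitted in closed form
        self.config = {"n_channels": n_channels, "n_lags": n_lags, "fs": fs}

    def params(self):
        return self._conv.params()

    def forward(self, x: np.ndarray):
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim != 3:
            raise ValueError(f"expected (batch, time, channels), got {x.shape}")
        if x.shape[1] < self.n_lags:
            raise ValueError(
                f"integration window of {self.n_lags} samples exceeds input length {x.shape[1]}"
            )
        y, cache = self._conv.forward(x)
        return y[..., 0], cache

    def backward(self, dy: np.ndarray, tape):
        return self._conv.backward(np.asarray(dy, dtype=self.dtype)[..., None], tape)

    @property
    def weights(self) -> np.ndarray:
        """Decoder weights as ``(n_lags, n_channels)``."""
        return self._conv.w.value[..., 0]

    @property
    def bias(self) -> float:
        return float(self._conv.b.value[0])

    def set_weights(self, w: np.ndarray, bias: float = 0.0) -> None:
        w = np.asarray(w, dtype=self.dtype)
        if w.shape != (self.n_lags, self.n_channels):
            raise ValueError(f"expected weights of shape {(self.n_lags, self.n_channels)}")
        self._conv.w.value[...] = w[..., None]
        self._conv.b.value[...] = bias


def build_linear_decoder(
    config: LinearDecoderConfig, n_channels: int, fs: float = 64.0, seed: int = 0
) -> LinearDecoderModel:
    return LinearDecoderModel(n_channels, config.n_lags(fs), fs, seed=seed)


def train_linear_si(
    decoder: LinearDecoderModel,
    train: WindowPairSet,
    val: WindowPairSet,
    learning_rate: float = 1e-3,
    batch_size: int = 64,
    seed: int = 0,
    max_epochs: int = 100,
):
    """Train the subject-independent linear decoder with Adam.

    Negative Pearson r loss on 5 s windows, learning rate 1e-3, batch size
    64, early stopping on validation loss — the same recipe as the neural
    decoder.  Returns ``(decoder, history)``.
    """
    from .training import TrainingConfig
    from .training import train as train_loop

    cfg = TrainingConfig(
        learning_rate=learning_rate, batch_size=batch_size, seed=seed, max_epochs=max_epochs
    )
    return train_loop(decoder, train, val, cfg)


def laplacian_penalty(n_lags: int, n_channels: int) -> np.ndarray:
    """Graph-Laplacian smoothness penalty over lags, identical per channel.

    For the path graph over adjacent lags: diagonal ``[1, 2, .., 2, 1]``,
    off-diagonal -1.  Penalizes squared first differences of the weight
    profile along the lag axis, leaving channels uncoupled.
    """
    lap = 2.0 * np.eye(n_lags) - np.eye(n_lags, k=1) - np.eye(n_lags, k=-1)
    lap[0, 0] = lap[-1, -1] = 1.0
    return scipy.linalg.block_diag(*([lap] * n_channels))


def _design_rows(eeg: np.ndarray, env: np.ndarray, n_lags: int):
    """Lag-expand one continuous (time, channels) segment with end truncation.

    Returns ``X`` of shape ``(n - L + 1, L * C)`` with columns ordered
    channel-major (``c * L + j``), and the matching target vector.
    """
    n, C = eeg.shape
    if n < n_lags:
        raise ValueError("segment shorter than the integration window")
    sw = np.lib.stride_tricks.sliding_window_view(eeg, n_lags, axis=0)  # (n-L+1, C, L)
    X = sw.reshape(n - n_lags + 1, C * n_lags)
    return X, env[: n - n_lags + 1]


def fit_ridge_decoder(
    train: WindowPairSet | tuple[np.ndarray, np.ndarray],
    val: WindowPairSet,
    config: LinearDecoderConfig | None = None,
    fs: float = 64.0,
    selection_tolerance: float = 1e-4,
) -> tuple[LinearDecoderModel, dict]:
    """Closed-form ridge decoder with validation-based grid selection.

    ``train`` may be a :class:`WindowPairSet` (each window lag-expanded with
    end truncation, no cross-window leakage) or a continuous
    ``(eeg (time, channels), env (time,))`` pair.  For each of the grid's
    ridge values the penalized normal equations are solved and scored by
    validation loss (negative Pearson r on the validation windows).  Among
    models within ``selection_tolerance`` of the lowest validation loss the
    most regularized one is returned (ties toward parsimony: on
    near-noise-free data many ridge values fit equally well and the
    under-regularized solutions have poorly determined weights), together
    with a report of per-lambda losses.
    """
    if config is None:
        config = LinearDecoderConfig(integration_window_ms=250.0)
    if isinstance(train, WindowPairSet):
        fs = train.fs
        segments = [(train.eeg[i], train.envelope[i]) for i in range(train.n_windows)]
        n_channels = train.n_channels
    else:
        eeg, env = train
        eeg = np.asarray(eeg, dtype=np.float64)
        if eeg.ndim != 2:
            raise ValueError("continuous EEG must be (time, channels)")
        segments = [(eeg, np.asarray(env, dtype=np.float64))]
        n_channels = eeg.shape[1]
    L = config.n_lags(fs)
    D = L * n_channels

    G = np.zeros((D, D))
    bvec = np.zeros(D)
    sx = np.zeros(D)
    sy = 0.0
    n_rows = 0
    for seg_eeg, seg_env in segments:
        X, y = _design_rows(np.asarray(seg_eeg, np.float64), np.asarray(seg_env, np.float64), L)
        G += X.T @ X
        bvec += X.T @ y
        sx += X.sum(axis=0)
        sy += y.sum()
        n_rows += X.shape[0]
    # center via the accumulated sums (equivalent to centering X and y)
    mx = sx / n_rows
    my = sy / n_rows
    Gc = G - np.outer(mx, sx) - np.outer(sx, mx) + n_rows * np.outer(mx, mx)
    bc = bvec - mx * sy - sx * my + n_rows * mx * my

    if config.laplacian_regularization:
        # The pure second-difference penalty leaves each channel's constant
        # lag-profile unpenalized; on degenerate (e.g. noise-free,
        # strongly band-limited) designs those directions can also carry no
        # data energy, making the problem singular at every ridge value.  A
        # small identity admixture keeps the estimator well-posed without
        # noticeably changing the smoothing behaviour.
        R = laplacian_penalty(L, n_channels) + 1e-6 * np.eye(D)
    else:
        R = np.eye(D)

    from . import nn

    def truncated_val_loss(model: LinearDecoderModel) -> float:
        # score only the lag-complete region of each window, matching the
        # end-truncated fitting convention (the final L-1 samples of a
        # window are predicted from zero-padded context)
        pred = model.predict(val.eeg)[:, : val.window_samples - L + 1]
        target = val.envelope[:, : val.window_samples - L + 1]
        r = nn.pearson_batch(np.asarray(pred, np.float64), target)
        r = r[np.isfinite(r)]
        if r.size == 0:
            raise ValueError("no validation window had a defined correlation")
        return float(-r.mean())

    report = {"lambdas": [], "val_loss": []}
    fitted: list[tuple[float, float, LinearDecoderModel]] = []
    for lam in config.ridge_grid:
        try:
            cho = scipy.linalg.cho_factor(Gc + lam * R)
        except np.linalg.LinAlgError:
            # numerically singular at this ridge strength; larger grid
            # values will regularize it
            report["lambdas"].append(float(lam))
            report["val_loss"].append(np.inf)
            continue
        w = scipy.linalg.cho_solve(cho, bc)
        model = LinearDecoderModel(n_channels, L, fs)
        model.set_weights(w.reshape(n_channels, L).T, bias=my - float(mx @ w))
        loss = truncated_val_loss(model)
        report["lambdas"].append(float(lam))
        report["val_loss"].append(loss)
        fitted.append((float(lam), loss, model))
    if not fitted:
        raise np.linalg.LinAlgError(
            "penalized design singular for every ridge value on the grid; "
            "use nonzero (larger) ridge values"
        )
    best_loss = min(loss for _, loss, _ in fitted)
    lam, _, model = max(
        (t for t in fitted if t[1] <= best_loss + selection_tolerance), key=lambda t: t[0]
    )
    model.ridge_lambda = lam
    report["selected_lambda"] = lam
    return model, report
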