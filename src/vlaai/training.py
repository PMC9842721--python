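"""Training loop, negative-Pearson loss, early stopping, and finetuning.

Decoders are trained on overlapping fixed-length windows with Adam and a
negative Pearson correlation loss (the correlation is computed per window
and averaged over the batch).  Early stopping watches the validation loss
with a patience of 5 epochs and a minimum improvement of 1e-4, and the
parameters from the best validation epoch are restored.

Subject-specific finetuning continues training a subject-independent
decoder on one subject's data with batch size 1 and a learning rate of
1e-4, optionally on a fixed budget of data (in minutes) drawn uniformly
across the subject's recording.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .containers import WindowPairSet
from .model import DecoderModel

__all__ = [
    "TrainingConfig",
    "FinetuneConfig",
    "EarlyStopper",
    "pearson_loss",
    "train",
    "finetune",
    "select_uniform_minutes",
]


@dataclass
class TrainingConfig:
    """Hyperparameters of the Adam training loop."""

    learning_rate: float = 1e-3
    batch_size: int = 64
    patience: int = 5
    min_delta: float = 1e-4
    max_epochs: int = 100
    seed: int = 0
    shuffle: bool = True

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.min_delta < 0:
            raise ValueError("min_delta must be >= 0")


@dataclass
class FinetuneConfig:
    """Hyperparameters for subject-specific finetuning.

    ``minutes_of_data`` limits the unique signal duration used, taken
    uniformly across the subject's training windows; ``None`` uses all data.
    ``freeze`` lists parameter-name prefixes excluded from updates (all
    layers train by default).
    """

    learning_rate: float = 1e-4
    batch_size: int = 1
    minutes_of_data: float | None = None
    patience: int = 5
    min_delta: float = 1e-4
    max_epochs: int = 100
    seed: int = 0
    freeze: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.minutes_of_data is not None and self.minutes_of_data <= 0:
            raise ValueError("minutes_of_data must be positive")


class EarlyStopper:
    """Stop when the monitored loss fails to improve by ``min_delta``
    for ``patience`` consecutive epochs; remembers the best epoch."""

    def __init__(self, patience: int = 5, min_delta: float = 1e-4):
        self.patience = patience
        self.min_delta = min_delta
        self.best = np.inf
        self.best_epoch = -1
        self._bad = 0

    def update(self, loss: float, epoch: int) -> bool:
        """Record this epoch's loss; return True when training should stop."""
        if loss < self.best - self.min_delta:
            self.best = loss
            self.best_epoch = epoch
            self._bad = 0
        else:
            # still track the strict best for weight restoration
            if loss < self.best:
                self.best = loss
                self.best_epoch = epoch
            self._bad += 1
        return self._bad >= self.patience


def pearson_loss(pred: np.ndarray, target: np.ndarray) -> float:
    """Negative Pearson correlation, averaged over windows.

    1-D inputs are treated as a single window.  Raises on zero-variance
    input, where the correlation is undefined.
    """
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.ndim == 1:
        pred, target = pred[None, :], target[None, :]
    loss, _ = nn.neg_pearson_loss(pred, target, grad=False)
    return loss


def _dataset_loss(model: DecoderModel, windows: WindowPairSet, batch_size: int = 64) -> float:
    losses = []
    for i in range(0, windows.n_windows, batch_size):
        y, _ = model.forward(windows.eeg[i : i + batch_size])
        loss, _ = nn.neg_pearson_loss(
            np.asarray(y, np.float64), windows.envelope[i : i + batch_size], grad=False
        )
        losses.append((loss, y.shape[0]))
    n = sum(k for _, k in losses)
    return float(sum(l * k for l, k in losses) / n)


def train(
    model: DecoderModel,
    train_windows: WindowPairSet,
    val_windows: WindowPairSet,
    config: TrainingConfig | None = None,
    callbacks=None,
) -> tuple[DecoderModel, dict]:
    """Train a decoder with Adam + negative Pearson loss + early stopping.

    Returns ``(model, history)``; the model carries the parameters of the
    epoch with the lowest validation loss.  ``history`` holds per-epoch
    train/val losses and the best epoch index.  Fully reproducible for a
    fixed ``config.seed``.
    """
    config = config or TrainingConfig()
    if train_windows.n_windows == 0:
        raise ValueError("training set is empty")
    if val_windows.n_windows == 0:
        raise ValueError("validation set is empty")
    rng = np.random.default_rng(config.seed)
    trainable = [p for p in model.params() if not _frozen(p, getattr(config, "freeze", []))]
    opt = nn.Adam(trainable, lr=config.learning_rate)
    stopper = EarlyStopper(config.patience, config.min_delta)
    history: dict = {"train_loss": [], "val_loss": []}
    best_state = {k: v.copy() for k, v in model.state_arrays().items()}
    n = train_windows.n_windows
    for epoch in range(config.max_epochs):
        order = rng.permutation(n) if config.shuffle else np.arange(n)
        ep_losses = []
        for i in range(0, n, config.batch_size):
            idx = order[i : i + config.batch_size]
            x = train_windows.eeg[idx]
            t = train_windows.envelope[idx]
            y, tape = model.forward(x)
            if not np.all(np.isfinite(y)):
                raise RuntimeError(
                    f"non-finite predictions at epoch {epoch}, batch starting at "
                    f"window {i}; check input scaling / learning rate"
                )
            loss, dy = nn.neg_pearson_loss(np.asarray(y, np.float64), t)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss ({loss}) at epoch {epoch}, "
                    f"batch starting at window {i}; check input scaling / learning rate"
                )
            opt.zero_grad()
            model.backward(dy, tape)
            opt.step()
            ep_losses.append(loss)
        val_loss = _dataset_loss(model, val_windows)
        if not np.isfinite(val_loss):
            raise RuntimeError(f"non-finite validation loss at epoch {epoch}")
        history["train_loss"].append(float(np.mean(ep_losses)))
        history["val_loss"].append(val_loss)
        if callbacks:
            for cb in callbacks:
                cb(epoch, history)
        improved = val_loss <= stopper.best
        stop = stopper.update(val_loss, epoch)
        if improved:
            best_state = {k: v.copy() for k, v in model.state_arrays().items()}
        if stop:
            break
    model.load_state_arrays(best_state)
    history["best_epoch"] = stopper.best_epoch
    history["best_val_loss"] = stopper.best
    return model, history


def _frozen(p: nn.Parameter, prefixes: list[str]) -> bool:
    return any(p.name.startswith(pre) for pre in prefixes)


def select_uniform_minutes(
    windows: WindowPairSet, minutes: float, window_s: float | None = None
) -> WindowPairSet:
    """Pick windows whose unique coverage totals ``minutes``, spread
    uniformly across the recording.

    Windows overlap, so the subset is chosen by evenly spaced source start
    times; the number of windows is ``minutes * 60 / window_s`` (each kept
    window contributes one window length of unique signal when the selected
    starts are at least one window apart).
    """
    if windows.n_windows == 0:
        raise ValueError("no windows to select from")
    if window_s is None:
        window_s = windows.window_samples / windows.fs
    span_s = (windows.start_samples.max() - windows.start_samples.min()) / windows.fs + window_s
    if minutes * 60.0 > span_s + 1e-9:
        raise ValueError(
            f"requested {minutes} min but only {span_s / 60:.2f} min of data available"
        )
    k = max(1, int(round(minutes * 60.0 / window_s)))
    k = min(k, windows.n_windows)
    order = np.argsort(windows.start_samples)
    pick = np.unique(np.round(np.linspace(0, windows.n_windows - 1, k)).astype(int))
    return windows.subset(order[pick])


def finetune(
    model: DecoderModel,
    subject_train: WindowPairSet,
    subject_val: WindowPairSet,
    config: FinetuneConfig | None = None,
) -> tuple[DecoderModel, dict]:
    """Turn a subject-independent decoder into a subject-specific one.

    Works on a copy — the input model is left unmodified.  Applies the same
    early-stopping rule as :func:`train` with the finetuning hyperparameters
    (batch size 1, learning rate 1e-4 by default).
    """
    config = config or FinetuneConfig()
    tuned = model.copy()
    if config.max_epochs == 0:
        return tuned, {"train_loss": [], "val_loss": [], "best_epoch": -1}
    data = subject_train
    if config.minutes_of_data is not None:
        data = select_uniform_minutes(subject_train, config.minutes_of_data)
    tcfg = TrainingConfig(
        learning_rate=config.learning_rate,
        batch_size=config.batch_size,
        patience=config.patience,
        min_delta=config.min_delta,
        max_epochs=config.max_epochs,
        seed=config.seed,
    )
    tcfg.freeze = list(config.freeze)  # type: ignore[attr-defined]
    return train(tuned, data, subject_val, tcfg)
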