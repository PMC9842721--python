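"""The VLAAI envelope decoder and its ablation variants.

The network maps 64-channel EEG ``(batch, time, channels)`` to a
reconstructed speech envelope ``(batch, time)``.  It stacks ``N`` blocks,
each made of three parts:

1. **CNN stack** — ``M`` valid convolutions (kernel ``K``), each followed by
   layer normalization and LeakyReLU; ``K - 1`` zeros of end-padding keep
   the time dimension equal to the input's.  Because the valid convolution
   consumes *later* samples, each conv layer looks ``K - 1`` samples into
   the future.
2. **Recombination layer** — a per-time-step dense layer (default 64 units)
   that recombines the CNN-stack filters.
3. **Output context layer** — a strictly causal convolution (kernel ``OC``,
   input front-padded with ``OC - 1`` zeros) followed by LeakyReLU and layer
   normalization; it refines the current prediction from the preceding
   context.

After every block except the last, the original EEG input is added back
(skip connection).  A final per-time-step linear layer collapses the output
context filters to the single envelope channel.  The CNN stack and the
output context layer share weights across blocks; the recombination layers
are per-block.

The maximal receptive field of one block is ``(-(OC - 1), (K - 1) * M)``
(past, future) samples, and the full network's is ``N`` times that; for the
default configuration (N=4, M=5, K=8, OC=32) this is (-124, 140) samples =
(-1.94, 2.19) s at 64 Hz.  :func:`receptive_field` evaluates the formula and
:func:`probe_receptive_field` measures it empirically on a built model.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn

__all__ = [
    "VlaaiConfig",
    "ReceptiveField",
    "DecoderModel",
    "VlaaiNetwork",
    "build_vlaai",
    "build_output_context_layer",
    "receptive_field",
    "probe_receptive_field",
    "build_ablation_variant",
    "ABLATION_STEPS",
]


@dataclass
class VlaaiConfig:
    """All architecture hyperparameters of the decoder."""

    n_blocks: int = 4
    conv_layers_per_block: int = 5
    kernel_size: int = 8
    conv_filters: list[int] = field(default_factory=lambda: [256, 256, 256, 128, 128])
    recombination_units: int = 64
    output_context: int = 32
    output_context_filters: int = 64
    leaky_slope: float = 0.3
    use_skip: bool = True
    use_output_context: bool = True
    share_weights: bool = True
    n_input_channels: int = 64

    def __post_init__(self) -> None:
        if self.n_blocks < 1:
            raise ValueError(f"n_blocks must be >= 1, got {self.n_blocks}")
        if self.conv_layers_per_block != len(self.conv_filters):
            raise ValueError(
                f"conv_layers_per_block={self.conv_layers_per_block} but "
                f"{len(self.conv_filters)} filter counts given"
            )
        if self.kernel_size < 1:
            raise ValueError("kernel_size must be >= 1")
        if self.output_context < 1:
            raise ValueError("output_context must be >= 1")
        if self.use_skip and self.n_blocks > 1:
            block_out = (
                self.output_context_filters if self.use_output_context else self.recombination_units
            )
            if block_out != self.n_input_channels:
                raise ValueError(
                    "skip connections add the EEG input to the block output: "
                    f"the block output width ({block_out}) must equal "
                    f"n_input_channels ({self.n_input_channels})"
                )

    def to_dict(self) -> dict:
        return asdict(self)

    @staticmethod
    def from_dict(d: dict) -> "VlaaiConfig":
        return VlaaiConfig(**d)


@dataclass(frozen=True)
class ReceptiveField:
    """Input offset range (past <= 0, future >= 0) influencing one output."""

    past: int
    future: int

    def __post_init__(self):
        if not (self.past <= 0 <= self.future):
            raise ValueError(f"need past <= 0 <= future, got ({self.past}, {self.future})")

    def seconds(self, fs: float) -> tuple[float, float]:
        return (self.past / fs, self.future / fs)


class DecoderModel:
    """Base interface: a trainable map from EEG windows to envelope windows.

    Subclasses implement ``forward`` (returning output and a backward tape)
    and ``backward``; ``predict`` is the inference entry point.  Output time
    length always equals input time length.
    """

    config: object

    def params(self) -> list[nn.Parameter]:
        raise NotImplementedError

    def forward(self, x: np.ndarray):
        raise NotImplementedError

    def backward(self, dy: np.ndarray, tape) -> np.ndarray:
        raise NotImplementedError

    def predict(self, eeg_windows: np.ndarray, batch_size: int = 64) -> np.ndarray:
        """Reconstruct envelopes for ``(n_windows, T, n_channels)`` EEG."""
        x = np.asarray(eeg_windows)
        out = []
        for i in range(0, x.shape[0], batch_size):
            y, _ = self.forward(x[i : i + batch_size])
            out.append(y)
        return np.concatenate(out, axis=0)

    @property
    def n_parameters(self) -> int:
        seen, total = set(), 0
        for p in self.params():
            if id(p) not in seen:
                seen.add(id(p))
                total += p.size
        return total

    def copy(self) -> "DecoderModel":
        return copy.deepcopy(self)

    def state_arrays(self) -> dict[str, np.ndarray]:
        """Unique parameter arrays keyed by stable names (for checkpoints)."""
        out, seen = {}, set()
        i = 0
        for p in self.params():
            if id(p) in seen:
                continue
            seen.add(id(p))
            out[f"{i:03d}:{p.name}"] = p.value
            i += 1
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        mine = self.state_arrays()
        if sorted(mine) != sorted(arrays):
            raise ValueError("checkpoint parameter names do not match this model")
        seen = set()
        uniq = []
        for p in self.params():
            if id(p) not in seen:
                seen.add(id(p))
                uniq.append(p)
        for key, p in zip(sorted(mine), uniq):
            if arrays[key].shape != p.value.shape:
                raise ValueError(f"shape mismatch for {key}")
            p.value[...] = arrays[key]


def _conv_block_layer(cfg: VlaaiConfig, c_in: int, c_out: int, rng, dtype, name) -> nn.Sequential:
    """One CNN-stack layer: forward-looking conv -> layer norm -> LeakyReLU.

    The convolution is valid with ``K - 1`` zeros appended to its input, so
    the time dimension is preserved for any input length (down to a single
    sample) and output ``t`` integrates inputs ``t .. t + K - 1``.
    """
    return nn.Sequential(
        [
            nn.Conv1d(
                c_in, c_out, cfg.kernel_size, rng, pad_end=cfg.kernel_size - 1,
                dtype=dtype, name=name,
            ),
            nn.LayerNorm(c_out, dtype=dtype, name=f"{name}.ln"),
            nn.LeakyReLU(cfg.leaky_slope),
        ]
    )


def build_output_context_layer(
    config: VlaaiConfig, rng: np.random.Generator | None = None, dtype=np.float32
) -> nn.Sequential:
    """Strictly causal context layer: front-padded conv -> LeakyReLU -> LN.

    The input is front-padded with ``OC - 1`` zeros, so the output at time
    ``t`` depends only on inputs at times ``<= t``.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    oc = config.output_context
    return nn.Sequential(
        [
            nn.Conv1d(
                config.recombination_units,
                config.output_context_filters,
                oc,
                rng,
                pad_front=oc - 1,
                dtype=dtype,
                name="output_context",
            ),
            nn.LeakyReLU(config.leaky_slope),
            nn.LayerNorm(config.output_context_filters, dtype=dtype, name="output_context.ln"),
        ]
    )


class VlaaiNetwork(DecoderModel):
    """See the module docstring for the architecture."""

    def __init__(self, config: VlaaiConfig, seed: int = 0, dtype=np.float32):
        self.config = config
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        cfg = config
        N = cfg.n_blocks

        def make_cnn_stack():
            layers = []
            c_in = cfg.n_input_channels
            for li, c_out in enumerate(cfg.conv_filters):
                layers.append(_conv_block_layer(cfg, c_in, c_out, rng, dtype, f"cnn{li}"))
                c_in = c_out
            return nn.Sequential(layers)

        n_stacks = 1 if cfg.share_weights else N
        self._cnn_stacks = [make_cnn_stack() for _ in range(n_stacks)]

        # recombination: per-block dense layer; when there is no output
        # context layer it is omitted in the last block (the final linear
        # layer plays that role there).
        self._recombination: list[nn.Dense | None] = []
        for i in range(N):
            present = cfg.use_output_context or (i < N - 1)
            self._recombination.append(
                nn.Dense(
                    cfg.conv_filters[-1], cfg.recombination_units, rng, dtype=dtype, name=f"recomb{i}"
                )
                if present
                else None
            )

        if cfg.use_output_context:
            n_oc = 1 if cfg.share_weights else N
            self._oc_layers = [build_output_context_layer(cfg, rng, dtype) for _ in range(n_oc)]
            final_in = cfg.output_context_filters
        else:
            self._oc_layers = []
            final_in = cfg.conv_filters[-1]
        self._final = nn.Dense(final_in, 1, rng, dtype=dtype, name="final")

    # -- plumbing -----------------------------------------------------------
    def _cnn_stack(self, i: int) -> nn.Sequential:
        return self._cnn_stacks[0 if self.config.share_weights else i]

    def _oc_layer(self, i: int):
        if not self.config.use_output_context:
            return None
        return self._oc_layers[0 if self.config.share_weights else i]

    def params(self) -> list[nn.Parameter]:
        out = []
        for s in self._cnn_stacks:
            out.extend(s.params())
        for r in self._recombination:
            if r is not None:
                out.extend(r.params())
        for o in self._oc_layers:
            out.extend(o.params())
        out.extend(self._final.params())
        return out

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray):
        """``(B, T, C) -> ((B, T), tape)``."""
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim != 3:
            raise ValueError(f"expected (batch, time, channels), got shape {x.shape}")
        cfg = self.config
        tape = []
        h = x
        for i in range(cfg.n_blocks):
            stack = self._cnn_stack(i)
            h, c = stack.forward(h)
            tape.append(("layer", stack, c))
            rec = self._recombination[i]
            if rec is not None:
                h, c = rec.forward(h)
                tape.append(("layer", rec, c))
            oc = self._oc_layer(i)
            if oc is not None:
                h, c = oc.forward(h)
                tape.append(("layer", oc, c))
            if cfg.use_skip and i < cfg.n_blocks - 1:
                h = h + x
                tape.append(("skip", None, None))
        y, c = self._final.forward(h)
        tape.append(("layer", self._final, c))
        return y[..., 0], tape

    def backward(self, dy: np.ndarray, tape) -> np.ndarray:
        """Accumulate parameter gradients; returns d_loss/d_input."""
        dh = np.asarray(dy, dtype=self.dtype)[..., None]
        dx_skip = None
        for kind, layer, cache in reversed(tape):
            if kind == "skip":
                dx_skip = dh if dx_skip is None else dx_skip + dh
            else:
                dh = layer.backward(dh, cache)
        if dx_skip is not None:
            dh = dh + dx_skip
        return dh


def build_vlaai(
    config: VlaaiConfig | None = None, seed: int = 0, dtype=np.float32
) -> VlaaiNetwork:
    """Build a (randomly initialized) VLAAI decoder from a configuration."""
    return VlaaiNetwork(config or VlaaiConfig(), seed=seed, dtype=dtype)


def receptive_field(config: VlaaiConfig) -> ReceptiveField:
    """Maximal receptive field from the closed-form block formula.

    One block spans ``(-(OC - 1), (K - 1) * M)``; ``N`` stacked blocks scale
    both extents by ``N``.  Without the output context layer, ``OC`` acts
    as 1.
    """
    oc = config.output_context if config.use_output_context else 1
    past_b = -(oc - 1)
    future_b = (config.kernel_size - 1) * config.conv_layers_per_block
    return ReceptiveField(config.n_blocks * past_b, config.n_blocks * future_b)


def effective_receptive_field(config: VlaaiConfig, t: int, n_samples: int) -> ReceptiveField:
    """Receptive field at output index ``t`` of an ``n_samples`` segment.

    The maximal field is clipped to the available input range; e.g. at the
    first sample of a segment there is no past, so the past extent is 0.
    """
    rf = receptive_field(config)
    past = max(rf.past, -t)
    future = min(rf.future, n_samples - 1 - t)
    return ReceptiveField(past, future)


def probe_receptive_field(
    model: DecoderModel,
    T: int = 512,
    t_probe: int | None = None,
    n_probes: int = 2,
    seed: int = 0,
) -> ReceptiveField:
    """Measure the receptive field of a built model by sensitivity probing.

    Backpropagates a unit perturbation of the output at time ``t_probe``
    through the network and reports the extremal input offsets with nonzero
    sensitivity.  Offsets outside the true receptive field are *structural*
    zeros (no convolution tap ever reaches them), so strict nonzeroness is
    the correct criterion; averaging over ``n_probes`` random inputs guards
    against accidental cancellation, which has probability zero for random
    weights.
    """
    cfg = getattr(model, "config", None)
    if cfg is not None and isinstance(cfg, VlaaiConfig):
        rf = receptive_field(cfg)
        needed = rf.future - rf.past + 1
        if T < needed + 1:
            raise ValueError(f"T={T} too short to contain the receptive field ({needed} samples)")
        n_ch = cfg.n_input_channels
    else:
        n_ch = getattr(model, "n_channels", 1)
    if t_probe is None:
        t_probe = T // 2
    if not (0 <= t_probe < T):
        raise ValueError("probe index outside the segment")
    rng = np.random.default_rng(seed)
    sens = np.zeros(T)
    for _ in range(n_probes):
        x = rng.standard_normal((1, T, n_ch))
        y, tape = model.forward(x)
        dy = np.zeros_like(y)
        dy[0, t_probe] = 1.0
        dx = model.backward(dy, tape)
        sens += np.abs(np.asarray(dx[0], dtype=np.float64)).max(axis=-1)
    nz = np.flatnonzero(sens > 0)
    if nz.size == 0:
        return ReceptiveField(0, 0)
    return ReceptiveField(int(nz.min()) - t_probe, int(nz.max()) - t_probe)


#: step number -> description of the ablation ladder, from a small CNN up to
#: the full decoder.
ABLATION_STEPS = {
    1: "small CNN (M=2, kernel 20, 256 filters)",
    2: "larger CNN (M=5, kernel 8, [256,256,256,128,128])",
    3: "largest CNN (M=5, kernel 8, 512 filters everywhere)",
    4: "larger CNN, N=4 blocks",
    5: "larger CNN, N=4 blocks + skip connections",
    6: "full VLAAI (adds the output context layer)",
}


def build_ablation_variant(step: int, seed: int = 0, dtype=np.float32) -> VlaaiNetwork:
    """Build one rung of the complexity ladder used in the ablation analysis.

    Steps 1-3 are single-block CNNs of growing width/depth with a final
    linear read-out; step 4 stacks four blocks (with a per-block
    recombination layer that is absent in the last repetition); step 5 adds
    the skip connections; step 6 is the full decoder.
    """
    if step not in ABLATION_STEPS:
        raise ValueError(f"ablation step must be 1..6, got {step}")
    base = dict(n_input_channels=64, use_output_context=False, use_skip=False)
    if step == 1:
        cfg = VlaaiConfig(
            n_blocks=1, conv_layers_per_block=2, kernel_size=20,
            conv_filters=[256, 256], **base,
        )
    elif step == 2:
        cfg = VlaaiConfig(n_blocks=1, **base)
    elif step == 3:
        cfg = VlaaiConfig(n_blocks=1, conv_filters=[512] * 5, **base)
    elif step == 4:
        cfg = VlaaiConfig(n_blocks=4, **base)
    elif step == 5:
        base["use_skip"] = True
        cfg = VlaaiConfig(n_blocks=4, **base)
    else:
        cfg = VlaaiConfig()
    return VlaaiNetwork(cfg, seed=seed, dtype=dtype)
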