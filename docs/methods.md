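# Methods

This note documents the models, the numerical choices, and the synthetic
data that the test suite and `scripts/acceptance.py` rely on. Everything
stated here is computed by the package itself; nothing is quoted from
external runs.

## Problem setting

The package implements *backward* (stimulus-reconstruction) modelling of
continuous speech from EEG: given multichannel EEG `X` recorded while a
person listens to running speech, reconstruct the slow amplitude envelope
`s(t)` of that speech, and quantify reconstruction quality as the Pearson
correlation `r` between the reconstruction and the true envelope on 5 s
windows. Window correlations are averaged per stimulus, then per subject.
Backward models are the workhorse of neural-tracking research: `r` serves
as an objective index of how strongly a listener's cortex tracks speech.

## Preprocessing

* **Envelope extraction.** The stimulus waveform is passed through a
  gammatone filterbank: 28 filters, 4th-order, center frequencies from
  50 Hz to 5 kHz spaced equally on the Glasberg & Moore ERB-rate scale
  (both endpoints included). Each subband is rectified (absolute value)
  and compressed with exponent 0.6 (an approximation of loudness growth),
  and the 28 compressed subbands are averaged. The filters are realized
  as cascaded biquads (`tf2sos`); the direct polynomial form of an 8th
  order IIR is numerically fragile at low center-frequency/sampling-rate
  ratios (linearity errors of several percent at 50 Hz were observed
  before the change).
* **EEG filtering.** Zero-phase (forward-backward) 1st-order Butterworth
  high-pass at 0.5 Hz.
* **Resampling.** Polyphase FIR with a Kaiser(5.0) window and linear-trend
  edge padding, in two stages (native rate → 1024 Hz → 64 Hz), matching
  the common acquisition pipeline. Output length is `round(n·q)`.
* **Referencing.** Common-average re-referencing after the final
  downsampling.
* **Splits.** 80/10/10 train/validation/test; validation and test are
  contiguous segments cut from the middle of the recording (recordings
  carry artifacts at their edges), the training set is the leading plus
  trailing remainder.
* **Normalization.** Per-channel statistics fitted on the training split
  only and applied to all splits. Default scaling divides by the standard
  deviation (`scale_kind="std"`); division by the variance is available as
  `scale_kind="variance"` for compatibility with pipelines that use it.
  Unit variance is the conventional choice for training stability, and the
  Pearson evaluation is scale-invariant either way.
* **Windowing.** 5 s windows with 80% overlap (1 s hop); the trailing
  remainder is discarded.

## The VLAAI decoder

The network maps `(batch, time, 64 channels)` EEG to a `(batch, time)`
envelope and is built from `N = 4` blocks:

1. **CNN stack** — `M = 5` valid convolutions with kernel `K = 8` and
   filter counts `[256, 256, 256, 128, 128]`, each followed by layer
   normalization (over the filter axis, independently per time step,
   eps 1e-3) and LeakyReLU (slope 0.3). Each convolution's input is
   end-padded with `K − 1` zeros, so output length equals input length and
   output `t` integrates inputs `t … t+K−1` (the network looks *forward*
   in time, integrating the neural response that follows the stimulus).
2. **Recombination layer** — a per-time-step dense layer of 64 units.
3. **Output context layer** — a strictly causal convolution (kernel
   `OC = 32`, 64 filters, input front-padded with `OC − 1` zeros) followed
   by LeakyReLU and layer normalization; it refines the current prediction
   from the preceding 31 predictions.

After every block except the last, the original EEG input is added back
(skip connection); a final per-time-step linear layer collapses the 64
context filters into the envelope. The CNN stack and output context layer
share weights across blocks; the recombination layers are per-block.

**Receptive field.** One block spans `(-(OC-1), (K-1)·M)` = (−31, 35)
samples (past, future); `N` blocks scale both extents, giving (−124, 140)
samples = (−1.94, 2.19) s at 64 Hz for the default configuration. At a
segment boundary the field is clipped to the available samples (past
extent 0 at the first sample). `probe_receptive_field` verifies the
formula on a built model by backpropagating a unit output perturbation and
reading off the support of the input sensitivity; offsets outside the true
field are structural zeros, so exact nonzeroness is the decision rule.

**Boundary handling.** End-padding each convolution's *input* (rather
than appending zeros to its output) keeps the time dimension intact for
any input length — down to a single sample — at the cost of letting the
last `K − 1` outputs of each layer see partially zero-padded context. The
two conventions agree everywhere except those trailing samples.

**Numerics.** The network runs on a small NumPy layer core
(`vlaai.nn`) with explicit backward passes, verified against central
finite differences (relative error ≤ 1e-5 per parameter in float64).
Compute dtype defaults to float32 for throughput; convolutions use an
unfold-plus-GEMM path with a per-lag fallback when the unfolded input
would be large. Weights initialize Glorot-uniform from a seeded
generator; builds are bit-reproducible given the seed.

**Ablation ladder.** `build_ablation_variant(1..6)` reconstructs the
model-complexity ladder: a small 2-layer CNN (kernel 20, 256 filters), the
5-layer CNN, the 512-filter CNN, the multi-block version (per-block linear
layer absent in the last repetition), the same with skip connections, and
the full decoder. Skip connections add no parameters (steps 4 and 5 have
identical counts), and step 6 is parameter-identical to the default build.

## Linear baselines

* **Subject-independent linear decoder:** envelope at `t` is a weighted
  sum of EEG over all channels and lags `t … t + L − 1` with a 500 ms
  integration window (32 lags at 64 Hz), trained with Adam (lr 1e-3,
  batch 64) on the negative-Pearson loss — the same criterion as the
  network, so the comparison isolates the architecture.
* **Subject-specific ridge decoder:** closed-form penalized least squares
  over the lag-expanded design (250 ms window by default), with a
  Laplacian (squared first-difference over lags) penalty plus a 1e-6
  identity admixture; the pure Laplacian leaves each channel's constant
  lag profile unpenalized, which makes noise-free, band-limited designs
  singular at every ridge value. Fifteen ridge strengths are sampled
  log-uniformly from 1e-7 to 1e7; among models within 1e-4 of the lowest
  validation loss the most regularized one is selected (on nearly
  noise-free data many strengths fit equally well and under-regularized
  solutions have poorly determined weights). The selection loss is
  computed on the lag-complete region of each validation window,
  consistent with the end-truncated fitting convention.
* **Lag direction.** Stimulus reconstruction integrates *post-stimulus*
  EEG: the decoder at time `t` uses samples `t … t + L − 1`. Within a
  window the final `L − 1` predictions use zero-padded context.

## Training

Adam (lr 1e-3, batch 64) on the negative mean per-window Pearson
correlation; early stopping on validation loss with patience 5 and minimum
delta 1e-4; the parameters of the best validation epoch are restored. A
cap of 100 epochs bounds runtime. Finetuning continues training on one
subject with batch size 1 and lr 1e-4; when a data budget (in minutes) is
given, windows are selected at evenly spaced source positions so the
subset covers the recording uniformly. All layers finetune by default; a
`freeze` list of parameter-name prefixes is available.

## Evaluation statistics

Two-sided Wilcoxon signed-rank tests on paired per-subject scores (exact
null for n ≤ 25, normal approximation with continuity correction above;
zero differences dropped; all-zero difference vectors return p = 1), with
Holm-Bonferroni correction over the declared family of comparisons. The
subjects-vs-performance relationship is summarized by least-squares
fitting `r(x) = tanh(x/a)^b` (positivity enforced by optimizing log a,
log b; initialized at `a = median(x)`, `b = 1`).

## Synthetic data

Each EEG channel is a lagged linear response to the stimulus envelope —
a per-channel temporal response function (TRF) over lags 0–500 ms —
optionally applied to a statically transformed envelope, plus additive
noise:

```
EEG_c = TRF_c * f(envelope) + noise_c
```

* **Envelope surrogate:** low-pass-filtered (8th-order Butterworth,
  5 Hz, zero-phase) rectified white noise — nonnegative and smooth, with
  modulation energy concentrated far below 10 Hz as in real speech
  envelopes. `cutoff_hz=None` yields the unfiltered (spectrally flat)
  surrogate used by identifiability and closed-form checks.
* **TRFs:** damped-cosine kernels with channel-specific latency, width,
  frequency and signed amplitude (`"smooth"`), or single impulses at
  channel-specific lags (`"lagged_impulses"`, an exactly invertible lagged
  mixture). Per-subject variation adds a smooth perturbation of relative
  size `subject_jitter` to the shared kernels.
* **Nonlinearities:** `none`; `compressive_power(p)` — the standardized
  (nonnegative) envelope raised to `p`; `saturating_tanh(g)` —
  `tanh(g·z)` of the centered standardized envelope. Power laws with
  `p > 1` are expansive: they emphasize envelope peaks (akin to the onset
  dominance of evoked responses) while remaining invertible, which is the
  property the model-ordering experiment exploits (see below).
* **SNR convention:** `snr_db` is the *in-band* SNR — signal variance
  divided by the noise variance inside the envelope's modulation band.
  Out-of-band noise is removable by linear filtering, so under this
  convention the best achievable linear reconstruction correlation for
  white noise and linear encoding is `r = sqrt(snr/(1+snr))` independent
  of the noise bandwidth; that closed form anchors the SNR-ceiling test.
  The band is defined by the same 5 Hz filter that shapes the envelope;
  with the flat envelope variant, in-band and broadband coincide.
* **Noise:** white (default, analytically tractable) or 1/f-shaped pink.

What the simulator deliberately omits: volume conduction, rhythmic
background EEG (alpha), eyeblink and movement artifacts, nonstationarity,
and real speech statistics. Tests that pass on this data show that the
algorithms are implemented correctly and behave as theory predicts under
the generative assumptions — not that any particular correlation level
will be reached on real recordings.

## The scaled-down model-ordering experiment

Dataset-scale results (tens of subjects, >100 h of EEG) are out of reach
on a desk, so the headline ordering is reproduced as a property at small
scale: 8 simulated training subjects (90 s each, 32-channel EEG — a
common montage; channel count also sets the quadratic cost of the output
context layer), an unseen 9th subject (480 s), smooth TRFs with jitter
0.2, in-band SNR 0 dB, and an expansive power-law encoding (`p = 4`).

The expansive encoding is the key design choice. A saturating
nonlinearity *destroys* information about envelope peaks, so under noise
no decoder — linear or not — can recover it, and the nonlinear advantage
shrinks to a reshaping effect of a few hundredths of `r`. An invertible
expansive encoding preserves the information but hides it from any linear
read-out; a decoder with pointwise nonlinearities can learn the
compressive inverse. Under these conditions the reduced decoder (N=2,
filters [64,64,64,32,32], recombination and context widths equal to the
channel count) beats the subject-independent linear decoder by ≈ 0.05
Pearson r on the unseen subject (5-seed median; the acceptance threshold
is 0.03). Finetuning is probed on a strongly individual subject (jitter
0.5) with 5 minutes of data: scores typically rise and, thanks to
best-weight restoration, essentially never fall.

Training lengths in the experiment (10 epochs for the network, 30 for the
linear decoder, 8 finetuning epochs, early stopping throughout) are the
package's desk-scale choices; they leave the network slightly short of
its asymptote, which makes the measured margin conservative.

## Known limitations

* The NumPy training core is single-threaded BLAS-bound; full-size
  decoder training at realistic data volumes is out of scope.
* The eyeblink-removal stage is a pluggable hook (`artifact_removal` in
  `preprocess_recording`); no artifact removal ships with the package.
* Ridge and gradient-trained linear decoders agree only up to their
  different regularizers and finite training; the suite asserts agreement
  within 0.02 r on matched synthetic data.
* The tanh subject curve is a summary fit; its extrapolations inherit all
  caveats of extrapolating a saturating two-parameter curve.
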