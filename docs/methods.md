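# Methods

This note documents the model, the data pipeline, the synthetic benchmark,
and the numerical and design choices behind them, for users who need to
know exactly what the package computes.

## Data model and preprocessing

The unit of data is the epoched trial set `[n_trials, n_channels,
n_samples]` (µV, labels as integer class indices, time axis last, half-open
windows, 0-based indices throughout). The canonical on-disk bundle is one
raw little-endian binary per array plus a JSON sidecar carrying dtype,
shape, channel names and a `format_version`; it is deliberately readable
from any language. EDF/GDF import is available behind an optional `mne`
dependency and is never required by the tests. The five channel subsets
(3 ⊂ 9 ⊂ 13 ⊂ 17 ⊂ 22 electrodes, growing outward from C3/Cz/C4) are
strictly nested and verified programmatically.

**Band-pass filter.** 0.5–30 Hz covers the task-relevant mu and beta
rhythms while removing drift and line noise. The filter family and phase
behavior are a package choice: 4th-order Butterworth applied
forward-backward (zero phase), which preserves waveform latencies — a
standard EEG practice. On a 4 s epoch the 0.5 Hz high-pass edge settles
over seconds, so pad-based `filtfilt` rings through the whole trial; we
use Gustafsson's minimum-transient initial conditions instead, which keeps
a 50 Hz stopband tone below ~2% RMS on a 4 s epoch while leaving a 10 Hz
passband tone essentially untouched.

**Z-scoring.** Each (trial, channel) fragment is standardized on its own
mean and *unbiased* (T−1) standard deviation; statistics are never pooled
across fragments or channels, so baseline drift in one trial or gain
differences between channels cannot leak. The map is idempotent and
equivariant under per-fragment affine transforms (`zscore(ax+b) =
sign(a)·zscore(x)`). A zero-variance fragment is a hard error identifying
the (trial, channel); an epsilon guard exists but is off by default, since
silent epsilons mask broken channels.

## Segmentation-and-reconstruction augmentation

Training trials of a class are cut into `Ns = 8` equal ordered slots (125
samples on 1000-sample trials); each new trial takes slot `j` from a
uniformly chosen same-class donor, independently per slot and with
replacement, preserving slot order so the within-trial temporal structure
survives. Sampling with replacement (rather than exhausting donors) was
chosen as the simplest scheme with the right marginal statistics. Gaussian
noise of σ = 0.2 (in z-scored units; the value is a package default — small
relative to unit-variance signal), clipped to [−1, 1], is added to the
reconstructed trials only; clipping is the simplest construction realizing
a hard bound. One reconstructed trial per original (`multiplier = 1`) is
generated and mixed with the originals under a seeded shuffle, so every
class count scales exactly by 2. Augmentation refuses any set whose
metadata marks it as test data, and the protocol runner re-checks
index-level disjointness on every run.

## The decoder

Reference shape chain for C=22, T=1000 at 250 Hz:
`(1,22,1000) → 3×(32,1,13) → (32,1,39) → tokens (13,32) → probabilities`.
Non-integer divisions floor throughout (1000/75 → 13).

**Front end.** Three branches with temporal kernels Fs/2, Fs/4, Fs/8
rounded to the nearest odd length (125/63/31) so 'same' padding is
symmetric; then a spatial convolution collapsing the channel axis, batch
norm, ELU, average pool (1,75), dropout 0.3. The spatial convolution is
depthwise (multiplier F2/F1 = 2, 16→32 maps) by default with a standard
(full-connectivity) variant behind `spatial_conv_mode="standard"`; the
depthwise form is what reproduces the reference parameter scale and
follows the compact-EEG-decoder tradition.

**Recalibration.** The cross-branch interaction keeps each branch and adds
the others — algebraically every branch receives the full sum — followed by
an independently parameterized CBAM per branch: channel gate from global
max+average pooling through a shared MLP (reduction 8; the package's
choice) and sigmoid; spatial gate from channel-wise max/mean maps through a
3×3 convolution and sigmoid. Both gates are strictly inside (0,1) and act
multiplicatively.

**Position-aware enhancement.** Parallel (1,3) and (1,7) convolutions with
separate batch norms, summed, ELU, pooled (1,3) back to 13 tokens, dropout,
then an additive learnable positional matrix initialized from a standard
normal. The matrix takes part in backpropagation; its gradient is verified
nonzero in the tests.

**Sparse attention.** Window s=4, stride d=1, depth N=6, heads h=4 are the
four-class defaults (N=4, s=5 for the two-class configuration). With 13
tokens, s=4/d=1 gives m=10 blocks. `top_k="auto"` keeps `max(1, ⌊m/3⌋)`
blocks, below half the block count as sparsity requires. Selection reuses
the aggregation score matrix; ties at the k-th score go to the lowest block
index so the mask is deterministic. Selection is treated as a discrete
choice (not differentiated); gradients flow through the scores of the
aggregation path and the keys/values of the restored tokens. The two paths
are combined by per-head elementwise sum — the most literal, parameter-free
reading of combining the two attentions. Encoder layers are pre-norm
(`x + MHA(LN(x))`); a feed-forward sublayer (`ffn_expansion > 0`) is
available but off by default — the default stack reproduces the reference
parameter count, and the attention itself carries per-token mixing. When
(n−s)/d is not integral the trailing tokens beyond the last full window are
covered only by earlier overlapping windows.

**Classifier.** Flatten → dense → softmax by default (a single output
layer, consistent with the reference parameter scale); a two-dense-layer variant with
dropout in between is available via `classifier_hidden`.

**Parameter accounting.** With the default switches the four-class
configuration counts 45,129 learnable parameters (branches 5,952; AFR 933;
PAE 10,848; SAT 25,728; head 1,668) and the two-class configuration
33,895. These are computed, not asserted, by `count_parameters`.

## Implementation of the numerics

No deep-learning framework is used: `apcformer.nn` is a minimal
reverse-mode autodiff engine over NumPy (float32 parameters) providing the
tensor operations, layers (conv2d with groups, batch/layer norm, dropout
with inverted scaling, pooling with floor semantics) and Adam with cosine
annealing (period = max_epochs, no restarts; β₁=0.9, β₂=0.999). Every
operation's vector-Jacobian product is tested against central finite
differences; the sparse attention is additionally tested against a dense
softmax-attention oracle in its limit cases (s=1,d=1 and k=m,d=s, ≤1e-5
over 100 seeded draws) and the trainable module against the chained
functional steps. Cross-entropy clamps probabilities at 1e-12 before the
log. Cohen's kappa is computed from the confusion-matrix marginals and
cross-checked against scikit-learn; the Wilcoxon test wraps
`scipy.stats.wilcoxon` (two-sided; an all-zero difference vector warns and
returns p=1) and is tested against the exact 2⁹ sign-flip enumeration.

## Training protocol

Within-session evaluation: stratified shuffle into 80% pool / 20% test,
then 20% of the pool as validation; five independent repeats (seeded by
(seed, repeat)), mean test accuracy reported. The repeated-shuffle reading
was chosen over literal five-fold cross-validation because the 80/20
ratios are the operational description. Model selection keeps the weights
of the epoch with the best validation *accuracy* (earliest on ties).
Batch 32, Adam at 1e-3 with cosine annealing to zero over `max_epochs`.

## Synthetic benchmark

The generator emulates the statistical skeleton of MI-EEG: 1/f^α
background noise per channel (spectrally shaped white noise, exact slope
control, unit RMS, zero mean) plus a class effect — a Hann-windowed
sinusoid at the class's rhythm frequency added on the class's designated
channels, with per-trial random phase. Defaults mimic contralateral mu ERD
(class 0 → 10 Hz on C4, class 1 → 10 Hz on C3; classes 2/3 use 22 Hz
midline/bilateral effects), 250 Hz, 4 s trials. `snr` is the *broadband*
amplitude ratio of effect to background on the affected channels, so
in-band detectability is much higher than `snr` suggests: a band-power
baseline transitions from chance to perfect between snr ≈ 0.05 and 0.3.
`snr=0` or `erd_depth=0` makes class distributions identical by
construction (same seed ⇒ bit-identical background).

What this does *not* emulate: volume conduction, inter-subject
variability, artifacts (EOG/EMG), non-stationarity, or true event-related
desynchronization (suppression of an ongoing rhythm — here the effect is
additive). Passing tests on this benchmark therefore demonstrate that the
pipeline and decoder are implemented correctly and can learn lateralized
band-limited structure, not that any accuracy level transfers to real
recordings.

The learning-sanity suite trains the full decoder (SAT depth reduced to 2
to keep the run at desk scale) on 200 separable trials, requiring ≥90%
held-out accuracy within 30 epochs, and verifies chance-level accuracy on
label-shuffled data over five repeats (within three standard errors of
1/2, with a binomial floor on the standard error so the test cannot pass
vacuously when all repeats coincide).

## Configuration and reproducibility

Layered configuration (defaults < YAML file < `key=value` overrides) with
unknown keys rejected by name; `sat.*` keys route into the model's
attention section. A single global seed fans out to per-stage seeds by
hashing the stage name, so stages are reproducible in isolation. Every CLI
run writes its config snapshot, package versions and seed before computing
anything; reruns with the same seed reproduce evaluation reports exactly.

## Known limitations

* Training is CPU-bound NumPy; wall-clock cost is dominated by the
  temporal convolutions' backward pass (~0.4 s per 32-trial batch on the
  3-channel configuration). Full-depth (N=6) training on 22 channels is
  feasible but slow; the tests use reduced depths.
* The two-class configuration's parameter count (33.9K) is ~15% above the
  reference 29.4K under counting rules that reproduce the four-class
  figure (45.5K) almost exactly; the residual is attributable to under-specified
  architecture details of the smaller variant.
* Cross-session and cross-subject transfer, artifact handling and montage
  re-referencing are out of scope.
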