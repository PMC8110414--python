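# Methods

This note documents the models and procedures implemented in
`ecgresnet`, the defaults and why they were chosen, what the synthetic
data generator does and does not emulate, and the numerical decisions
a maintainer would want written down.

## Problem setting

Ambulatory single-lead ECG is classified at the level of 3-second
windows ("slices") into the five AAMI heartbeat classes: N (normal,
including bundle-branch-block and escape beats), V (ventricular
ectopic), S (supraventricular ectopic), F (fusion) and Q
(unknown/paced). Evaluation is *interpatient*: whole records
(patients) are assigned to training, validation or test, never split
across them, because mixing one patient's beats between training and
test inflates accuracy without clinical meaning.

## Record I/O

WFDB conventions are read and written directly: text headers,
format-212 signal packing (two 12-bit two's-complement samples per
three bytes, gain in ADU/mV, default 200) and the binary annotation
stream (6-bit type code + 10-bit sample delta per word, with SKIP
escapes for long gaps). A plain-text dialect (header with format token
`txt`, one mV sample row per line, CSV annotations) is supported so
fixtures remain human-readable. Read-back error after a format-212
round trip is at most one quantization step (1/gain mV). Sample
indices are 0-based; all windows are half-open `[start, start+width)`.

The 15 MIT-BIH beat symbols map onto {N,V,S,F,Q} by the standard AAMI
table. Beat symbols outside the table map to Q ("unclassifiable") with
a logged warning; non-beat annotations (rhythm changes, artifacts) are
dropped at parse time. Channel 0 (MLII on most MIT-BIH records) is the
default analysis channel.

## Wavelet denoising

Nine-level discrete wavelet decomposition with db8, symmetric boundary
extension (PyWavelets). Detail coefficients are soft-thresholded,
`sign(c)·max(|c|−t,0)`, with the universal threshold
`t = σ̂·sqrt(2 ln n)` where `σ̂ = median(|d₁|)/0.6745` is the MAD
noise-scale estimate on the finest band; the approximation band is
never thresholded.

By default only the **three finest detail bands** are thresholded
(≈ 22–180 Hz at 360 Hz sampling). Applying the universal threshold to
all nine bands — classic VisuShrink — was measured to give almost no
SNR gain on ECG-like signals (≈ +0.3 dB at 10 dB input SNR): the soft
threshold's constant shrinkage bias on the many large QRS and T-wave
coefficients in the mid and coarse bands cancels the noise removed.
Restricting shrinkage to the high-frequency bands — where muscle
artifact, powerline and broadband noise live, and which is the
demonstrated effect of ECG wavelet denoising — yields ≈ +7 dB at 10 dB
input SNR across seeds. `n_threshold_bands=None` restores all-band
VisuShrink; `zero_approximation=True` additionally removes baseline
drift (off by default since it also removes the DC level).

The depth is capped at PyWavelets' maximum useful level for short
inputs (with a warning). The whole pipeline is deterministic.

## Slicing and labeling

Windows of 1080 samples (3 s × 360 Hz) start at sample 0 and advance
by a stride of 540 (50% overlap; overlap is used to increase the
number of training samples — the stride amount is a package default,
config-exposed). A beat belongs to a window iff its annotated R-peak
index lies in the half-open interval. Labels follow four rules: all-N
→ N; any non-N beat → abnormal; the most frequent abnormal type wins;
ties break to the abnormal type appearing first. "Abnormal" includes
Q. Windows containing no annotated beat are dropped by default (no
rule covers them). The labeler is tested exhaustively against an
independent brute-force implementation over all 780 ordered beat
sequences of length ≤ 4.

Slice counts are per-slice throughout. Published beat-level test
counts (e.g. 51,086 test beats) cannot be reconstructed from slice
predictions without an unstated slice-to-beat mapping; this package
reports slice counts and does not guess such a mapping.

## Interpatient split

The default `SplitSpec` is the published 44-record arrangement:
training {124, 201, 203, 205, 207, 208, 209, 215, 220, 223, 230},
validation {101, 106, 108, 109, 112, 114, 115, 116, 118, 119, 122},
and the 22-record test set. The three paced records (102, 104, 107)
are excluded by omission, not hard-coded. `swap_cross_validation`
exchanges the training and validation halves (the second fold);
whether results should be averaged over both half-swaps or taken from
the fixed split is left to the caller — both are supported.

Slice amplitudes are z-scored per slice by default before training:
raw mV inputs with a large learning rate are numerically fragile, and
per-slice normalization also removes residual baseline offsets.

## Network architecture

All tensors are `(batch, channels, length)`; convolutions are
cross-correlations with "same" zero padding, He fan-in
initialization, seeded. The full-size network for 1080-sample slices:

1. conv(length 32, 12 kernels) + ReLU + dropout 0.5 — large kernels
   suit low-frequency, low-sampling-rate signals; a 3-wide image
   kernel sees too little of an ECG waveform to form a meaningful
   feature;
2. one classic residual stage: branch = conv–ReLU–conv (length 16),
   shortcut = max-pool (window 3, stride 1), then add and ReLU;
3. seven improved residual stages, each `batch norm → [conv–ReLU–conv
   + shortcut] → ReLU`. Kernel counts follow (12, 12, 24, 24, 48, 48,
   96): each width change uses a stride-2 first convolution and a 1×1
   stride-2 projection shortcut, all other shortcuts are identities;
4. flatten → fully connected → softmax (5 classes).

The residual block computes `y = F(x) + shortcut(x)` with
`F = W₂·σ(W₁·x)`; with the branch weights zeroed and an identity
shortcut the block is exactly the identity (tested). Softmax is
max-shifted for stability. L2 regularization attaches to every
convolution kernel and the fully connected weights (not biases or
batch-norm parameters). The per-stage dimensions are a documented
reconstruction — only the initial kernel length (32), the starting
kernel count (12), the "seven times" repetition, the stage-doubling
convention and the five outputs are fixed points; everything is
config-overridable through `ModelSpec`. The seven improved stages are
seven distinct weight sets (the standard residual-network reading),
not one stage applied seven times.

Forward and backward passes are implemented directly on numpy
(im2col-style windows + BLAS contractions); gradients are verified
against central finite differences in the test suite. One caveat
worth recording: with biases at exactly zero, edge windows over
ReLU-zeroed, zero-padded inputs place some pre-activations exactly on
the ReLU kink, where a two-sided numerical derivative is ill-defined;
the gradient check therefore perturbs biases off zero first. This is
a property of the check, not of training.

## Training

Mini-batch SGD with momentum 0.9. Loss = mean cross-entropy
`−Σ yᵢ ln pᵢ` (probabilities clamped at 1e-12) + `α·Σ‖W‖²` with
α = 1e-4. Defaults follow the full-scale recipe: lr 0.1, ×0.1 at
epochs 51 and 76 ("step change" after convergence begins around epoch
50), batch 128, 100 epochs, dropout 0.5. "Iterations" are read as
epochs: validation accuracy is measured after each epoch and the
weight snapshot with the highest value is returned (ties to the
earliest epoch). Non-finite loss aborts with a diagnostic. Runs are
exactly reproducible from the seeds (model init, dropout, shuffling).

Momentum, batch size and α are package defaults (unstated in the
original recipe), logged in every run manifest.

## Synthetic data generator

Beats are sums of Gaussian bumps, one per wave (P, Q, R, S, T), with
class-specific morphology: N a full P-QRS-T complex; V wide
high-amplitude QRS, absent P, discordant T; S near-normal morphology
with a peaked early P *and* premature arrival (the preceding RR
interval is multiplied by 0.6 — rhythm, not shape, is the dominant
cue, as for real atrial premature beats); F intermediate between N
and V; Q a pacing spike plus a broad complex. Beats are placed on an
RR grid (mean 0.8 s, 5% Gaussian jitter) and a small multiplicative
amplitude jitter varies successive beats. Noise is strictly additive:
0.3 Hz sinusoidal baseline wander (0.10 mV), 50 Hz powerline
(0.05 mV) and white broadband noise (σ 0.03 mV). The generator
returns both the clean and the noisy signal so denoising can be
scored against a known reference.

Default per-beat class probabilities (V 23.61%, S 3.80%, F 0.57%,
Q 0.02%, remainder N) reproduce the heavy class imbalance of the
clinical beat inventory this package's evaluation tables refer to, so
imbalance-driven behaviour — in particular zero sensitivity on the
vanishing Q class — appears in synthetic experiments too.

What the generator does *not* emulate: physiological morphology
variation between patients, compensatory pauses, electrode-motion
artifacts, atrial-fibrillation rhythms, or any patient-specific
structure. Consequently, passing synthetic tests demonstrates that
the pipeline's mechanics (denoising, labeling, splitting, learning,
evaluation) are correct and that the classifier can exploit both
morphological and rhythm cues — it does not certify clinical-grade
accuracy on real ECG.

## The scaled-down experiment

The desk-scale end-to-end experiment (`RunConfig.scaled_down`,
`ecgresnet run`) generates 32 records of 96 s (2016 slices at 50%
overlap: 1008 training, 504 validation, 504 test, records assigned
2:1:1 round-robin), denoises, slices, trains the scaled-down network
30 epochs and evaluates on the held-out records. The scaled-down
`ModelSpec` keeps the architectural ideas (large initial kernel,
classic + improved stages, stage doubling with projection shortcuts)
at reduced size: 8 initial kernels with stride 4, two improved stages
(16, 32), length-16 residual kernels, dropout 0.2.

Two optimizer deviations from the full-scale defaults, found by pilot
runs and kept deliberately: lr 0.1 diverges on the small network
(weights blow up into a majority-class collapse within two epochs),
so the scaled run uses lr 0.03 with ×0.3 decay at epochs 18 and 26;
and batch 64 doubles the updates per epoch, which lets the
rare-class (S) features emerge within the 30-epoch budget — with
batch 128 the S class is still at zero sensitivity at epoch 30,
while the same model reaches it by epoch 60. Dropout 0.5 on the
8-channel first feature map starves the small model entirely (it
never leaves majority-class prediction), hence 0.2.

Typical held-out accuracy is 92–94%: N and V near-perfect, roughly
half of S slices recovered (their only reliable cue is one shortened
RR interval, which is invisible when the premature beat's predecessor
falls outside the window), F and Q essentially missed — the same
imbalance pattern reported for full-scale interpatient experiments.

## Metrics and the two conventions

`confusion_matrix` counts (actual, predicted) pairs with rows =
actual. `overall_accuracy` = 100·trace/total. Sensitivity and
precision per class come in two conventions: `standard` (Se = diag /
row total, P+ = diag / column total) and `paper_table` (the
transpose). Both are provided because the published confusion matrix
and its companion sensitivity/precision table that this package
reproduces are mutually consistent only under the transposed reading;
which of the two printed artifacts has swapped axes cannot be
determined from the text, so the discrepancy is preserved rather than
silently resolved. `standard` is the default for new results;
`paper_table` reproduces the printed tables. The two conventions
coincide on symmetric matrices, and accuracy is invariant under
transposition. Degenerate 0/0 ratios are reported as 0; reported
percentages round half-up to two decimals.

## Reproducibility

One global seed drives everything: per-stage seeds derive as
`sha256(seed:stage) mod 2³¹`, so any stage can be re-run in isolation
and the whole experiment reproduces bit-identically. The run manifest
embedded in every report records all resolved defaults (stride,
threshold rule and band count, momentum, batch size, α, schedule,
filter schedule), making runs auditable.

## Known limitations

* The network trains on one CPU at desk scale only; the full-size
  configuration is provided and tested for shape/determinism but a
  full clinical-scale training run is outside the test suite.
* Per-beat evaluation (beat counts rather than slice counts) is not
  implemented for lack of a defined slice-to-beat mapping.
* No class re-weighting or augmentation (deliberately out of scope);
  rare-class sensitivity is accordingly limited.
* The annotation reader supports the single-byte-pair MIT annotation
  codes plus SKIP/NUM/SUB/CHN/AUX escapes; multi-segment records and
  rhythm/ST annotations are not supported.
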