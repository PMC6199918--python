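# Methods

## Signal model and preprocessing

The package treats both neural multi-unit activity and EMG as nonnegative
RMS envelopes.  Raw broadband signal is high-pass filtered (Butterworth,
20 Hz, 3rd order, applied forward and backward so the net phase shift is
zero), squared, smoothed with a Gaussian kernel (σ = 10 ms, truncated at
±4σ and renormalized to unit sum), and square-rooted.  Because the filters
are applied twice, the effective magnitude response is the squared
Butterworth response: a sinusoid exactly at the cutoff emerges with
amplitude gain 0.5.  EMG envelopes are additionally low-pass filtered
(3rd-order zero-phase Butterworth, 1–5 Hz, default 5 Hz) to form the
regression target; lower cutoffs turn bursts into smoother rate-like
traces and are more forgiving of small timing errors.  Envelopes are then
decimated to 100 Hz by plain stride selection — no extra anti-alias stage,
since the Gaussian kernel (half-power ≈ 37.5 Hz for a frequency-domain σ of
100/π Hz) and the EMG low-pass already band-limit the signal.  Zero-phase
filtering uses reflection padding of three filter orders to suppress edge
transients on 3–4 s trials.

A note on the Gaussian kernel's stated bandwidth: the package exposes
`halfpower_frequency(sigma_f) = sigma_f * sqrt(2 ln 2)`, the half-power
point of a Gaussian *frequency response* with standard deviation
``sigma_f``; for ``sigma_f = 100/π`` Hz this is ≈ 37.5 Hz.  The standard
Fourier pair of a 10 ms time-domain Gaussian would instead give a
frequency-domain σ of 1/(2π·0.01) ≈ 15.9 Hz; the two conventions do not
reconcile, and the package implements the stated frequency-domain figure
rather than silently "fixing" it.

## Decoder

Per-session feature stacks (pointwise affine + leaky ReLU, negative slope
0.01, widths 27 → 21 → 15 → 9, biases initialized to zero) compensate for
day-to-day electrode micro-drift by projecting each session into a shared
feature space.  Feature layers have no temporal extent, so all temporal
memory lives in the shared regression stack (widths 9 → 6 → 3 → 1).  In the
Gamma configuration each kernel is F(t) = αβ²·t_f·exp(−βt_f) with the
SoftPlus-warped time t_f; kernels span 300 ms (30 taps at 10 ms bins) and
are sampled at t = k·dt, k from 0.  Leaky ReLU sits between regression
layers; the final single-channel output is raw — small negative excursions
are penalized by the loss, not clipped, even though EMG envelopes are
nonnegative.  The naive configuration replaces Gamma kernels with free
10-bin tap vectors under the identical convolution operator.  The linear
control is a single pointwise affine map (with bias) and no rectification.

All convolutions are front-zero-padded, so the network is causal by
construction; this is verified by perturbation tests rather than assumed.

Numerical choices:

* **SoftPlus warp** is computed as `logaddexp(0, θβ(t−t₀)) / (θβ)`, exact in
  both tails without overflow; no ε-guards are needed anywhere because the
  warp is strictly positive (underflow to zero occurs only ~700 log-units
  below onset, far outside any kernel span used).
* **Gradients are closed-form.**  The network is small and fixed-shape, so
  forward and reverse passes are hand-derived NumPy (kernel-tap partials
  ∂F/∂α, ∂F/∂log β, ∂F/∂log t₀ chained through the convolution).  Every
  backward rule is tested against central finite differences to a relative
  error below 1e-4.
* **Initialization**: α and feature weights are Xavier-uniform
  (limit √(6/(fan_in+fan_out))); t₀ and the warped time-to-peak 1/β are
  drawn uniformly from 5–30 ms (both "on the order of 10 ms"; the exact
  distribution is this package's choice) and optimized through their logs
  so positivity holds by construction.
* **Kernel area discretization**: the continuous form conserves area
  exactly; the discrete tap sum conserves it to < 2% only when the kernel
  is both contained (t₀ + 8/β < span) and resolved (τ = 1/β not far below
  the bin width).  The area tests therefore sample at 2 ms.

## Training and validation protocol

Full-batch ADAM (learning rate 0.1, β₁ = 0.9, β₂ = 0.999, ε = 1e-8),
1000 steps, no L1/L2 regularization.  The loss is the plain sum of squared
errors over training trials, excluding the first second of each trial
(100 bins) so solutions cannot exploit the convolution stack's startup
transient; the same burn-in exclusion applies to all metrics, for
consistency.  R² is pooled — one computation over all included
(trial, bin) points per set, not a per-trial average — and Pearson
correlation is computed over the same pooled points.  Each EMG channel is
fit independently.  Targets are used in native envelope units.

Trials split deterministically in sequential groups of five
(train, train, train, A, B); a trailing partial group follows the same
truncated pattern, so remainders land in the training set first.  Sixteen
restarts differ only in initialization (seed + attempt index).  Per
restart, the states maximizing R² on A and on B are kept (ties keep the
earliest step).  Fold selection ranks checkpoints by R²(train) + R²(val)
with exact ties resolved to the lowest attempt index; the untouched fold is
then scored once.  Non-convergent attempts stay in the records with their
scores rather than being resampled.  Controls (linear, shuffle) run under
the identical protocol.  The shuffle permutes whole cross-channel time
slices over all pooled (trial, bin) positions: instantaneous spatial
statistics are preserved exactly, so the null isolates temporal structure;
whether channels should instead be permuted independently is ambiguous, and
the joint choice is deliberate.

## Synthetic data generator

Sessions are built from a small number of latent command signals: each
trial superimposes Gamma-shaped bursts (width 150 ms, count ~Poisson(3) per
trial) with onsets jittered around the trial midpoint (reach-to-pull
alignment) and ~20% amplitude jitter.  Neural envelopes are a
session-specific nonnegative mixing of the latents plus half-normal
(truncated-at-zero) noise, keeping envelopes nonnegative by construction;
mixing matrices drift between sessions while latent→EMG dynamics stay
shared.  EMG is a rectified sum of Gamma-filtered latents (default planted
onset delays 20/40 ms, time constants 30/60 ms) plus half-normal noise.
SNR is defined as clean power over the noise's second moment.

What the generator does *not* emulate: biomechanics and stretch-reflex
feedback, spiking statistics, movement artifacts, electrode crosstalk, or
any behavioral variability beyond burst jitter.  Passing tests show the
method recovers planted structure under its own assumptions — they are not
evidence about any particular animal recording.

## Benchmark problem sizes

The recovery and control benchmarks use a deliberately small configuration
chosen once for single-CPU runtimes: one session of 20 four-second trials,
12 neural channels mixed from **one** latent, one EMG path planted with
t₀ = 40 ms and τ = 1/β = 60 ms (EMG peaks 100 ms after the latent — the
lag regime where a pointwise decoder must fail).  The decoder is
12 → 6 → 1 feature widths plus a single 1 → 1 Gamma regression layer whose
kernel spans 600 ms so the planted response fits inside one kernel — the
closed form costs the same three parameters at any length.  The noise-free
recovery run uses 4 restarts × 1000 steps and unfiltered targets (the clean
envelope is already band-limited; low-pass filtering the target would fold
the non-causal zero-phase filter response into the kernel being recovered).
The noisy suite (EMG SNR ≈ 10 dB, 5% neural noise, 5 Hz target filtering)
uses 8 restarts × 600 steps for the decoder, the linear control, and the
shuffle null.

Recovery is judged on the **end-to-end impulse response**: the trained
network is probed with a single-bin input along the true mixing column, the
zero-input baseline is subtracted, and a Gamma function is fit to the
response.  Individual layer parameters of a deep composition are not
identifiable; the composite response is.

## Known limitations

* Onset-delay recovery is resolution-limited by the 10 ms bin width and by
  a mild t₀↔β trade-off when inputs are smooth; errors of a few ms are
  expected even noise-free.
* The hand-rolled reverse-mode pass covers exactly the layer types defined
  here; it is not a general autodiff.
* Deterministic trial splitting assumes trials are exchangeable in
  sequence; slow within-session drift would leak into both folds equally.
* With very short time constants (τ below about half the bin width) the
  sampled kernel under-resolves the rising edge and the discrete area
  deviates from α by more than the 2% bound; training at 100 Hz keeps
  learned kernels well above this regime.
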