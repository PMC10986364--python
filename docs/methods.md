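# Methods

This note documents the models, estimators and design choices behind
`p3dseize`, in the order the pipeline applies them, together with the
numerical conventions a reader needs to reproduce any number the package
prints.

## Problem setting

The package classifies 6-second multichannel scalp-EEG windows into two
states: *preictal*, operationalized as the seizure prediction horizon (SPH)
from 15 down to 5 minutes before an annotated seizure onset, and
*interictal*, at least 15 minutes away from every onset. Windows in neither
zone — ictal data, the final 5 minutes before onset, and anything straddling
a zone boundary — are discarded so every retained window is homogeneous in
label. Classes are balanced 1:1 by seeded subsampling of the majority class,
allocated across subjects proportionally (largest-remainder rounding).

## Synthetic data generator

The generator emulates only the statistical structure the method exploits: a
complexity contrast between regimes. Each regime is a sinusoid plus
1/f^α colored noise (spectral shaping of seeded white noise, DC removed,
normalized to unit variance before scaling):

| parameter | interictal | preictal | unit |
|---|---|---|---|
| sine frequency | 10 | 10 | Hz |
| sine amplitude | 10 | 30 | µV |
| noise amplitude | 20 | 6 | µV |
| noise color α | 1.0 | 0.5 | – |

The preictal regime is rhythm-dominated (lower complexity), the interictal
baseline noise-dominated; amplitudes are ordinary scalp-EEG magnitudes. The
regime weight is 1 inside `[onset−900 s, onset−300 s)` with a 2-s linear
cross-fade inside the zone edges, avoiding step discontinuities. Channels
get an independent seeded gain in [0.8, 1.2] and independent noise/phase
draws. Output is bit-reproducible from the configuration (including seed).

What the generator does **not** emulate: seizure morphology, artifacts (eye
blink, EMG), inter-subject variability, nonstationary background rhythms.
Consequently, a classifier scoring well here demonstrates that the pipeline
can recover a complexity contrast through the full feature-selection and
spatiotemporal-modeling machinery — not that it would reach the same
accuracy on clinical recordings.

Sampling rate defaults to 256 Hz with the 23 referential 10–20 electrode
names (AF7 … PO8) used throughout.

## Preprocessing

Band-pass 0.5–75 Hz with a 4th-order Butterworth filter applied
forward-backward (zero phase), so window boundaries suffer no group delay;
filtering is idempotent within 1% RMS for in-band signals. An optional
50/60 Hz notch exists but defaults to off. Windows tile each recording from
t = 0 in non-overlapping 6-s strides; each window splits into two 3-s steps
(the model's T = 2 sequence).

## Nonlinear features

Computed per channel per 3-s step. Estimator conventions (frozen so the
brute-force oracle tests can mirror them exactly):

* **Higuchi fractal dimension.** Curve lengths
  `L_m(k) = (1/k) Σ_i |x(m+ik) − x(m+(i−1)k)| · (N−1)/(⌊(N−m)/k⌋ k)`,
  `L(k) = (1/k) Σ_m L_m(k)`; the dimension is the least-squares slope of
  `ln L(k)` on `ln(1/k)` over k = 1…kmax. The slope form is preferred over a
  single-k ratio because the intercept `ln((N−1)·E|Δ|)` biases single-k
  estimates; a straight line gives exactly 1.0 and white noise ≈ 2 under the
  slope form.
* **Approximate entropy.** Chebyshev template distances; match counts use
  `d ≤ r` and include the self-match; `φ(m,r)` is the mean log match
  fraction over the N−m+1 templates; ApEn = φ(m) − φ(m+1).
* **Sample entropy.** Strict `d < r`, self-matches excluded; B^m averages
  per-template match fractions `count/(N−m)` over the N−m+1 templates;
  SampEn = −ln(B^{m+1}/B^m). Zero matches at either dimension raise an
  error rather than returning a number.
* **Fuzzy entropy.** Templates are mean-removed; similarity is the Gaussian
  membership `exp(−d^n / r)` (with r, not r^n, in the denominator — the
  convention is pinned and mirrored by the oracle); FuzzyEn =
  ln Φ^m − ln Φ^{m+1}.

Defaults: embedding m = 2, tolerance r = 0.2·SD of the series, fuzzy
exponent n = 2, kmax = 10 — standard literature values. Tying r to the SD
makes ApEn/SampEn invariant to affine rescaling and FuzzyEn additionally
exactly offset-invariant. Constant series return 0 for the entropies and
raise for HFD (zero curve length); inside block extraction any estimator
failure is recorded as 0 with a logged warning so one dead channel cannot
abort a run.

The production path uses numba-compiled O(N²) kernels (one fused pass
serves both embedding dimensions and both threshold conventions); the test
suite checks all four estimators against independent plain-Python
brute-force implementations to 1e-10 on random series.

## Feature selection (mRMR)

Ranking variables are per-feature channel-and-step averages (four
variables), matching the granularity at which the feature families are
compared; per-channel granularity is available behind a flag. Mutual
information uses equal-frequency binning into `min(⌈√n⌉, 16)` bins
(robust to heavy tails; inputs with few distinct values are used as
categories directly) and the plug-in contingency estimate in natural-log
units. The incremental search selects first the max-relevance variable,
then repeatedly the candidate maximizing relevance minus mean MI with the
already-selected set; ties break by lexicographic variable name. The
reported importance is the incremental score at selection time (min-max
rescaled to [0, 1] for display; raw scores retained).

The retained count comes from an accuracy sweep over ranked prefixes under
a fixed seeded CV plan, returning the smallest count achieving the maximum.
The sweep's default evaluator is the fast KNN baseline (k = 5) to keep the
sweep cheap; the pipeline pins the retained count to 3 by default (the
reference architecture's N) unless configured otherwise.

## Spatial tensorization

The 23 electrodes map to fixed cells of a 4×7 grid, rows anterior →
posterior, columns left → right:

```
  .  AF7  AF3   .   AF4  AF8   .
 FT9 FT7  FC3  FCz  FC4  FT8  FT10
 T7  TP7  CP3  CPz  CP4  TP8   T8
  .  PO7  PO3  PO4  PO8  P8    .
```

The layout is pinned (a config override is accepted and serialized with
results). Z-scoring statistics are estimated per (feature, cell) on the
*training split only* and applied to both splits — fitting per CV fold, a
deliberate leakage-control choice even though fitting on all data would be
simpler. Empty cells and zero-variance cells carry 0 (the standardized
mean), keeping convolutions well-defined. Each window becomes a
(T=2, N, 4, 7, 1) tensor; placement is by electrode name, so channel order
is irrelevant.

## Classifier

Time-distributed pseudo-3D CNN → bidirectional ConvLSTM3D → squeeze-
excitation channel attention → dense head, implemented in NumPy (float64)
with hand-written backpropagation and Adam.

* **Pseudo-3D stack.** Six same-padded convolutions alternating spatial
  1×3×3 and feature-axis 3×1×1 kernels, channel ladder 64-64-128-128-256-
  256, ReLU after each, batch normalization after every pair. Spatial
  dimensions are preserved, so each 3-s step maps (3,4,7,1) → (3,4,7,256).
  The factorization of a k×k×b kernel into k×k×1 then 1×1×b is exact in the
  linear case (verified against a full 3-D convolution), and the stack is
  applied to both time steps with shared weights by folding time into the
  batch axis — so batch-norm statistics pool over batch × time.
* **Bi-ConvLSTM3D.** Gates i, f, g, o with sigmoid/tanh nonlinearities,
  `C_t = f⊙C_{t−1} + i⊙g`, `H_t = o⊙tanh(C_t)`, where ⊙ is the element-wise
  product and gate pre-activations are convolutions of the input and the
  previous hidden state plus bias. Reference size: 256 input channels,
  256 hidden per direction, 1×1×1 kernels, biased gates — 1,050,624
  trainable parameters over both directions. Peephole connections
  (per-channel weights on the cell state) are implemented but disabled by
  default, because the reference parameter count excludes them. The two
  directions' final hidden states are concatenated (512 channels). The
  forget-gate bias starts at 1 (standard recurrent-training practice).
* **Attention.** Squeeze = global average over the three feature/spatial
  axes per channel; excitation = 512→64 (ReLU) →512 (sigmoid), both biased
  (66,112 parameters); scale = per-channel multiply. Since the weights lie
  in (0,1), attention is a contraction on channel magnitudes.
* **Head.** Global average pool → dense 64 (ReLU) → dropout 0.25 →
  softmax(2). Training uses cross-entropy with Adam (lr 1e-3, batch 32),
  a stratified validation split (10% by default), and a single seeded RNG
  driving initialization, shuffling and dropout, so identical configs give
  identical histories.

A desk-scale preset (`ModelConfig.reduced()`: ladder 8-8-16-16-32-32,
16 hidden recurrent channels, attention 32/4, head 16, 12 epochs) is used
for cross-validation experiments and tests; the reference configuration is
used for architecture/parameter-count checks. Parameter counts are
available both from shape formulas and by enumerating instantiated weight
arrays, and the two are tested to agree on random configurations.

### Numerical notes

* All neural computation is float64; convolutions use im2col so each pass
  is a single matmul; gradients are verified against central differences.
* With zero-initialized biases, zero padding, and ReLU-clipped inputs, some
  pre-activations sit exactly at the ReLU kink (an all-zero patch makes the
  output equal the bias); the subgradient convention there is 0. Gradient
  checks therefore evaluate at a jittered parameter point.
* Batch-norm uses biased batch variance with running-average momentum 0.1;
  evaluation mode uses the running statistics.

## Evaluation

Stratified k-fold cross-validation (k = 5), independently repeated
(5 repeats = 25 folds in the full protocol; tests and the bundled study use
1 repeat to stay desk-scale). Stratification is a stabilizing choice for
small samples; folds are sample-level, with a subject-aware mode available
behind a flag. Per fold: z-scorer fit on the training rows, a fresh seeded
model trained, confusion counts retained. Metrics: accuracy, sensitivity,
precision, specificity, reported as mean ± std over folds; a metric with a
zero denominator is reported as undefined, never as 0. Baselines — KNN
(k = 5, Minkowski p = 2) and SVM (RBF kernel, one-vs-one, C = 1, scaled
gamma) on flattened step × feature × channel vectors, standardized per
fold — consume the identical fold plan, making comparisons paired.

## Study conditions used by the bundled tests

Two synthetic recordings of 1800 s with one onset each at 1800 s yield 200
preictal and 300 interictal windows, balanced to 400 total. All four
features are extracted, mRMR ranks them, the top 3 feed the 4×7 tensors,
and the desk-scale model runs 5-fold CV. Under the default contrast the
model reaches mean accuracy ≥ 0.90 while a label-permuted control stays at
chance (0.40–0.60) — the pair of checks that distinguishes real signal
recovery from memorization. Problem sizes (recording length, window count,
desk-scale architecture, epochs) are chosen to keep the full study around
four minutes on one CPU core.

## Known limitations

* The synthetic contrast is far cleaner than clinical EEG; absolute
  accuracies here say nothing about CHB-MIT-scale performance.
* No artifact handling: the manual ICA-based cleaning used on clinical data
  is inherently irreproducible and is exposed only as a hook point.
* EDF support is plain EDF (16-bit), with onsets in a TSV sidecar rather
  than EDF+ annotations; heterogeneous sampling rates are not resampled.
* The mutual-information estimator is the binned plug-in (bias ~(B−1)²/2n),
  adequate for ranking four variables, not for precise MI values.
* Training is CPU NumPy: the reference architecture is practical for
  forward passes and parameter audits, while routine training uses the
  desk-scale preset.
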