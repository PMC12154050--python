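# Methods

## The coherence time-graph representation

A multichannel EEG recording is reduced to a sequence of functional
connectivity graphs and then to an image. The segment is the
classification unit: fixed length (10, 20 or 30 s), zero overlap, trailing
remainder dropped, label inherited from the subject. Within a segment a
0.4 s analysis window advances in 0.2 s steps (50 % overlap); each window
yields one graph, hence one pixel column.

### Coherence estimation

The edge weight between channels x and y is the magnitude-squared coherence
`|P_xy|² / (P_xx P_yy)`, estimated by Welch's method and averaged over a
frequency band. Choices, with defaults:

| parameter | default | notes |
|---|---|---|
| sub-segment length | 100 samples (0.2 s at 500 Hz) | gives M = 3 sub-segments per 0.4 s window and 5 Hz resolution |
| sub-segment overlap | 50 % | standard Welch trade-off |
| taper | Hann (periodic) | |
| detrend | constant (per sub-segment) | removes DC offsets that would inflate low-frequency coherence |
| averaging band | 0.5–45 Hz, DC bin excluded | the broad EEG band (delta through gamma); configurable for sub-band variants |

M ≥ 2 is enforced: with a single sub-segment the coherence estimate is
identically 1 for *any* pair, so that configuration is rejected rather than
silently returned. Zero-variance channels are likewise estimation errors that
name the offending channel.

Small-sample bias is inherent to Welch coherence: for independent Gaussian
signals the expected estimate is ≈ 1/M per bin (slightly above 1/3 at M = 3
because Hann-tapered 50 %-overlapping sub-segments are weakly correlated),
and for true coherence κ approximately κ + (1−κ)²/M. The per-window images
therefore sit on a ~0.33 noise floor at the defaults. This is deliberate: the
bias is identical across pairs and classes, and the closed-form limits are
still recovered when M is large (verified in the tests with M ≈ 230).

The all-pairs adjacency is computed vectorised (one tapered FFT per channel
sub-segment, cross-spectra by outer product); a brute-force estimator using
explicit loops and discrete Fourier sums (`oracle_msc`) shares no code with
the fast path and pins it to 1e-10 in the tests. The matrix is symmetrised
exactly and the diagonal set to 1 (self-coherence; it never enters the
flattened vector).

### Flattening and the image

The strictly-upper triangle is flattened in row-major pair order
(0,1), (0,2), …, (c−2,c−1) — the order is recorded in the image metadata,
since any fixed convention works but pixel-row identity must be stable.
Columns are tiled left→right in window order. No per-image normalisation is
applied: coherence is already in [0, 1], so the grayscale scale is absolute
and images are comparable across segments and subjects. PNG export quantises
with `clamp(floor(255 v + 0.5))` (≤ 1/510 per-pixel error); classifiers
consume the float NPZ, never the quantised PNG.

## Synthetic cohort

The generator plants coherence structure with a shared-source model:
channel i is the sum of unit-variance latent sources of the groups containing
i plus `σ · N(0,1)` independent noise. Sources are white noise passed through
a zero-phase 4th-order Butterworth band-pass (default 4–30 Hz) and rescaled to
unit sample variance; band-limited noise rather than sinusoids keeps the
coherence estimate stable across the averaging band. With
`source_band=None` the source is white, per-bin SNR is 1/σ², and a coupled
pair's population coherence is exactly (1/(1+σ²))² — the analytic oracle used
by the estimator tests. One global seed expands to per-subject sub-seeds by
a fixed counter, so each subject is reproducible independent of generation
order.

The default study cohort has two classes of 6 subjects (60 s each at 500 Hz,
19 channels named after the 10–20 montage): both couple the same
central-posterior block, the control class at σ = 1 and the dementia-like
class at σ = 2.5. This emulates the *reduced* coherence reported in dementia
EEG relative to controls and — unlike a purely spatial contrast (same
coupling strength in different blocks) — is visible to a
translation-invariant conv + global-average-pool classifier. A spatial
frontal-vs-occipital contrast is still exercised in the tests via pixel-row
means (AUC ≥ 0.95 over segments).

What the generator does **not** emulate: eye-blink/muscle artifacts, volume
conduction, 1/f spectral shape, nonstationarity, inter-subject anatomical
variability. Consequently a perfect synthetic CV score demonstrates that the
pipeline is correct and leakage-free, not that comparable accuracy is
attainable on clinical recordings; published dataset-scale accuracies require
the real cohort and are out of scope here.

## Splitting and leakage

Fold assignment is stratified by class label (shuffle within class, deal
round-robin), seeded, and performed at the *subject* level before
segmentation — the order matters, because segment-level splitting lets a
subject's highly correlated segments straddle train and test. The CV harness
re-asserts disjointness of train/test subject sets on every fold and raises a
hard error on violation. Within each training fold an optional subject-wise
validation holdout (default 10 % of training subjects, at least one subject
per class retained) supplies learning curves; the coherence transform has no
fitted parameters, so per-fold preprocessing independence is automatic.

Seconds→samples conversions use round-half-up (exact at 500 Hz: 0.4 s → 200,
0.2 s → 100). Partial trailing segments and windows are dropped.

## Classifiers

Both architectures run on `cohgram.nn`, a small NumPy engine (im2col
convolutions, max-pool with argmax routing, batch norm, residual blocks,
Adam) whose backward passes are finite-difference checked in the tests.
Training is deterministic given the seed.

* **custom_cnn** — 2-D, valid (unpadded) 3×3 convolutions at 32/64/128
  filters, each followed by ReLU and 2×2 max-pool (floor), then Flatten →
  Dense(128, ReLU) → softmax. On 171×149 input the feature maps are
  169×147×32 → 84×73×32 → 82×71×64 → 41×35×64 → 39×33×128 → 19×16×128,
  flatten length 38 912 (≈5.1 M parameters, dominated by the first dense
  layer).
* **shallow_resnet** — 1-D over the *pair* axis with the window axis as input
  features (an unusual orientation, but it is what the layer shapes dictate):
  Conv1D(64, k3, stride 2, same padding) + BN + ReLU → MaxPool(2) → three
  basic residual blocks (two k3 convs + BN each, ReLU between, add, ReLU) at
  64/128/256 filters, the latter two downsampling by stride 2 with 1-tap
  projection shortcuts → global average pool → softmax (≈0.47 M parameters).
  Residual-block internals (BN placement, projection shortcuts) follow the
  standard minimal completion of a basic block.

Defaults: Adam at 1e-3, categorical cross-entropy, batch size 8, epochs 50
(the study runs use 30 — the loss plateaus well before that on the synthetic
cohort). He-normal initialisation, seeded.

## Problem sizes used in the checked experiments

The end-to-end study is 2 classes × 6 subjects × 60 s → 72 segments of
171×49 images, subject-wise 5-fold CV with the shallow ResNet at 30 epochs;
it completes in about two minutes on one CPU and reaches mean CV accuracy
1.0 under the default contrast. Estimator checks use ≥10⁴ pair-window
estimates for the 1/M bias and 3×10⁵ samples per σ for the closed-form
recovery.

## Numerical notes and limitations

* Coherence values are clipped to [0, 1] against floating-point overshoot;
  identical-signal coherence equals 1 to ~1e-15.
* `flatten_upper` rejects asymmetry beyond 1e-9 rather than silently
  averaging; the adjacency constructor symmetrises exactly before that.
* Max-pool ties route the gradient to the first maximum (argmax convention).
* EDF is read via MNE; the package writes its own NPZ schema (EDF export is
  not provided). Resampling is out of scope: other sampling rates are
  accepted and window lengths convert via round-half-up.
* Band-pass preprocessing (0.5–45 Hz Butterworth, zero phase) is available
  but off by default — the transform is defined on recordings as given.
* The NumPy engine is CPU-only and single-threaded beyond BLAS; it is sized
  for the package's study scale, not for dataset-scale deep learning.
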