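# Methods

`eegsev` implements a pipeline for predicting a continuous clinical anxiety
severity score (HAM-A total, 0–56) from resting-state EEG functional
connectivity, together with a synthetic cohort generator that makes every
stage testable against known ground truth.  This note records the models,
the numerical choices, and what the synthetic experiments do and do not
demonstrate.

## Pipeline

A 16-channel 10–20 recording (FP1, FP2, F3, F4, C3, C4, P3, P4, O1, O2,
F7, F8, T3, T4, T5, T6; 250 Hz) is downsampled to 125 Hz, band-passed 4–30
Hz with a 4th-order Butterworth filter, cut into non-overlapping windows
(2–10 s; default 10 s), and each window is filtered into four bands:
theta 4–8, alpha1 8–10, alpha2 10–13, beta 13–30 Hz.  All filtering is
forward–backward (zero-phase): the downstream statistic is a phase
quantity, so filter phase distortion must be avoided.  Band filtering runs
per epoch, after segmentation; windows of ≥ 2 s at 125 Hz are long enough
that the zero-phase filter's edge transients do not dominate (we measured
their effect on the PLI null and it does not vanish with edge-trimming, so
no trimming is applied by default).

Per band-limited epoch, the instantaneous phase of each channel is the
argument of the analytic signal (Hilbert transform), and for every channel
pair the Phase Lag Index is

    PLI = | ⟨ sign( sin(Φ_i(t) − Φ_j(t)) ) ⟩ |,

the absolute time-mean of the sign of the sine of the phase difference.
sign(0) contributes 0, making PLI(x, x) = 0 exact and zero-lag
(volume-conduction-like) coupling invisible.  With 16 channels this gives
120 pairs per band and 480 features per epoch, ordered bands-outermost
(theta, alpha1, alpha2, beta), pairs in row-major upper-triangle montage
order.  The `index_map` carried with every feature matrix makes the layout
explicit.  Features can be used per epoch ("epoch mode") or averaged over
a recording's epochs into one sample per subject ("subject mode"); both
are supported because epoch-level splitting of within-subject windows
leaks subject identity across the train/test boundary — `run_cv`
demonstrates this directly, and the default CV grouping is therefore by
subject.

## The Conv_gMLP regressor

The regressor is a gated MLP adapted to 1-D feature vectors:

1. **Channel expansion.**  A kernel-size-1, stride-1 1-D convolution lifts
   the 1×480 input to d_channel×480.  With one input channel, kernel k is a
   scalar weight and bias: row k = w_k·x + b_k.  This map, A, is also the
   attribution target.
2. **gMLP blocks** on X ∈ R^(480×d_channel) ("spatial" = feature axis,
   "channel" = expanded axis): `shortcut = X; X = norm(X);
   Z = GELU(X U); Z̃ = SGU(Z); Y = Z̃ V; return Y + shortcut`, with U:
   d_channel→2·d_ffn and V: d_ffn→d_channel.  The Spatial Gating Unit
   splits Z in half along the channel axis into u and v, normalizes v,
   applies a spatial linear map W^T v + b (W ∈ R^(480×480), b broadcast
   over channels), and returns u ⊗ (W^T v + b).  W is initialized uniform
   in ±1e-3 and b to 1, so each block starts as an identity-gated linear
   layer; the zero-init identity (W=0, b=1, norm off ⇒ SGU output = u) is
   asserted by the tests.
3. **Head.**  Average-pool over the feature axis, then a linear map
   d_channel→1.

The **SC ablation variant** applies the spatial gating first, on the
d_channel-wide stream (which must be even to split), then the
FFN projections; the proposed ordering (channel projection → spatial
gating) is variant **CS**.  The exact SC wiring is a documented repo
convention — the ablation is specified only by its ordering.

Normalization is selectable: `batch` (per-channel statistics over batch ×
spatial positions, running averages at inference), `layer` (per-position
over channels), or `none`.  The package default configuration is
d_channel 64, 8 blocks, d_ffn 256, BatchNorm, batch size 96, Adam at
5.5e-4 — the configuration a 30-trial TPE search over the documented
space selects for clinical-scale data.  Training minimizes MSE with Adam,
holds out 10% of the training data for validation (whole subjects when
group labels are provided), early-stops on validation MAE with patience
20 (default), and restores the best-validation parameters.  The head bias
is warm-started at the training-label mean.  Training is deterministic
given the spec seed.

There is no GPU framework dependency: the networks (Conv_gMLP, the MLP
and 1-D CNN comparators) run on a small reverse-mode autodiff engine over
numpy written for this package (`eegsev.autodiff`).  Every operator's
gradient, and every model parameter tensor's gradient, is validated
against central finite differences in the test suite.

## Baselines

MLP (ReLU, num_layers × num_ffn) and a 1-D CNN (two conv stages of 32/64
filters, kernel 7, same padding, max-pool 2, then two linear+ReLU modules
— depth and kernel sizes are a repo convention, as only the linear output
modules are prescribed) share the autodiff engine; LightGBM and XGBoost
are wrapped from their libraries with hyperparameters clamped (with a
warning) to the documented search-space bounds.  A CatBoost comparator is
not included.  All baselines expose the same `fit(X, y, groups)` /
`predict(X)` contract so the evaluation code is model-agnostic.

## Evaluation protocol

`run_cv` performs 3 × 5-fold cross-validation (15 fits) and reports the
mean and population standard deviation of fold MAEs.  Subject grouping
shuffles unique subjects per repeat (seeded) and never splits a subject;
epoch grouping is retained as a replication mode.  `window_sweep` reruns
the full preprocess → features → CV pipeline per window length.

`tpe_minimize` is a self-contained Tree-structured Parzen Estimator:
10 random start-up trials, then the observed trials are split at the
γ·√n best (γ = 0.25, capped at 25), per-parameter 1-D Parzen densities
l(x) and g(x) are built over good/rest (log-space for loguniform
parameters, Laplace-smoothed categoricals for choices), and the best of
24 candidates drawn from l under the l/g log-ratio is evaluated next.
Component widths are neighbor distances clipped to [span/100, span/8],
and a full-span prior component is always mixed in so the sampler keeps
exploring; bounded draws use rejection rather than clipping to avoid
boundary atoms.  On seeded 2-D quadratic problems this beats equal-budget
random search in ~19/20 runs.  Search spaces follow the documented
per-model tables (e.g. LightGBM num_leaves ∈ [16, 96], learning rate
loguniform [5e-3, 0.1]; gated-MLP d_channel ∈ {32...256}, learning rate
loguniform [5e-5, 1e-3]); budget 30 trials.  By default the trial
objective is a cross-validated MAE on held-out folds; optimizing test-set
MAE directly is possible but not the default, for the obvious selection-
bias reason.

## Grad-RAM attribution

For a sample (x, y) the regression target is y_e = 1 / ((ŷ − y)² + 1e-9)
— large where the model is accurate; at zero error it equals exactly
1/1e-9.  With A the channel-expansion output (the model's only
convolutional layer), channel weights are α_k = (1/480) Σ_s ∂y_e/∂A_{k,s}
(the normalizer is the single spatial axis length), and the feature map is
L = ReLU(Σ_k α_k A_k) ∈ R^480_{≥0}.  Gradients come from the autodiff
tape, which retains gradients on intermediate tensors.  Cohort-level
attributions average per-sample maps over the evaluated set.  Rollups
credit each pair feature to both member electrodes (an undirected feature
has no single anatomical home), electrodes sum into five regions (frontal,
central, parietal, occipital, temporal), and features sum by band; hence
Σ region = 2 × Σ features while Σ band = Σ features.

A structural consequence worth knowing: because A is affine in x with
position-independent coefficients, the per-sample map is
ReLU(c₁·x_f + c₀) — a rectified affine function of the feature *value*.
Band-level comparisons are therefore only meaningful against a
band-uniform background level, which drives a generator design decision
below.

## Synthetic cohort generator

Each channel is a sum of four unit-amplitude narrowband oscillations (one
per band; carriers 6, 9, 11.5, 21.5 Hz) with Wiener phase noise, scaled
to 10 µV, plus white Gaussian noise at 10 dB SNR per channel (the noise
model and level are package choices; disable with `snr_db=None`).

A `CouplingSpec` plants a band-specific phase coupling on an electrode
pair: strength κ ∈ [0, 1] and lag ∈ (0, π) (0 and π excluded — invisible
to PLI).  Couplings in one band sharing electrodes are merged into a
group driven by one common phase walk, with per-channel offsets assigned
over a spanning tree of the coupling graph, so every planted pair keeps a
consistent lag (independent walks per overlapping pair would destroy it).
A coupled channel's band phase is the blend
(1 − κ)·own walk + κ·(common walk + offset): phase-domain blending makes
pair PLI monotone in κ by construction (the relative-phase diffusion
shrinks as (1 − κ)² while the consistent lag grows as κ·lag) and reaches
PLI ≈ 1 at κ = 1.  An earlier amplitude-domain mixture was rejected
because PLI dipped below the null at small κ.

Per-band phase-diffusion rates (theta 3.14, alpha1 4.38, alpha2 3.56,
beta 2.65 rad²/s) were calibrated once by Monte-Carlo so that uncoupled
pairs show the same PLI null (≈ 0.20) in every band at the default 10-s /
125 Hz analysis setting.  A single shared rate gives band-dependent nulls
(narrow band filters smooth the phase walk and raise the apparent
synchrony), and with a value-affine attribution map a band-uniform null
is a precondition for interpreting band-level attribution at all.

Severity maps to coupling through a configurable function; the default
scales κ linearly (severity/56) on four fronto-temporal beta pairs
(FP1–T3, FP2–T4, F7–T3, F8–T4), so attribution recovery has a known
target.  Cohort severities are uniform on [0, 56] by default; a bimodal
healthy-control/patient preset (N(2.3, 0.9) and N(24.6, 8.1), mixed
39:80) is provided.  Labels are severity plus optional Gaussian noise,
clipped to [0, 56].

**What the generator does not emulate:** 1/f background spectra, ocular
and muscle artifacts, volume conduction (zero-lag mixing), non-stationary
coupling dynamics, and inter-subject anatomical variability.  Passing the
synthetic recovery study therefore shows that the pipeline recovers
planted phase-lag structure and attributes it correctly — not that the
model would reach any particular accuracy on clinical recordings.

## Recovery study (the package's headline experiment)

`evaluation.recovery_study` generates the default cohort (120 subjects ×
600 s), computes subject-averaged 480-dimensional PLI features at 10-s
windows (one sample per subject; 60 epochs averaged), makes a
subject-grouped 80/20 split, trains the gated-MLP regressor, and evaluates

- test MAE against the train-mean predictor's MAE (the no-information
  baseline, ≈ 14 for uniform labels on [0, 56]);
- the mean Grad-RAM rank of the 4 planted features among 480 on the test
  set;
- the band-score ranking (beta should lead).

The study uses a reduced model configuration — d_channel 16, 2 blocks,
d_ffn 64, no normalization, Adam 1e-3, ≤ 120 epochs — sized for ~100
subject-level samples: with so few samples per batch-statistics update,
BatchNorm's running averages interact badly with best-epoch restoration,
and the un-normalized variant is both faster and markedly more accurate
at this n (test MAE ≈ 1.6 vs ≈ 8.8 at seed 1).  This is a property of the
small-sample synthetic regime, not a claim about the clinical-scale
configuration, where batch statistics are computed from far more data.
`scripts/acceptance.py` reruns this study from scratch and writes the
measured quantities as JSON.

## Numerical notes and edge cases

- Phases are wrapped to (−π, π]; the −π edge returned by `np.angle` is
  folded onto +π.  Constant channels raise (phase undefined).
- PLI of series shorter than 2 samples raises; length mismatches raise.
- Resampling uses polyphase filtering with the rational rate ratio;
  upsampling is rejected.
- EDF output is plain 16-bit EDF with 1-s records (integer sampling rates
  only; physical range padded by 1 µV); round-trip error is bounded by the
  16-bit quantization step.  EDF input is read through `mne` with channels
  reordered to the canonical montage; missing montage channels raise.
- The EDF severity label travels in the cohort manifest CSV, not the EDF
  header.
- All randomness (generator, splits, initializations, batch order, TPE)
  derives from integer seeds; identical seeds give bit-identical results
  on a fixed platform.
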