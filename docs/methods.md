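# Methods

This note documents the models, numerical choices and limitations behind
`emg2stroke`: a pipeline that classifies single-channel surface-EMG grasp
recordings as *control* or *post-stroke* from time–frequency images using
compact CNNs.

## Acquisition protocol and the synthetic cohort

The pipeline targets one bipolar surface-EMG channel over the flexor
digitorum profundus, sampled at 250 Hz during a timed protocol: 30 s of
stabilization, then 5 cycles of a 6 s sustained grasp followed by 15 s of
rest — a 135 s session of 33,750 samples. Because no public recordings of
this protocol exist, the `synthetic` module generates protocol-faithful
sessions so that every downstream stage is testable end to end.

The signal model is

```
x(t) = A · e(t) · c(t) + a_pl · sin(2π·50·t + φ) + σ_w · n(t)
```

* `c(t)` — the EMG carrier: Gaussian noise spectrally confined to a
  configurable band, default **110–122 Hz**. The band brackets the
  115–120 Hz analysis passband used downstream, so synthetic energy
  survives filtering. Shaping is done by zeroing rFFT bins outside the
  band and renormalizing to unit variance.
* `e(t)` — the activation envelope. Each grasp window gets a raised-cosine
  envelope with 0.5 s on/off ramps. A *fragmentation* parameter k splits
  the window into k burst-like sub-envelopes (60 % duty, random per-burst
  strength in [0.6, 1]) separated by quiet gaps.
* Per-cycle onset times are jittered with a configurable standard
  deviation (*rhythm jitter*), clipped so grasps stay ordered and inside
  the session.
* 50 Hz powerline interference (pure sinusoid, random phase) and white
  baseline noise are added throughout.

Default phenotypes encode the qualitative contrast reported for paretic
muscle — attenuated activation, clustered/burst-like activity, irregular
contraction rhythm:

| parameter            | control | stroke |
|----------------------|---------|--------|
| burst amplitude      | 1.0     | 0.45   |
| fragmentation        | 1       | 3      |
| rhythm jitter (s)    | 0.05    | 0.4    |
| powerline amplitude  | 0.15    | 0.15   |
| white-noise sigma    | 0.08    | 0.08   |

The stroke amplitude (0.45) and fragmentation (3) are not published
quantities; they were fixed once at values that give a clear but
noise-contaminated group contrast (grasp-window RMS ratio ≈ 0.3 after
noise). All randomness flows from explicit integer seeds; per-subject
seeds are drawn from a master seed, so cohorts are bit-reproducible.

**What the generator does *not* emulate:** motor-unit action potentials,
recruitment/firing-rate structure, electrode artifacts, movement artifacts,
inter-subject anatomical variability, or any realistic spectral shape
outside the carrier band. Passing tests therefore demonstrate that the
pipeline's machinery is correct and that it separates groups whose
difference matches the modelled phenomenology — not that the classifiers
would reach comparable accuracy on clinical recordings.

## Preprocessing

Fixed order: 50 Hz notch → 115–120 Hz band-pass → min–max normalization
→ segmentation.

* **Notch**: IIR notch at 50 Hz, Q = 30 (≈1.7 Hz bandwidth — a standard
  powerline notch; the bandwidth is not a published value).
* **Band-pass**: Butterworth of total order 4 (two pole pairs per skirt).
  The unusually narrow 115–120 Hz passband is deliberate: the recordings
  this pipeline models carry their discriminative energy near 118 Hz, and
  lower frequencies are dominated by motion artifacts. The digital design
  places the −3.01 dB points exactly at the band edges; tests verify this
  against the closed-form analog magnitude response.
* Both filters are applied forward–backward (`filtfilt`), i.e. zero phase,
  so grasp onsets are not delayed — segment windows would otherwise drift
  against the protocol schedule. Attenuations quoted for a single pass
  double in dB under zero-phase application.
* **Normalization** is per whole recording (not per segment), preserving
  relative amplitude between contractions of one subject. Constant signals
  raise a degenerate-input error rather than silently returning zeros.
* **Segmentation** is disjoint-window, one 6.0 s window per grasp cycle
  (the protocol fixes windows between 5 and 6 s; 6.0 matches the grasp
  duration and is configurable). Default placement uses the generator's
  ground-truth onsets (*schedule* mode); a moving-RMS threshold detector
  (*threshold* mode) is provided for data without onset metadata and falls
  back to the schedule with a warning when it does not find exactly one
  burst per cycle. Segments are labeled `H0XX_NN` / `P0YY_NN`.

## Time–frequency representation

The transform is a frequency-adaptive Gaussian-window analysis
(Stockwell-transform family):

S(τ, f) = (|f|/√(2π)) ∫ b(t) · exp(−(τ−t)² f²/2) · exp(−j2πf t) dt

The window standard deviation is 1/f seconds, so frequency resolution is
traded for time resolution as f grows; the |f|/√(2π) prefactor makes the
window unit-area, giving |S| = 1 for a unit complex tone at its own
frequency. At f = 0 the transform degenerates and the signal mean is used
(the standard convention). Frequencies are reported on a normalized axis
with 1.0 = Nyquist; at 250 Hz the 115–120 Hz passband sits at 0.92–0.96,
inside the 0.9–1.0 band rendered prominently ("yellow line") in control
spectrograms.

Two evaluators:

* `tfr_brute_force` — the direct Riemann sum over every (τ, f) pair; the
  correctness oracle, also used for the closed-form impulse and tone tests.
* `tfr_fast` — per analysis frequency, the modulated signal
  b(t)·exp(−j2πft) is convolved with the sampled Gaussian window via
  zero-padded FFTs (exact *linear* convolution). A circular spectral
  implementation would wrap the Gaussian at low analysis frequencies where
  the window is wider than the segment; the zero-padded form matches the
  oracle to machine precision (~1e−16 relative Frobenius) at every
  frequency. Cost is O(n_freq · N log N); a 1500-sample segment on a
  451×451 grid takes ~0.15 s.

Near Nyquist a *real* tone's negative-frequency image lies only
fs − 2f away after aliasing and leaks through the wide Gaussian window,
beating against the positive component; single-column ridge positions are
therefore only clean for analytic (complex) tones. This is a property of
the transform, not an implementation artifact — both evaluators agree.

**Rendering**: power in dB (10·log10(|S|² + 1e−12), clipped to
[−120, 0] dB), min–max scaled over the image's own range (so a uniform
power factor does not change the image; an all-equal matrix renders as the
lowest color), flipped so frequency increases upward, bilinearly resampled
to 451×451, then quantized through a 256-entry viridis lookup table.
Quantization happens after resampling, so every pixel is an exact LUT
entry and higher power always maps to a higher LUT index. Images carry no
axes, ticks or margins.

## Feature-image datasets

Four datasets, one 451×451×3 RGB image per contraction segment:

1. **spectrogram** — the full-band rendering above.
2. **yellow_roi** — only rows with normalized frequency in [0.9, 1.0]
   (46 of 451 bins on the default grid), re-rendered to full height
   (stretched, not padded).
3. **amplitude_spectrum** — the one-sided DFT magnitude of the
   mean-subtracted segment drawn as a connected polyline (single blue line
   on white, no axes). Mean subtraction keeps the DC bin from dwarfing the
   carrier peak after per-image scaling.
4. **peak_strength** — local maxima of the amplitude envelope drawn as
   red stems over time. The envelope is the Hilbert (analytic-signal)
   magnitude smoothed by a 50 ms moving average; a rectify-and-average
   envelope was rejected because the rectified carrier's 2f component
   aliases to fs − 2f ≈ 14 Hz for the 115–120 Hz band at 250 Hz and
   ripples through any short average, producing dozens of spurious maxima.
   Peaks require prominence ≥ 0.1 of the envelope maximum (configurable).

The spectrum/peak renders are hand-rasterized rather than drawn through a
plotting backend so that datasets are deterministic pixel-for-pixel across
environments.

## Classifiers

Three architectures on a numpy layer engine written for this package
(convolution via im2col + matmul, 2×2/stride-2 max pooling, ReLU,
per-channel batch normalization with running statistics, dense + softmax):

* **shallow** — one 5×5 convolution (8 filters) + pool + ReLU + dense.
* **lenet5** — classic three-stage form: 5×5 convolutions with 6/16/120
  filters, 84-unit dense layer, softmax head.
* **tri_ccnn** — 5×5(8) → pool → ReLU → 3×3(8) → batch norm → pool →
  ReLU → 2×2(4) → pool → ReLU → dense → softmax; shrinking kernels with
  batch normalization after the second convolution. Input channel counts
  follow filter chaining (8 feeds the second conv, 8 feeds the third).

Training regime (identical for all models): SGD with momentum 0.9,
learning rate 1e−4, mini-batch 4 (last batch may be smaller), exactly 10
epochs, cross-entropy loss, no early stopping, no schedule, no weight
decay. Weights use He (fan-in-scaled) initialization; momentum 0.9 is the
conventional SGDM default. All randomness (init, shuffling) is seeded and
runs are bit-reproducible on one device; the backward pass is verified
against central finite differences.

The first dense layer is sized by a dry forward pass, so models accept any
input grid. The native image geometry is 451×451×3; for CPU-budget runs
the images are bilinearly resized to a **reduced training grid, default
80×80**. The grid must not be made too small: the Tri-CCNN trunk divides
the spatial extent by 8 and its last stage has only 4 filters, so at
~48 px it flattens to only 64 features (vs ~11.7 k at 451 px), crippling
the very capacity the three-architecture comparison is about; 80 px is the
smallest grid that preserves the relative head sizes of the three models.
Grids below 20 px collapse Tri-CCNN entirely and are rejected with a
configuration error.

## Evaluation

Holdout splits at train fractions 0.70/0.80/0.90, stratified by class,
with per-class train size floor(fraction·n) — deterministic sizing,
seed-dependent membership only. A subject-level mode keeps all five
segments of a subject on one side (the leakage-safe alternative; the
default segment-level split mirrors the common practice for this kind of
small-cohort study, but note it lets segments of one subject appear on
both sides).

Metrics (positive class = stroke): accuracy, precision, recall and F1 as
percentages; a zero denominator returns 0 with a `degenerate` flag rather
than NaN — the outcome produced when a model predicts one class for the
whole test side. No confidence intervals are emitted; interval
construction is left to the caller.

`evaluate_matrix` runs the full architecture × dataset × split (× seed)
grid and `run_pipeline` ties all stages together under one YAML-serialized
config whose hash stamps the run manifest; an unchanged config with
existing outputs is skipped.

## Problem sizes used by tests and the acceptance script

The default study cohort is 10 control + 10 stroke subjects → 100
segments → 100 images per dataset kind. The acceptance script renders
spectrograms at the native 451 grid, checks transform-oracle equivalence
on 50 random 64-sample signals, metric arithmetic on 1000 random label
vectors, and trains Tri-CCNN and LeNet-5 on the spectrogram dataset at the
80 px training grid over three splits and three derived seeds (~2.5 min on
one CPU in total).

## Known limitations

* Synthetic data only; see the generator caveats above. Accuracies on this
  cohort (≈100 %) reflect the strong programmed group contrast, not
  clinical difficulty.
* Single channel, single muscle, fixed protocol timing.
* The narrow 115–120 Hz band is taken as given; no attempt is made to
  validate it as an EMG practice (conventional surface-EMG analysis uses
  20–500 Hz).
* The CNN engine is CPU-only and optimized for clarity and determinism,
  not throughput; the 451 px native grid is impractical to train on
  directly and is always reduced first.
* Batch normalization uses running statistics at evaluation; with batch
  size 4 the train/eval statistics mismatch adds variance on very small
  datasets.
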