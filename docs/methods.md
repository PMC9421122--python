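# Methods

## Scope

`pcgbench` compares data-augmentation strategies for binary heart-sound
classification from Mel-spectrogram images. Eleven arms share one dataset, one
preprocessing chain, one spectrogram recipe, one CNN architecture and one
stratified fold plan; the arms differ only in how each training fold is
doubled. This note records the model, the defaults and why they were chosen,
the numerical conventions, and what the synthetic data does and does not show.

## Synthetic PCG model

Clinical PCG corpora cannot be redistributed with a package, so the generator
produces recordings with the statistical structure the analysis needs:

* **Cardiac cycle.** S1 and S2 are Gaussian-windowed sinusoidal bursts
  (envelope σ of 18 ms and 15 ms, ≈90 ms audible duration) placed at the cycle
  start and at end-systole; systole is fixed at one third of the cycle, a
  standard physiological approximation. Heart rate is drawn uniformly from
  60–100 bpm per recording with 1% beat-to-beat jitter; S2 is 0.7× the S1
  amplitude.
* **Frequency content.** Burst center frequencies are drawn inside the
  configured S1 (30–100 Hz) and S2 (50–150 Hz) bands with a 3σ spectral margin
  (σ_f = 1/(2πσ_t)), so each burst's energy stays within its band — without
  the margin, S2 tones near 150 Hz leak into the murmur band and blur the
  class boundary, which would be a modelling artifact rather than physiology.
  A band-limited noise floor (20–480 Hz) sits at −30 dB relative to the
  S1/S2 RMS.
* **Abnormal class.** Exactly one extra component per abnormal recording:
  a systolic murmur (probability 0.60), diastolic murmur (0.38), S3 (0.01) or
  S4 (0.01). Murmurs are 4th-order-Butterworth band-limited Gaussian noise
  (150–400 Hz) gated into the systolic or diastolic interval with 20 ms ramps,
  at −12 dB relative to the S1/S2 RMS — audible but quieter than the valve
  sounds. S3/S4 are 25–60 Hz bursts placed 120 ms after S2 / 100 ms before S1.
  Murmurs dominate the mix because gallop-only presentations are rare in
  referral PCG data, and because the generator is calibrated so that a
  murmur-band (150–400 Hz) energy threshold separates the classes at
  ROC AUC ≥ 0.95 — the documented guarantee that downstream stages have
  signal to learn; gallop-only recordings carry no murmur-band energy, so
  their share bounds that statistic.
* **Bookkeeping.** Sample rate 2000 Hz (the PhysioNet/CinC 2016 convention),
  durations uniform on 6–60 s, class imbalance ≈3.9:1, per-record seeds
  derived from a master seed via `numpy.random.SeedSequence`; identical
  arguments give bit-identical WAV files.

What the generator does **not** emulate: real murmur morphology (crescendo/
decrescendo shapes, radiation), respiratory and stethoscope-handling noise,
sensor variation, inter-subject correlation, or disease mixtures. Passing
tests therefore demonstrate that the pipeline is correct and that the
comparison machinery behaves as designed — not that any augmentation ranking
transfers to clinical recordings.

## Preprocessing

3rd-order Butterworth band-pass, 20–500 Hz. The filter is applied
forward-backward (`sosfiltfilt`): the effective magnitude response is the
square of the design response, but there is no group delay, so S1/S2 onsets
are not shifted — preferable for transient-based signals. Recordings shorter
than 8 s are discarded (exactly 8 s is kept); recordings longer than 30 s keep
their first 30 s (exactly 30 s is untruncated). Amplitude is then peak
normalized, `x / max(|x|)`; normalization comes last so the peak is measured
after filtering. An all-zero signal is a degenerate input and raises.

## Spectrograms and images

Frames: Hann window of 512 samples, hop 256, no padding
(`floor((len−512)/256)+1` frames), 512-point FFT, squared magnitude. The Mel
filterbank (128 triangular channels) is built on
`Mel = 2595·log10(1 + f/break)` with **break = 500 Hz by default** — the
convention this pipeline standardises on (2595 pairs with log10); the common
700 Hz break is a config switch. dB conversion uses the amplitude convention
`20·log10(A/A_max)` (a power-convention switch is exposed), clamped at
−80 dB, with the loudest Mel cell as the 0 dB reference. The dB matrix maps
through a perceptually-uniform dark-to-yellow colormap (`inferno` by default)
and is bicubic-resized to 100 rows × 180 columns × 3 channels, low
frequencies at the bottom. 128 Mel channels before a 100-row resize keeps the
filterbank comfortably oversampled relative to the image grid.

## Augmentation arms

Every method preserves the class label and is sampled independently per
training item from a seed derived from (master seed, item index, method).

* **Pitch/time (arm 1).** Phase vocoder (Hann 512, hop 128, reflect-centered),
  so the two operations are independent: pitch shift by p semitones
  (p = ±integer 1–10, sign equiprobable since only "up or down" is specified)
  scales frequencies by 2^(p/12) at constant duration; time stretch by
  t ~ U[0.5, 2.0] scales duration at constant pitch. Applied pitch-first.
  The shifted/stretched audio is re-peak-normalized before re-rendering.
* **Noise (arm 2).** Element-wise i.i.d. N(0, σ²) with σ = RMS(signal) — a
  0 dB SNR by construction. The sum is peak-normalized afterwards to keep
  samples in [−1, 1] (the clipping behaviour is otherwise unspecified).
* **Flips (arms 3.1/3.2).** (x, y) → (width−x−1, y) and (x, height−y−1);
  bit-exact involutions.
* **SV perturbation (arm 4.1).** Two blending passes,
  `Blend·(1−α) + Original·α`: brightness against a black image
  (α ~ U[0.5, 2]), then saturation against the image's own luma grayscale
  (α ~ U[0.1, 2]); brightness first (the order is otherwise unspecified);
  channels clipped to [0, 255].
* **PCA color augmentation (arm 4.2).** Eigen-decomposition of the 3×3
  covariance of the image's raw 0–255 RGB values (per-image by default; a
  dataset-wide mode is exposed). One α ~ N(800, 10) multiplies all three
  eigenvalues and `P·(α·λ)` is added to every pixel, then clipped.
  Eigenvectors are sign-normalized (largest-magnitude component positive) so
  the perturbation direction is well defined. With α ≈ 800 on this pixel
  scale the shift is large and the output saturates along the first principal
  component — the parameterization is deliberately aggressive, and the
  harness measures its effect rather than moderating it.
* **Random color filters (arm 4.3).** One conversion drawn uniformly from a
  versioned registry of exactly 150 three-channel color-space mappings
  (channel permutations/inversions and scikit-image conversions to
  HSV/XYZ/LAB/LUV/YUV/YIQ/YPbPr/YCbCr/YDbDr/RGB-CIE/HED with fixed affine
  range-mapping, plus their permuted/inverted variants), output reinterpreted
  as RGB.
* **Masking (arm 5).** Applied to the Mel dB matrix before colormap/resize:
  three frequency masks [f₀, f₀+f) and three time masks [t₀, t₀+t), integer
  widths uniform on [0, 20] (channels are discrete), starts within
  (0, v−f) / [0, τ−t]; masks may overlap. Masked cells are set to 0 dB so
  they render at the colormap maximum (bright bars). Pre-resize masking keeps
  mask widths defined in spectrogram units.
* **Compositions (arms 6/7).** PCA then horizontal flip; SV then horizontal
  flip — in that printed order (flips commute with per-pixel color
  operations, so the order only matters for bookkeeping).

## CNN

conv(32, 3×3, stride 1, ReLU) → maxpool(2×2, stride 2) → conv(64, 3×3,
stride 1, ReLU) → maxpool(2×2, stride 2) → flatten (63,296 for 100×180×3) →
dense(64, ReLU) → dense(1, sigmoid). No padding in any layer. Adam
(lr 1e−3, β = 0.9/0.999), binary cross-entropy on logits, 10 epochs, batch
size 32, pixels scaled to [0, 1], He-normal initialization from a per-fold
seed. Batch size, learning rate, the hidden-layer ReLU and the [0, 1] input
scaling are unstated in the source recipe and fixed here as the conventional
choices. The implementation is numpy (im2col + BLAS matmuls, with optional
numba-fused pooling/Adam kernels; both paths produce bit-identical pooling
decisions and agree to float32 rounding in gradients). Training is
deterministic for a fixed seed and example order; the architecture hash is
asserted identical across arms.

## Evaluation

Stratified k-fold (k = 5 by default; k is not fixed by the source recipe and
is config-exposed) built once per experiment and shared by all arms — paired
comparisons are only meaningful on identical folds, and the fold-plan hash is
recorded in every arm result. Augmentation is applied to training folds only;
a leakage guard asserts every augmented item's source lies in the training
fold. Metrics per fold: accuracy and F1 (abnormal class) at threshold 0.5,
sensitivity, specificity at the loosest threshold whose sensitivity ≥ 0.90
(no interpolation; with all-tied scores this is 0 by construction), ROC AUC
(trapezoidal; equals pairwise concordance), PR AUC (average precision, step
interpolation). Across folds: mean and 95% t-interval; arm-vs-baseline
comparisons use the paired per-fold difference with a 95% t-interval
(`mean ± t₀.₉₇₅,ₖ₋₁·sd/√k`; zero-variance differences give a point
interval), and the significance call is whether the interval excludes zero.

## Problem sizes

The package's own validation runs the baseline arm at the study scale used
throughout — 400 recordings (318:82), k = 5 — where the baseline CNN reaches
mean ROC AUC ≥ 0.90 on synthetic data, and exercises all eleven arms
end-to-end on a smaller dataset (18 recordings, k = 2) chosen to keep the
whole suite fast on one CPU; `scripts/acceptance.py` uses 120 recordings with
k = 3 for its two-arm experiment. These sizes are reproducibility choices:
the comparison machinery is identical at every scale, but confidence
intervals at desk scale are wide, and arm rankings on synthetic data are not
evidence about clinical recordings.

## Known limitations

* The synthetic abnormal class is acoustically easy; absolute metric values
  are far above what clinical data yields and should not be quoted as
  performance claims.
* The phase vocoder introduces the usual transient smearing; pitch/duration
  ratios are accurate to well under 2% on tones, which is what the tests pin.
* PCA color augmentation at α ~ N(800, 10) saturates images (see above); the
  arm is faithful to its printed definition rather than useful.
* `specificity@90% sensitivity` is undefined without positive test examples;
  fold plans guarantee at least one positive per fold only when the minority
  class has ≥ k members, which the config validator enforces.
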