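# Methods

## The problem

In an auditory oddball brain–computer interface, a listener attends to one
of six virtual sound directions while 100 ms noise bursts arrive from all
six in pseudorandom order. A burst from the attended (*target*) direction
elicits a P300 — a positive EEG deflection 250–700 ms after stimulus onset,
strongest over centro-parietal scalp. The classification task is single-trial
and heavily imbalanced: 1 trial in 6 is a target.

This package implements the full experimental pipeline on simulated data:
an oddball EEG simulator, the preprocessing chain, a spatially faithful
tensor encoding of each trial, a family of small convolutional networks
indexed by convolution/pooling patch shapes and pooling strides, a
class-balanced accuracy metric, and one-way ANOVA comparisons across the
model family.

## Synthetic recordings

The simulator is first-class, tested code; its defaults are the study
conditions.

**Schedule.** Each subject completes 12 sessions of 180 trials at a fixed
trial length (500, 400 or 300 ms — stimulus plus silence). Directions are
pseudorandomized in blocks of six: every aligned block is a permutation of
the six directions, so the target rate is exactly 1/6, and block
permutations are redrawn so that no two targets are ever consecutive —
enforced across block *and* session boundaries (the conservative reading;
the boundary case is patched by redrawing the first block of the next
session). The attended direction rotates 1..6 over sessions 1–6 and repeats
for 7–12.

**Signal.** 64 channels at 256 Hz, in microvolts:

* background: Gaussian noise with 1/f power spectrum (exponent 1.0),
  std 10 µV per channel — a realistic broadband EEG floor;
* drift: a 5 µV sinusoid per channel at 0.02–0.08 Hz with random phase;
* alpha: a 1 µV 10 Hz sinusoid (outside the analysis band; removed by the
  bandpass, present for realism);
* P300: for every target event, a Gaussian bump (default amplitude 5 µV,
  peak 400 ms post-onset, σ = 75 ms, per-event latency jitter σ = 30 ms)
  added to all channels scaled by a spatial prior — a Gaussian falloff on
  the electrode grid centred between Cz and Pz, normalized so the peak
  channel receives the full amplitude. Amplitude 0 makes the signal
  synthesis independent of the labels entirely (tested bit-exactly).

Sessions are concatenated with a 2 s gap, 1 s of lead-in and 1.5 s of
tail so every trial has a full analysis window.

**What the simulator does not emulate:** eye/muscle artifacts, channel
covariance of real EEG (noise is independent per channel), non-Gaussian
single-trial ERP variability, attention lapses, or between-subject
differences beyond seed and amplitude. Passing tests therefore demonstrate
the machinery and its contracts, not expected accuracy on human EEG.

## Preprocessing

1. **Bandpass** the continuous recording: Butterworth 0.1–8 Hz, order 4,
   applied forward–backward (zero phase, via second-order sections).
   Filtering precedes epoching so filter edge effects never sit inside an
   analysis window.
2. **Baseline correction**, per trial and channel: a Savitzky–Golay smooth
   of the span from 100 ms before onset to the end of the trial is
   subtracted from that span; beyond the trial end the trend's final value
   is carried forward (no step discontinuity). Window = the whole span,
   odd-forced; polynomial order 3. A shorter window (half the span) was
   rejected after measurement: with ~600 ms spans it tracks and removes the
   P300 bump itself (~90% amplitude loss); the full-span cubic removes
   constant, linear and slow trends while sparing ERP-scale structure.
   Note the correction span inevitably overlaps the deflection for long
   trials, so some attenuation is inherent to this scheme.
3. **Epoching**: 1100 ms after every stimulus onset, regardless of trial
   length — windows deliberately overlap succeeding trials for 300–500 ms
   trials. Events with less than 1100 ms of signal left are skipped with a
   warning.
4. **Decimation** by 10 (256 → 25.6 Hz): keep source samples 10, 20, …,
   280 relative to onset, i.e. exactly 28 samples in (0, 1100] ms. The 8 Hz
   bandpass is the anti-alias guard (new Nyquist 12.8 Hz). This integer
   convention is the single authoritative one; it is what makes "one
   feature map per time sample" come out to 28.

The pipeline is label-agnostic (tested by flipping labels).

## Input encodings

* **3D (grid) input**: each (64, 28) epoch is scattered onto a 10 × 11
  scalp grid → a (10, 11, 28) tensor. The 46 cells without an electrode
  are exactly zero in every slice; electrode read-back is the bit-exact
  inverse. Axis convention: rows anterior→posterior, columns left→right,
  axis 2 time.
* **2D (flat) input**: the (64, 28) epoch matrix itself.

The bundled layout file places the standard BioSemi-64 10/20 montage
row-wise on the grid (Fp row at the top, Iz at the bottom). The layout file
is the source of truth — any 64-channel assignment of distinct in-range
cells can be supplied, and the loader validates count, range and
duplicates with line-level errors.

## The classifier family

One convolution stage, one max-pooling stage, one hidden layer, softmax:

* **Convolution**: a single 2D spatial kernel shared across time slices
  (stride 1, valid), producing 28 feature maps — one per time sample —
  followed by tanh. A per-slice-kernels variant sits behind a flag.
  Patch shapes: [3×3], [2×2], [3×2], [2×3], [2×4], [1×4] (digits 0–5).
* **Max pooling**: patch from [2×2], [3×3], [1×2], [1×3], [2×3] (digits
  0–4); stride either "default" (= patch, non-overlapping) or fixed
  [1×1], [1×2], [1×3], [2×2], [2×3]. Window origins lie on the stride
  lattice; every origin inside the map is used, truncated at the boundary.
  A stride smaller than the patch on an axis makes windows overlap; a
  stride larger than the patch skips cells (both behaviours are exercised
  in tests).
* **Head**: flatten → 64 tanh hidden units (configurable; the depth and
  width of the head are not dictated by the family definition) → 2-class
  softmax.
* **Training**: mini-batch SGD, learning rate 0.008, batch size 100,
  100 epochs, no early stopping, class imbalance left untouched (it is
  compensated in the metric, not the loss). Weights are initialized
  uniform ±1/√fan-in from a seeded generator; training is bit-reproducible
  per seed. Backpropagation is hand-written numpy and verified against
  numerical differentiation.

A two-digit *patch code* (conv digit, pool digit) names each of the
6 × 5 = 30 models; with 6 stride options, 9 subjects and 3 trial lengths
the full study grid is 4860 trained networks.

## Evaluation

Per subject and trial length: shuffle targets and nontargets separately,
put half of each class in the training and test sets (odd counts: extra
example to training). A full subject gives ~1080 trials per set with 180
targets and 900 nontargets. Performance is

    accuracy = (TP / P) · (TN / N)

the product of per-class recalls, in [0, 1]; an all-nontarget predictor
scores 0 (plain accuracy would score 0.83). Every grid cell derives its
own training seed from the master seed via `SeedSequence`, so any cell
reproduces in isolation.

## ANOVA

Accuracies are first averaged over subjects, giving a 30 × 6 (code ×
stride) table per trial length. Two one-way fixed-effects analyses:

* across **models**: 30 groups with the 6 per-stride values as
  observations → df (29, 150), critical F(0.05) = 1.543;
* across **strides**: 6 groups with the 30 per-model values as
  observations → df (5, 174), critical F(0.05) = 2.266.

This observational unit is pinned down by those critical values; per-subject
replicates would give different df. The sum-of-squares decomposition is
computed directly (and checked against `scipy.stats.f_oneway` and a t-test
oracle in tests); only the F distribution's tail/quantile come from scipy.
Degenerate case: SS terms below float round-off of the raw sum of squares
are treated as zero, and an exactly constant table yields F = 0, p = 1.

## Problem sizes and numerical choices

* The quick grid (4 codes × 2 strides, one subject, 500 ms trials) is the
  package's standard demonstration size: ~2 minutes on one CPU at the
  default 100 training epochs; the full 4860-cell grid is the same code at
  scale.
* The "high-amplitude" regime used to demonstrate the learning property is
  10 µV (double the default), chosen once as an upper-range single-trial
  P300; it yields balanced accuracies around 0.83–0.93.
* Savitzky–Golay: full-span window, order 3 (see above). Butterworth:
  order 4, zero-phase. Decimation: integer, convention above.
* Ties in max-pooling resolve to the first (row-major) maximum; with
  continuous data ties have probability zero.
* Template support: the Gaussian bump is evaluated on [0, 1100] ms and is
  zero outside; latencies outside 250–700 ms are allowed for ablation but
  warn.

## Known limitations

* The baseline-correction span overlaps the P300 for 500 ms trials, so
  measured amplitudes are attenuated by design; conclusions about absolute
  accuracy transfer to real EEG only qualitatively.
* The grid layout is a reconstruction from standard montage coordinates,
  not a copy of any specific cap's published figure; left/right orientation
  follows the stated axis convention.
* The ANOVA treats the 30 × 6 table cells as independent observations; in
  reality they share training data, which inflates significance — the
  analyses are comparative summaries, not confirmatory inference.
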