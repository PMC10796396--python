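# Methods

This note records the scientific and numerical choices behind `intakefuse`:
what each stage computes, which parameters matter, what the synthetic data
does and does not emulate, and where the design was genuinely open.

## Signal model and segmentation

The pipeline assumes a head- or eyewear-mounted tri-axial accelerometer
sampled at 128 Hz. Chewing produces a band-limited oscillation at roughly
1–2.5 Hz, superimposed on a slowly varying gravity/posture baseline, sensor
noise, and transient motion (head turns, walking). The recording is cut
into fixed, non-overlapping 15-s windows (1920 samples per axis), matching
the camera's capture interval so each segment pairs with exactly one image.
A trailing partial window is discarded.

Ground-truth eating is an interval list (start/end seconds). A segment is
labeled intake when at least 50% of it overlaps a truth interval. The 50%
threshold is this package's convention for discretizing interval
annotations onto the segment grid; any episode lasting at least one window
is then guaranteed at least one intake segment, and boundary segments with
marginal overlap are not forced into the positive class.

## Scalograms

Each axis of a segment is transformed with a continuous wavelet transform
built on generalized Morse wavelets, the analytic family defined in the
frequency domain by Ψ(ω) ∝ ω^β exp(−ω^γ) for ω > 0. Defaults are symmetry
γ = 3 and time–bandwidth P² = βγ = 60 — the standard "Airy" parameterization
of common numerical toolboxes — exposed in `CWTConfig`. The filter bank
holds 64 center frequencies on a geometric grid over 1–64 Hz (geometric
spacing is the natural discretization of scale; a linear grid is available
as a config option). Scales are chosen so each filter's spectral peak lands
on its center frequency, and filters are L1-normalized (constant peak
height), so the magnitude of a unit-amplitude sinusoid reads as ≈ 1 in its
frequency row. The transform is computed by FFT multiplication; a test
verifies it against direct time-domain quadrature of the transform integral
to better than 1% at matched scales.

Quantization maps each per-axis 64 × 1920 magnitude onto 8-bit pixels with
min → 0 and max → 255, rounding half away from zero and clipping —
documented because environments differ in their float-to-uint8 casts. A
constant (flat) scalogram quantizes to all zeros with a logged warning
rather than raising, so gaps in free-living recordings do not abort batch
runs. Normalization is applied **per axis before concatenation**, so one
high-variance axis cannot blank the other two; normalizing over the
concatenated image instead is a one-line change and both behaviors are
covered by the same quantizer. The three quantized axis images are stacked
(x, y, z) to 192 × 1920 and the time axis is bilinearly downsampled to 192
columns using half-pixel-center coordinate mapping (each output value is a
weighted average of the closest two source columns; rows are untouched
because 3 × 64 already equals 192), then re-rounded to 8 bits.

## Sensor CNN

The 15-layer classifier is: conv → ReLU → cross-channel LRN → max-pool,
twice; conv → ReLU → max-pool; dropout; fully connected (2 units); softmax;
classification. Training runs 8 epochs at batch size 32. Only that layer
composition and training budget are fixed by the method; the remaining
hyperparameters are package defaults, all exposed in `ModelConfig`:

| parameter | default | note |
|---|---|---|
| conv filters | 8, 16, 32 | doubling per block |
| conv kernels | 5×5, 3×3, 3×3 | same padding, stride 1 |
| pooling | 2×2, stride 2 | halves each spatial dim |
| LRN | window 5, k = 1, α = 1e-4, β = 0.75 | after ReLU of blocks 1–2 |
| dropout | 0.5 | before the FC layer |
| optimizer | SGD, momentum 0.9, lr 0.02 | He initialization |

Inputs are scaled to [0, 1]; class imbalance is handled by
inverse-frequency sample weighting (free-living data is mostly non-intake).
The learning rate was set so that training converges within the fixed
8-epoch budget on the synthetic task; it is a package default, not a claim
about the original study. The network is implemented directly in NumPy
(im2col convolutions, analytic LRN gradient, inverted dropout), which keeps
the dependency footprint small and makes runs bitwise reproducible under a
fixed seed on single-threaded BLAS.

## Fusion

Per segment, image evidence is the maximum detector confidence over food
boxes (S_f) and over beverage boxes (S_b); a missing image contributes
S_f = S_b = 0 rather than dropping the segment, so sensor evidence still
flows. The predictor vector appends the n previous segments' scores,
zero-padded before the first segment (zero = "no evidence", the same
convention as a missing detection). The classifier is a random forest with
30 trees and at most 1000 splits per tree; the misclassification cost
matrix [0 1; 2 0] is realized as class weights {intake: 2, non-intake: 1},
the standard mapping of cost to weighted impurity in ensemble trees. The
fused score reported per segment is the fraction of trees voting intake.
Grid search over n = 0…4 maximizes validation F1, breaking ties toward the
smallest n (the cheapest model).

Two distributional points matter in practice and are reflected in the
pipeline defaults:

* the CNN needs training data spanning many chewing episodes (frequencies
  and orientations vary per episode); a training recording with only a few
  long episodes lets the network memorize them and fail on unseen meals;
* the fusion forest is sensitive to the intake prior, so it is trained and
  grid-searched on recordings with the same free-living episode statistics
  as the evaluation data. Trained instead on a dense-eating series, it
  passes isolated image false positives through, and a single such segment
  in a meal gap can bridge two meals under the 15-min merge rule.

## Events, episodes, matching

Maximal runs of intake segments become events spanning run start to run end
plus one window. Events with an inter-event interval strictly below 15
minutes merge into one episode; a gap of exactly 15 minutes starts a new
episode. Merging tracks the running maximum end time, so nested events
cannot split a cluster, and a test verifies equivalence with brute-force
transitive-closure clustering. Episode-level evaluation uses greedy
one-to-one matching in time order, requiring at least 1 s of overlap
(configurable): matched predictions are TP, unmatched predictions FP,
unmatched truths FN. The matching rule is this package's construction — at
episode level only sensitivity and precision are reported, and a single
predicted episode spanning two true meals counts one hit and one miss.

## Evaluation

Segment metrics follow the standard confusion-table formulas; undefined
ratios (zero denominators) are reported as NaN with a warning rather than 0
to avoid silently inflating averages. McNemar's test uses the
continuity-corrected statistic (|e01 − e10| − 1)²/(e01 + e10) against the
χ²₁ upper-α quantile computed from the inverse distribution function (α
configurable, default 0.01). Detection quality is mAP@[.5,.95]: average
precision is the trapezoidal area under precision–recall points sampled at
confidence thresholds 0, 0.1, …, 1.0, with detections matched greedily by
descending score to unmatched same-image truth boxes at the given IoU
threshold; AP is averaged over IoU thresholds 0.50–0.95 in steps of 0.05
and over the two classes, reported on the 0–100 scale. Split utilities
provide leave-one-subject-out folds and the seeded 80/10/10 holdout.

## Synthetic data: what it emulates, what it does not

The generator reproduces the statistical structure the pipeline relies on:
a drifting gravity baseline, Gaussian sensor noise (0.05 g), Poisson motion
bumps (20/h), and per-episode chewing bursts — an amplitude-modulated
sinusoid (0.15 g) at an episode-specific frequency from 1–2.5 Hz with mild
frequency jitter, projected onto a random orientation. Detector streams
draw positive scores from Beta(5, 2) and negative from Beta(2, 5), with
capture probability 0.7 in intake segments, false-positive rate 0.2
elsewhere, and 5% missing images; box fixtures jitter truth boxes and add
low-scored spurious boxes. The free-living default is a two-hour stretch
with 5–15-min meals separated by 16–40-min gaps, so distinct meals survive
the 15-min merge.

It does **not** model bite/chew/swallow microstructure, drinking without
chewing, device-specific noise spectra, image content, or inter-subject
variability. Passing tests therefore demonstrate that the pipeline
recovers a band-limited chewing signature and suppresses independent image
false positives under controlled conditions — not that it attains any
particular accuracy on real recordings, where class overlap is far larger.

## Problem sizes and runtime

The packaged benchmark trains the CNN on 200–220 segments (8 epochs, batch
32, ~2 CPU-minutes), the fusion forest on a 480-segment free-living series,
and evaluates on a 360–480-segment held-out day; the fusion-dominance check
runs 5 replicates over detector-stream seeds with the CNN trained once.
These sizes keep a full run in single-digit CPU-minutes while leaving every
stage's statistical structure intact.

## Known limitations

* The CNN's unreported hyperparameters (filters, kernels, optimizer) are
  package defaults; results on real data will depend on them.
* Chewing is a phenomenological oscillation model, not biomechanics; the
  synthetic task is easier than free-living classification.
* The episode-matching rule is a reasonable construction, not a community
  standard; episode-level numbers are only comparable under the same rule.
* AP uses raw trapezoids over the 11-threshold PR samples; interpolated
  variants give slightly different values.
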