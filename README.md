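# intakefuse

Passive detection of eating episodes from two wearable modalities: a
tri-axial accelerometer sampled at 128 Hz (chewing and temporalis-muscle
motion leave a band-limited 1–2.5 Hz oscillation) and an egocentric camera
that captures one image every 15 s, scored by an external food/beverage
object detector. The package is aimed at researchers in dietary monitoring
who need the full sensor-side pipeline — time–frequency transformation,
segment classification, score-level fusion, episode aggregation and the
matching evaluation suite — runnable end-to-end on synthetic data with the
same statistical structure as free-living recordings.

## Method

Each recording is cut into non-overlapping 15-s segments (15 × 128 = 1920
samples per axis), aligned with one image. Per axis, the continuous wavelet
transform with a generalized Morse mother wavelet (symmetry γ = 3,
time–bandwidth P² = 60) is evaluated on 64 center frequencies spanning
1–64 Hz:

    C(a, b) = ∫ s(τ) ψ*((τ − b)/a) dτ,        S = |C(a, b)|

The 64 × 1920 scalogram S is quantized to 8 bits,

    I(x, y) = round(255 · (S − S_min) / (S_max − S_min)),

the three per-axis images are concatenated to 192 × 1920 and bilinearly
downsampled along time to a 192 × 192 × 1 image. A 15-layer CNN (three
conv/ReLU/max-pool blocks, two cross-channel normalization layers, dropout,
a 2-unit fully connected layer, softmax, classification) is trained for 8
epochs with batch size 32 and emits the sensor confidence score S_s per
segment. Image evidence per segment is the maximum detector confidence over
food boxes (S_f) and beverage boxes (S_b). The per-segment predictor vector
with temporal lag n,

    [S_f(t) … S_f(t−n),  S_b(t) … S_b(t−n),  S_s(t) … S_s(t−n)],

is classified by a cost-sensitive random forest (30 trees, at most 1000
splits per tree, misclassification cost [0 1; 2 0] doubling the penalty on
missed intake); n is chosen by grid search over n = 0…4 on a validation
split. Maximal runs of intake segments become eating events; events closer
than 15 minutes merge into eating episodes. Evaluation covers segment-level
sensitivity, precision, accuracy and F1, episode-level matching, COCO-style
mAP@[.5,.95] for the detector, and McNemar's continuity-corrected test
χ² = (|e01 − e10| − 1)²/(e01 + e10) for paired classifier comparison.

## Worked example

```python
from intakefuse import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(seed=1))
print(report["chosen_n"])                                 # 4
print(report["segment_metrics"]["fused"]["f1"])           # 0.9953...
print(report["segment_metrics"]["image_only"]["f1"])      # 0.9315...
print(report["episode_metrics"]["fused"]["sensitivity"])  # 1.0
```

This simulates a dense training recording (220 segments, 10 chewing
episodes), free-living fusion/validation/test recordings (meals of 5–15 min
separated by 16–40 min), trains the CNN and the fusion forest, and evaluates
on the held-out day. With seed 1 the fused classifier reaches a segment F1
of 99.5% against 93.2% for the image-only baseline, whose false positives
also merge the test day's three meals into fewer detected episodes
(image-only episode sensitivity 66.7%, fused 100%) — the central benefit of
combining the two modalities. The same pipeline is available from the shell:

```bash
intake-fuse demo --seed 1 --out runs/demo
intake-fuse simulate recording --seed 2 --out runs/sim
intake-fuse evaluate mcnemar --e01 70 --e10 6
```

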