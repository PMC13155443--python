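# Methods

## Detection model

The detector treats mislabel identification as an out-of-fold
disagreement problem. The dataset is partitioned into n folds whose
sizes differ by at most one (remainders go to the earliest folds; fold
membership comes from a seeded permutation by default, since
consecutive 1-second trace segments are temporally correlated and
contiguous splits would let a fold share an event tail with its
training data — a `shuffle=False` flag restores contiguous splits, and
an optional `stratify` flag deals each class round-robin across folds).
In each round every ensemble member is rebuilt from its spec — same
initial weights every round, no state carried over — trained on the
n − 1 training folds, and asked for softmax vectors on the held-out
fold. No classification accuracy is computed from these
cross-validation models; their only job is to judge labels on data
they have not seen.

Votes are confidence-gated: a disagreeing prediction participates only
when its top softmax probability is **strictly greater** than δ. The
strict inequality is deliberate (an exactly-δ confidence does not
vote), and δ = 0 therefore means "no gate" because every softmax
maximum is positive. Abstentions do not shrink the denominator: a k/m
rule always compares the vote count against m, so an under-confident
ensemble can only fail to flag, never flag more easily. Consensus
filtering consequently requires all m members to be *gated voters*,
not merely to disagree.

Recovery is computed from the same m out-of-fold predictions: the
plurality class, with ties resolved first by the largest summed
probability over the tied classes and then by the lowest class index.
Ties are vanishingly rare for confident ensembles but the rule makes
the output deterministic. The report records recovered labels for
every sample flagged by at least one configured rule.

## Evaluation conventions

TP/FP/FN are set intersections between the flagged set and the
injected-flip set; TP + FN always equals the injection count.
Zero-denominator metrics (no flags, or no injections) are reported as
0 together with an `undefined` marker rather than NaN, so sweep tables
stay numeric. The recovery fraction is undefined (None/NaN) when no
injected sample was flagged.

Sweeps deliberately share one training pass: prediction records are
computed once per configuration and every (δ, rule) cell re-tallies
the frozen records. Retraining per cell would confound the δ
comparison with training stochasticity; freezing makes the documented
monotonicities (|C| non-increasing in δ and in k) exact properties of
the tally rather than statistical tendencies.

## Base learners

With no deep-learning framework among the dependencies, the CNNs are
implemented directly in numpy (im2col convolution, mean pooling, dense
layers, softmax cross-entropy, momentum SGD), single-threaded and
bit-deterministic given a seed — which is exactly what reproducible
acceptance runs need.

* `TinyCNNClassifier`: 3×3 conv (8 ch) → ReLU → 2×2 mean-pool → 3×3
  conv (16 ch) → ReLU → pool → dense(width) → ReLU → dense(K) →
  softmax. The dense width is the ensemble "variant": widths
  (32, 48, 64, 96, 128) with distinct init seeds give a cheap
  near-homogeneous but diverse ensemble.
* `BackboneHeadClassifier`: frozen feature extractor plus three new
  fully connected layers of decreasing width (default 256 → 64 → K,
  ReLU between, softmax out); only the head trains. The default
  backbone is a fixed seeded random conv stack — a synthetic stand-in
  feature map carrying no pretrained knowledge; any object with
  `transform(X)` can replace it.

Two training configs are used. The package default (`TrainConfig()`)
is 30 epochs, fixed learning rate 0.001, batch 32, plain SGD — the
fine-tuning recipe appropriate when only a small head is trained. The
desk-scale experiments train tiny CNNs from scratch, where that
schedule is too slow to converge; they use 15 epochs, lr 0.01,
momentum 0.9, batch 32, a standard from-scratch recipe chosen once and
fixed in `mislabel.experiments`.

## Synthetic data

The nanopore generator emulates the morphology that matters to the
classifier: a baseline ionic current (default 100 arbitrary units)
with Gaussian noise (σ = 2), Poisson-arriving translocation events
(default 10 /s) that subtract a rectangular blockade of depth
~N(amplitude_mean, amplitude_sd) for a dwell ~N(50 ms, 12.5 ms)
truncated positive. Class identity lives in the per-class amplitude
(defaults 15 / 45 / 80 for empty / ssDNA / dsDNA-like classes — chosen
for clear visual separation of blockade depths at 32×32 rendering,
mirroring the qualitative depth ordering of capsid payloads). Traces
are cut into non-overlapping 1-s segments (trailing partial dropped so
all model inputs share a shape) and rasterized by a column-envelope
renderer: each pixel column is stroked from the covered samples'
minimum to maximum, joined to the previous column — the deterministic
limit of a line plot with many samples per pixel. y-limits are fixed
globally (0–120) because per-segment autoscaling would leak class
identity through the axis scale; rare excursions outside (overlapping
deep events) are clipped with a warning. The default sample rate is
250 kHz so a 1-s segment holds 250,000 points; the desk-scale runs
simulate at 2 kHz, which leaves the rendered 32×32 images essentially
unchanged (62 samples per pixel column) at 1/125 the cost.

What the generator does **not** emulate: 1/f and capacitive noise,
baseline drift, event sub-structure (multi-level blockades), variable
translocation velocity, or real AAV amplitude scales. Passing tests
therefore demonstrate the correctness of the detection machinery and
its behaviour on separable-but-noisy inputs, not performance on real
nanopore recordings, whose class overlap is far larger.

The stand-in image set gives each class a fixed template (a smoothed,
thresholded random field in a class-specific color, seeded by class
index only) perturbed by integer pixel jitter ~round(N(0, jitter_sd))
and pixel noise N(0, noise_sd), clipped to [0,1] and quantized to the
8-bit grid so PNG round-trips are lossless. Defaults
(jitter 1 px, noise 0.05) produce a set a 1-NN classifier separates
perfectly — the "well-separated" regime in which injected flips should
be fully detectable. Label flips choose `count` distinct samples
uniformly without replacement and re-label each uniformly over the
K − 1 other classes; the pre-flip label is kept in the hidden
`true` field and in the injection record.

## Problem sizes

The canned experiments in `mislabel.experiments` are sized for minutes
on one CPU: (a) 10 classes × 100 images (28×28), 50 flips, five
tiny-CNN variants, 10 folds, δ = 0.5 — 50 trainings of ~900 images;
(b) 3 nanopore classes × 120 one-second segments (32×32 from 2 kHz
simulation), 20 flips, three variants, 2/3 voting — 30 trainings of
324 images. All seeds derive from a single master seed via
`numpy.random.SeedSequence`.

## Known limitations

* Tiny CNNs trained from scratch stand in for fine-tuned pretrained
  backbones; architectural diversity here comes only from dense width
  and initialization, so ensemble disagreement is weaker than in a
  truly heterogeneous ensemble.
* The detector assumes every sample receives exactly m verdicts; it
  does not yet support ragged ensembles (members skipping rounds).
* Recovery quality is only meaningful when the ensemble is
  substantially more accurate than the label-noise rate; on
  hard-to-separate data the plurality label can itself be wrong.
* `ImageDataset` holds all images in memory (float32); at 10⁵+ images
  a memory-mapped variant would be needed.
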