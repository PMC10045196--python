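# Methods

## Problem and pipeline

In immunofluorescence images of cultured human cells, centrioles and
procentrioles appear as minute, bright, near-diffraction-limited foci.
A mature centriole and the procentriole it seeds sit roughly 300 nm
apart, which at the assumed pixel pitch of 102.5 nm is about 3 px — so
a useful detector must keep members of such pairs as *separate*
detections, and every accuracy number in this package is quoted at a
3-px matching tolerance. `centriodet` implements the full scoring
pipeline:

1. **data layer** — multi-channel z-stacks (OME-TIFF, canonical axes
   `(channel, z, row, col)`) are max-projected along z; annotations are
   `x,y` CSVs (origin top-left) and 16-bit label masks;
2. **detection layer** — a multiscale U-Net regresses Gaussian
   probability maps for the marker channel; nuclei are segmented from
   the DNA channel;
3. **scoring layer** — detected foci within 3 px of each other are
   grouped and the group is assigned jointly to the nearest nucleus,
   yielding a count per fully visible cell.

## The multiscale spot detector

**Targets.** Each annotated focus is rendered as an unnormalised
Gaussian, `exp(-d^2 / (2 sigma^2))` with spread `sigma = 1.5` px and
peak 1; overlapping Gaussians combine by pixelwise maximum, so a 3-px
pair keeps two unit peaks separated by a saddle (≈ 0.61). Peak-1
targets make the binary cross-entropy well posed. Coarser targets at
1/4 and 1/16 resolution are built by 4x4 max pooling — max rather than
mean, because mean pooling would dim an isolated peak by up to 16x and
starve the coarse losses of signal.

**Architecture.** A U-Net with `depth = 3` supervised resolution
levels. Each encoder level applies two 3x3 convolutions (ReLU) and a
4x4 max-pool, caching the pre-pool features; the decoder mirrors this
with 4x nearest-neighbour upsampling and skip concatenation. Every
level carries a 1x1-convolution head producing a logit map (sigmoid
probability at readout), and the training loss is the *sum* of the
per-level pixel-wise BCEs. Weights are He-initialised. `base_filters`
(doubled per level) defaults to 32; the desk-scale benchmark uses 16
(see *Problem sizes*). The deep supervision is what makes learning on
extremely sparse targets (tens of positive pixels per 10^5) stable:
the coarse levels retain gradient signal early in training.

The network and its backpropagation are implemented directly on numpy
(`centriodet.nn`): same-padded convolutions evaluated as k^2
shift-and-matmul products, max-pool/upsample pairs, Adam and momentum
SGD. Gradients are validated against central finite differences in the
test suite.

**Loss weighting.** Because positives are so sparse, plain BCE has a
strong local optimum at the all-black map. Pixels whose target exceeds
0.5 are up-weighted by `w(e) = 1 + (w0 - 1) * (1 - e / E)` with
`w0 = 10` at epoch 0, decaying linearly to ~1 by the last epoch `E` —
a strong early push away from black, relaxed late so it does not
induce false positives.

**Training.** Adam at learning rate 3e-4, binary cross-entropy, 100
epochs by default. Images are percentile-normalised (1st-99.8th
percentile to [0, 1]) — robust to the large staining-intensity
differences between markers — and, for real data, augmented with
random flips, random affine (rotation up to 15 deg, scale 0.9-1.1,
shift up to 5%), random brightness/contrast and random gamma; point
annotations are transformed consistently and the targets re-rendered
after augmentation. One random `patch_size` crop is taken per field
per epoch; crops with no foci are kept as negatives. All randomness
flows from the config seed, so a fixed seed reproduces the loss
trajectory exactly.

Two optional stabilisers address the gradient noise of single-image
steps (the package trains one crop at a time rather than in batches):
a learning-rate decay to 10% of the base rate across the final third
of training, and an exponential moving average of the weights (decay
0.999) used as the inference weights. Both are off by default and on
in the synthetic benchmark, where they visibly reduce run-to-run
spread. The benchmark also trains *without* augmentation: the
generator already samples focus orientation, position and intensity
uniformly, so augmentation adds no new variation there, while the
bilinear interpolation of the affine warp blurs structure at the
1.5-px spot scale and measurably costs accuracy; on real data, where
augmentation substitutes for limited annotation, it stays on.

Training can optionally be validation-gated
(`train_with_validation`): a split carved from the training fields —
never from held-out data — is scored after the configured epochs, and
training continues in short warm-restart rounds while validation F1
stays below a target, up to a hard cap. The benchmark uses a fixed
epoch count instead, for a deterministic runtime.

**Readout.** Arbitrary image sizes are handled by reflect-padding to a
pooling-compatible size and, beyond `tile_size` (512), by overlapping
tiles blended with a linear taper (64-px overlap) before a single peak
extraction on the stitched map. Peaks are local maxima (3x3 window)
with probability >= 0.5, thinned greedily by descending value under a
*Euclidean* minimum separation of 2 px. The Euclidean rule matters: a
square suppression window of half-size 2 (Chebyshev) would merge
diagonal 3-px pairs, whose member peaks are only 2 units apart per
axis. The threshold (0.5) and separation (2 px, deliberately below the
3-px pair spacing) are exposed in the config. An optional test-time
augmentation averages the probability maps over the four axis flips
before peak extraction — foci are flip-equivariant, so the average
suppresses orientation-dependent prediction noise at pure inference
cost; the benchmark readout uses it.

## Nucleus segmentation and per-cell scoring

The DNA plane is mean-binned so its side is ~256 px (8x8 binning for a
2048-px field; mean rather than decimation to keep dim chromatin
texture), segmented, and the labels are upscaled back by nearest
neighbour. The `pretrained` backend adapts the published star-convex
fluorescence model when that package is importable; the default
`classical` backend — Gaussian smoothing, Otsu threshold, hole filling,
distance-transform watershed — is self-contained and is what the test
suite exercises. Nuclei whose mask touches the field border are
flagged and removed before counting, since their centriole complement
may lie outside the field. Nucleus detection quality is assessed by
centroid matching at a 50-px (~5 µm) tolerance.

Scoring groups foci by single-linkage over the <= 3 px proximity graph
(transitive, so close chains stay together) and assigns each group to
the nucleus minimising the distance from the group centroid to the
nearest pixel of the nucleus mask — not the nucleus centroid, which
would misassign peripheral centrioles of large nuclei. Distance ties
break towards the lowest label; the assignment radius is unbounded by
default and configurable. Nuclei without foci keep explicit zero
counts, so depleted conditions are reported rather than silently
dropped.

## Evaluation

Predictions and annotations are paired one-to-one by the Hungarian
algorithm on the Euclidean distance matrix. Entries above the
tolerance are saturated to a large constant *before* assignment so the
matcher never trades one valid pair for two invalid ones; matched
pairs above tolerance are then discarded. The tolerance test is
inclusive (`<=`), so a pair at exactly 3 px counts — the
centriole-procentriole spacing itself must land inside. Degenerate
cases: both lists empty scores 1.0 for precision/recall/F1; exactly
one empty scores 0. Across a test split, F1 is computed per field and
aggregated as unweighted mean with sample (n-1) standard deviation; a
pooled mode (summing tp/fp/fn first) is available behind a flag. The
Hungarian result is itself tested against exhaustive enumeration for
small instances. An F1-vs-tolerance sweep over 0-5 px is provided; it
is non-decreasing by construction of the matching.

## Baseline detectors

* **LoG ladder** — scale-space Laplacian-of-Gaussian maxima over 10
  sigmas from 1 to 2 px (blob radii `sigma * sqrt(2)` ≈ 1.4-2.8 px),
  detection threshold 0.1 on the normalised response.
* **Threshold-sweep blob detector** — the image is reduced to 8 bits
  (linear min-max by default; a fixed divide-by-256 mode exists for
  bit-exact comparisons), binarised at thresholds swept across 0-255
  in steps of 10; connected components with area between 5 and 100 px
  are kept when their centres repeat across at least 2 thresholds
  within 4 px, and the mean centre is reported.
* **Shallow CNN ("FociDetector"-style)** — four 5x5 convolutions of 10
  filters with ReLU, plus a 1x1 sigmoid head (an interpretation: a
  10-filter stack cannot emit a single-channel map on its own), trained
  with plain BCE and SGD (lr 0.01, momentum 0.9, weight decay 1e-4)
  against the same full-resolution Gaussian targets the multiscale
  model sees at its finest level. At inference its probability map is
  multiplied by the min-max unit-scaled input before peak extraction.
  Without positive-pixel weighting and multiscale supervision this
  model tends towards high precision but poor recall on sparse foci.

The single-scale ablation of the main model ("plain U-Net") is
realised as the same architecture with losses attached only to the
full-resolution head (`num_heads = 1`), not as a separate module.

## Synthetic fields

The generator emulates the data regime end to end: a DNA channel with
smooth elliptical nuclei (a minority crossing the field border), a
marker channel with Gaussian foci (sigma 1.5 px) in pairs exactly 3 px
apart placed in an annulus just outside their nucleus, short z-stacks
with an out-of-focus attenuation profile, and 16-bit noise — Poisson
counting noise (0.05 photons/ADU) plus Gaussian read noise (sigma 50
ADU) over a 500-ADU background, giving planted peaks (2000 ADU) a
signal-to-noise ratio well above 5. Exact ground truth (sub-pixel
focus coordinates, label masks, per-nucleus planted counts) is
returned and written in the standard annotation formats. Every field
is reproducible bit-for-bit from its seed.

What the generator does **not** model: realistic PSF shape and optical
aberrations, marker-dependent focus morphology (PCM markers are larger
and more diffuse than centriolar ones), intensity correlations between
channels, autofluorescent debris, and the cell-density statistics of
real cultures (nuclei are drawn smaller and sparser than life;
sizes/densities are scaled to the 256-px default side while the pixel
pitch and the 3-px pair separation are kept at face value). Passing
the synthetic benchmark therefore demonstrates that the implementation
learns and resolves close pairs under noise as designed — not that the
shipped defaults transfer to any particular real dataset, which
requires training on annotated data of that modality.

A note on difficulty: with rendering sigma 1.5 px, the *intensity* sum
of a 3-px pair has an essentially flat plateau between the two centres
(two equal Gaussians merge into a single maximum at separations <= 2
sigma). Naive local-maximum detectors therefore see one blob per pair,
which caps their recall near 0.5 on pair-rich fields; the learned
model must infer doubling from brightness and elongation. This makes
the synthetic benchmark a genuine test of the multiscale detector
rather than a smoothing exercise.

## Problem sizes and numerical choices

Desk-scale benchmark (used by the acceptance script and the end-to-end
tests): 200 nucleus-free 256-px fields with 2-8 pairs each, 90/10
train/test split, `base_filters = 16`, 64-px random training crops,
100 epochs, no augmentation, with the learning-rate decay and weight
averaging described above. The crop size and epoch count trade off
against each other at fixed compute; small crops with many epochs
proved both the most CPU-cache-friendly and the most stable across
random seeds in a preliminary calibration (hyper-parameters were fixed
once and not revisited per run), training in roughly 10-15 minutes on
one CPU core. The published-scale configuration (2048-px fields,
512-px patches, 32 base filters, augmentation on) remains the package
default.

Other numerics: probability maps are float32 and losses are
accumulated in float64; the BCE is computed on logits via
`softplus(z) - t*z` for stability; Adam uses the standard bias
correction with eps 1e-8; the all-equal (constant) probability map
yields no peaks; empty training sets and NaN losses abort with
explicit errors; nucleus placement failure after bounded retries
raises a descriptive error rather than looping forever.

## Open design points resolved here

* Train/test split: fields are shuffled with a fixed seed, one marker
  channel per field is assigned round-robin so markers are represented
  nearly evenly, and ~10% per marker group is held out. The split is
  written to `train.txt`/`test.txt` and is deterministic.
* Annotation CSVs may carry integer or sub-pixel coordinates; both are
  accepted.
* Per-field F1 values are averaged with field as the unit of analysis
  (pooling available behind a flag).
* Group-level (not per-focus) nucleus assignment, per the joint
  treatment of 3-px pairs.
* Missing pixel-size metadata falls back to 102.5 nm/px with a logged
  warning.
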