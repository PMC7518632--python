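# Methods

This note documents the models, parameters, and design choices behind
`metabrand`: what each stage computes, which knobs matter, what the
synthetic phantoms do and do not emulate, and the numerical conventions
used throughout.

## Covariate model

Five participant-level variables accompany each scan. Age in years is
grouped into four inclusive integer bins (46–55, 56–65, 66–75, and
76–85 for the population-study scheme or 76–90 for the ADNI-style
scheme; the schemes differ only in the top bin). Education in years is
grouped into ≤10 / 11–13 / ≥14. Gender (2), marital status (4) and
APOE-ε4 carrier status (2) pass through, giving 15 categories across
5 variables. Ages outside the scheme's range raise an error by default;
an explicit clamp option maps them to the nearest extreme bin, because
silently clamping would hide data problems.

## Marker branding

Each category owns a 10×20 binary {0, 255} pattern drawn i.i.d. per
pixel from a seeded generator (default marker seed 42, recorded in run
metadata). Within a variable, patterns are redrawn until every pair
differs in at least 60 of 200 pixels; random patterns differ in ~100
pixels on average (binomial, sd ≈ 7), so resampling is rare and the
draw loop is capped at 10,000 attempts. The margin guarantees that
nearest-pattern decoding tolerates up to 29 corrupted pixels, which is
why markers survive the enhancement stage.

Marker `i` (variable order: age, gender, education, marital status,
APOE-ε4) occupies rows [0, 10) and columns [10+25i, 10+25i+20): five
20-px markers with 5-px gaps, ending at column 130. Branding happens on
the 8-bit resized slice *before* enhancement, so the markers also pass
through CLAHE and NL-means. Branding is idempotent and touches nothing
outside the marker rectangles.

## Volume preparation and enhancement

Scans are converted to stacks of 8-bit 224×224 slices: per-volume
min–max scaling to [0, 255] (no percentile clipping — the simplest
convention, at the cost of outlier sensitivity), bilinear resampling,
rounding. Slice sampling takes every second slice from index 8 through
166 inclusive — 80 slices — so volumes must have ≥ 167 slices.

Each slice becomes 3 channels:

* channel 0 — the slice itself;
* channel 1 — CLAHE: 8×8 tile grid, 256 bins, uniform target histogram,
  relative clip limit 0.01, output stretched to the full 8-bit range.
  The "distribution parameter" (0.4) is kept in the configuration for
  fidelity but only applies to non-uniform target shapes. A constant
  image is returned unchanged (the underlying library's behavior on a
  degenerate histogram is not meaningful).
* channel 2 — non-local means: patch radius 4 (9×9 patches), search
  radius 4, smoothing strength 0.05 of the intensity range, blockwise
  (fast-mode) averaging.

Both operators are pure functions; identical inputs give byte-identical
outputs. Channel order (original/CLAHE/NL-means) is fixed but
arbitrary and recorded in run metadata.

**Exact incremental enhancement.** Branding edits only rows 0–9.
NL-means output at row r depends on input rows within r ± 8 (patch
radius + search radius), so only rows 0–17 of the NL-means channel can
change; they are recomputed on a top strip tall enough (26 rows) that
every recomputed pixel sees exactly the pixels a full-image pass would
use, and rows 18+ are reused. CLAHE is recomputed in full (cheap).
The spliced result is bit-identical to full recomputation (tested), and
makes repeated branded-variant extraction (ablations, replicated
studies) several times cheaper.

## Feature extraction

A backbone maps one 3-channel slice to 2048 activations; a scan is the
80×2048 sequence of its sampled slices (163,840 values). The default
**surrogate backbone** is deterministic and weight-free: a 16×16 grid
of 14×14 patches, 8 statistics per patch (per-channel mean and sd, max
of the channel-mean image, mean squared gradient magnitude), computed
on intensities scaled to [0, 1]. It preserves the pipeline's
structure — local image content at fixed spatial positions — without
pretrained weights. A pre-trained Inception-v3 ImageNet backbone is
exposed through the same interface when a deep-learning runtime and
weights are present; it is never required by tests.

## Classifier

The sequence classifier is an LSTM stack: recurrent layer emitting its
final hidden state (dropout 0.5) → dense sigmoid layer → dropout 0.5 →
dense softmax over (control, aMCI). Architecture defaults are 2048
recurrent units and 512 dense units. The implementation is NumPy:
Glorot-uniform seeded initialization (forget-gate bias 1), full
backpropagation through all 80 steps, inverted dropout, Adam
(default learning rate 1e-4, batch 8, 50 epochs), global gradient-norm
clipping at 5, optional early stopping on validation loss (patience
10, best-parameters restore).

Two practical additions, both off by default and controlled by the
configuration:

* **Feature standardization** (always on in `fit`): features are
  z-scored per coordinate with training-set statistics stored on the
  model and re-applied at prediction. The surrogate backbone's
  statistics have widely varying scales (marker-identity information
  lives in coordinates with tiny absolute ranges), and gradient-based
  training cannot reach such coordinates unstandardized.
* **Stochastic weight averaging** (`average_tail`): parameters are
  averaged over the final fraction of epochs. Small-batch training on
  small cohorts oscillates epoch to epoch; averaging the tail of the
  trajectory yields a stable representative model rather than a
  last-epoch lottery draw.
* **Reliability weighting** (`reliability_weighting`): each
  standardized coordinate is additionally scaled by its
  between-participant variance share, Var(participant means) /
  (Var(participant means) + mean within-scan variance), computed
  unsupervised on the training set. For participant-level labels this
  emphasizes participant-stable coordinates (e.g. constant-across-slices
  marker content) over per-slice acquisition noise, which a plain
  z-score amplifies to the same unit scale.
* Two further optional regularizers for small-sample work: Gaussian
  input jitter on the standardized training batches
  (`input_noise_sd`) and proximal L1 shrinkage of the input weight
  matrix (`l1_input`). Both default to off.

aMCI is the positive class; prediction ties break toward aMCI
(screening posture). Determinism: bit-reproducible on one platform
with one BLAS under fixed seeds; across platforms agreement is only
within floating-point tolerance.

**Input modes.** `original` uses features of untouched slices;
`branded` of marker-branded slices; `widedeep` multiplies each
original-mode feature row elementwise with a 2048-dim embedding of the
15-dim one-hot covariate vector (seeded fixed linear map, scaled to
unit variance for 5-hot inputs) — a dot-product-style wide-and-deep
cross.

## Evaluation

Stratified holdout allocates the test set proportionally per class
(largest-remainder rounding) and samples without replacement; class-wise
k-fold cross-validation is delegated to scikit-learn's stratified
splitter. Confusion metrics use aMCI as positive: sensitivity
TP/(TP+FN), specificity TN/(TN+FP), precision TP/(TP+FP),
F1 = 2PR/(P+R), accuracy (TP+TN)/n. Zero-denominator ratios are
reported as undefined (`None`), never as 0. Cross-validation aggregates
report mean ± sd per metric; the sample (n−1) convention is the
default and configurable. The ablation runner evaluates six branded
variants — all markers, then each variable omitted — on one identical
split with identical seeds, so the omitted marker is the only
difference between runs.

## Synthetic phantoms

Volumes are 192×224×224 ellipsoid "brains" (intensity 180) with an
inner ellipsoid "ventricle" (intensity 30) whose radius scale is drawn
per participant from a class-dependent normal (control mean 1.0, aMCI
mean 1.35, sd 0.08 — an atrophy proxy, i.e. enlarged ventricles in
aMCI), plus Gaussian noise (sd 10 gray levels), min–max scaled to
8-bit. The proxy gives the image channel a controllable class signal;
it makes no claim about aMCI anatomy, and the phantoms have no MRI
physics (no bias field, no k-space artifacts), no anatomy beyond two
ellipsoids, and no inter-subject registration variability. Passing
tests on phantoms therefore demonstrates the pipeline's mechanics and
the branding mechanism, not clinical performance.

Covariate tables draw each variable from configurable marginals; the
shipped presets encode the two published cohort summaries (n=120,
aMCI fraction 61/120; n=624, aMCI fraction 397/624). The APOE-ε4 /
diagnosis association is specified as an odds ratio; per-class carrier
probabilities are solved (scalar root-finding) so the mixture marginal
is preserved exactly. Raw ages and education years are drawn uniformly
inside the sampled bin. Per-participant volume seeds are derived by
hashing the cohort seed with the participant id.

The **signal-injection preset** (used by the mechanism studies)
balances the classes and the APOE marginal and uses fixed-count draws:
exactly n/2 aMCI labels and exactly the tilted number of carriers per
class. With the odds ratio at 10 this pins the best achievable
("Bayes") held-out accuracy at 0.75 for every replicate instead of
letting it fluctuate binomially — at n=40 the association itself would
otherwise vary enough (sd ≈ 0.07) to dominate the quantity under
study. The study's volume panel additionally zeroes the atrophy
spread, making every phantom's geometry identical: with no
participant-identifying anatomy, the only participant-stable image
content is the branded marker band, which isolates the metadata
channel the study is about.

## Signal-injection study design

The study asks whether branding injects usable covariate signal: with
phantom volumes that carry *no* class signal and APOE-ε4 tilted at odds
ratio 10, branded-mode held-out accuracy should clearly exceed
original-mode accuracy (which can only be chance); omitting the APOE
marker should produce the largest ablation drop; and with all signal
off, accuracy should sit at chance.

Problem sizes (chosen once for desk-scale studies): cohorts of n=40
over a fixed panel of 40 signal-free phantom volumes shared across
replicates (the volumes are label-independent by construction, so
resampling only covariates, labels, folds and training seeds loses no
generality); 5 replicates; per replicate, held-out accuracy is measured
by class-wise 4-fold cross-validation pooled over all 40 participants
(every participant predicted by a model that never saw it) — a 10-part
holdout would give 0.1-resolution accuracies too noisy to compare
modes. The classifier uses the down-scaled study configuration
(48 recurrent / 32 dense units, Adam 1e-3, batch 8, 25 epochs with
weight averaging over the final 60%, reliability weighting on); the
full-width published architecture is impractical and unnecessary at 30
training samples. The short epoch budget is deliberate: with a
strongly label-associated covariate the network learns the covariate
rule within the first ~10–25 epochs and afterwards begins memorizing
the (noisily labeled) training cohort, which degrades held-out
accuracy; averaging the tail of a short run captures the
rule-following regime. The ablation reuses replicate 0's folds, so
the omitted marker is the only feature difference between its runs,
and each variant's pooled accuracy is additionally averaged over 3
training seeds so optimizer noise does not swamp the per-variable
differences; the null control (odds ratio 1, no image signal)
averages 3 further replicates.

Known limits: with the odds ratio fixed at 10 and balanced classes the
Bayes accuracy is 0.75, so the branded-vs-original margin is at most
~0.25; at n=40 a single replicate's pooled-CV accuracies still carry
several points of sampling and training noise, and with 30 training
scans, 2048 feature coordinates and ~25% effective label noise the
sequence classifier recovers the covariate rule only partially
(branded accuracy typically 0.5–0.7 against the 0.75 ceiling, original
mode ~0.4–0.55). Replicate-level branded-vs-original gaps therefore
fluctuate around ~0.1–0.2 and the study judges the branded advantage
by majority over replicates; the per-variable ablation attribution
(APOE-ε4 largest drop) is the more stable readout of the mechanism.

## Known limitations

* The surrogate backbone's patch statistics are far weaker descriptors
  than pretrained CNN activations; marker categories differ only
  through pattern-density statistics, which is why feature
  standardization matters so much at this scale.
* The phantom generator's image-signal pathway (ventricle size) is
  deliberately simple; pipelines that pass here may still fail on real
  anatomy.
* The NumPy LSTM is single-threaded-deterministic but not fast; the
  published layer widths (2048/512) are supported but intended for
  real-data scales, not the synthetic studies.
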