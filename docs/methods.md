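# Methods

This note documents the models, algorithms, numerical choices and
limitations of the `litenet` package, in the order data flows through it.

## Synthetic ECG generator

The generator exists so that every stage — segmentation, balancing,
training, evaluation — is exercisable and reproducible without downloading
clinical data.  Each beat is a sum of five Gaussian bumps standing in for
the P, Q, R, S and T waves:

    beat(t) = Σᵢ aᵢ · exp(−½ ((t − cᵢ)/wᵢ)²),   i ∈ {P, Q, R, S, T}

with amplitudes aᵢ (signal units), centres cᵢ (seconds relative to the
R-peak) and widths wᵢ (Gaussian SD, seconds).  The R bump must carry the
largest |amplitude| so the R-peak is the window argmax.  Five presets encode
class identity the way a cardiologist would sketch it: N is a textbook
narrow-complex beat; S has a sharp narrow R, inverted P and a short mean RR
interval (0.55 s); V has a wide, tall R with no P and a discordant negative
T; F blends N and V morphology; Q is low-amplitude and irregular with a long,
variable RR.  The pairwise Pearson correlation between noise-free, R-aligned
default templates is at most 0.88 (tested bound: < 0.95), which is what makes
the end-to-end classification property meaningful.

A record concatenates beats (round-robin over classes) at jittered RR
intervals (Gaussian per class, clipped to [0.4, 2.0] s), then adds white
Gaussian noise (default sd 0.03 signal units against an R amplitude of ~1)
and a sinusoidal baseline drift (default amplitude 0.05, frequency 0.33 Hz,
random phase) — the two dominant artifacts of ambulatory ECG.  One RNG
stream per call is consumed in a fixed order (RR jitter → noise → drift
phase), so a seed pins the record bit-exactly and the stream layout is
stable even when noise or drift is disabled.

What the generator does **not** emulate: rhythm-level context (a real
supraventricular beat is defined partly by its relation to neighbouring
beats), intra-class morphological diversity across patients, electrode
artifacts, and non-stationary noise.  Passing the end-to-end tests therefore
shows the pipeline and model are correct and trainable on separable
morphologies — not that the architecture reaches any particular accuracy on
clinical recordings.

## Preprocessing

* **Segmentation** cuts the half-open window `[r−h, r+h)` around each
  annotated R-peak: exactly 2h samples with the R-peak at local index h.
  The half-open convention resolves the off-by-one ambiguity of "h samples
  on both sides" in favour of the stated segment lengths (2h).  Beats whose
  window would cross a record edge are skipped and counted, never truncated.
* **Z-score** uses the population (n) standard deviation, normalizing each
  segment to mean 0, sd 1; this removes amplitude scaling and offset.
  A constant segment maps to all zeros with a `degenerate` flag rather than
  raising — degenerate inputs are data, not programming errors.
* **Balancing** synthesizes minority-class segments from uniformly chosen
  same-class originals by (i) translating the window start by an integer
  drawn uniformly from [−shift_max, +shift_max], re-cut from the source
  record when available (falling back to a circular shift), and (ii) adding
  white noise with sd equal to `noise_sd_fraction` of the segment's own sd.
  Defaults: shift_max = 18 samples (5% of a 360-sample window) and noise
  fraction 0.05 — both small enough to preserve class identity, large enough
  to decorrelate copies.  Originals are never modified, and the per-class
  target may exceed every existing class count (so even the largest class
  can be augmented).  Normalization is applied **after** augmentation, so
  synthesized segments are also unit-variance; the pipeline exposes this as
  an explicit ordering rather than a hidden convention.
* **Folds** are stratified: per class, fold sizes differ by at most one;
  folds are disjoint and cover the dataset.  Stratification is required for
  per-class metrics to be defined in every fold.  Segments are put into a
  canonical order (by provenance and content) before the seeded shuffle, so
  the fold *contents* are independent of the dataset's storage order.

## The micro-framework

All kernels are plain numpy with analytic backward passes, each checked in
the test suite against central finite differences (relative error < 1e-5,
with an eps of 1e-4 and a small denominator floor so cancellation noise on
near-zero gradients is not misread as error) and against naive triple-loop
references (< 1e-12).

* Feature maps are `(batch, channels, length)` arrays.
* Layer convolutions are cross-correlations with "same" zero padding — pad
  ceil((k−1)/2) left, floor((k−1)/2) right — and stride s, giving output
  length ceil(L/s).  Length preservation at stride 1 is what makes the
  architecture's bookkeeping (360 → 180 → 90 with 18 channels) work, and
  postponing down-sampling to the pooling layers keeps activation maps
  large.  The flip-and-slide *full* convolution (y[n] = Σ x[k]h[n−k],
  output length m+k−1) is kept as its own primitive, `conv1d_full`.
* Depthwise convolution uses channel multiplier 1 (one kernel per channel);
  pointwise is the k = 1 special case of the standard layer.  Their
  factorization costs k·C + C·C′ multiply-accumulates per output position
  versus k·C·C′ for a standard layer — at k = 3, C = C′ = 10 that is
  130 vs 300, the ≥2× saving that motivates separable convolutions.
* Max-pooling is non-overlapping (window = stride = 2 throughout the
  architectures), trailing remainder dropped: output length floor(L/2).
  Ties route the gradient to the first maximum (numpy argmax convention).
* Dropout is inverted (scale by 1/(1−rate) at train time, identity at eval);
  LeakyReLU's subgradient at 0 is taken as 1.
* Softmax subtracts the row max before exponentiating; cross-entropy uses
  the natural log with predictions clipped at 1e-12, averaged over the
  batch, and validates that expected-distribution rows sum to 1 (tol 1e-6).
  The softmax + cross-entropy head differentiates jointly to (q − p)/B.

**Initialization.**  Weights are He-style fan-in-scaled uniform,
U(−√(6/fan_in), +√(6/fan_in)), biases zero.  The classifier head (the dense
layer feeding the softmax) is drawn at 1/20 of that scale so the initial
predictive distribution is near-uniform and the initial loss on balanced
5-class data sits at ≈ ln 5; small-scale final-layer initialization is also
what keeps early training stable.  Parameters are drawn in graph order from
one seeded generator.

**Parameter ledger.**  Each conv layer contributes k·C_in·C_out weights +
C_out biases (depthwise: k·C + C); dense layers F·U + U.  The model-size
metric PC sums conv-layer parameters only (squeeze/standard/depthwise/
pointwise, weights and biases), excluding dense layers, whose size is
dominated by the flatten width rather than by the architecture's design.
The ledger reports weights and biases separately so alternative counting
conventions can be recomputed; under this one, basic LiteNet has PC = 300
(stem 30; module: squeeze 18, branch a 24, branch b 42+18+42, branch c
60+24+42) against 368/415/810/1054 for the four 1-D comparison networks,
preserving the ordering in which LiteNet is smallest.

## Architectures

The Lite module's internal branch topology is the unique arrangement that
consumes each configured layer exactly once — squeeze 1×1→3; then branches
(a) standard 1×1→6, (b) standard 1×2→6 → depthwise 1×2 → pointwise 1×1→6,
(c) standard 1×3→6 → depthwise 1×3 → pointwise 1×1→6 — and yields the 18
concatenated channels the second max-pool expects.  An optional residual
connection adds the module input through a 1×1 projection when channel
counts differ; it changes no shapes.

The four comparison networks are deliberately small 1-D miniatures:
AlexNet-1D (three standard convs 1×5/1×3/1×3 with 5/10/20 filters),
GoogLeNet-1D (1×5×10 stem, one inception module with 1×1/1×2/1×3 branches of
8 filters, then a 1×2×10 conv), SqueezeNet-1D (1×5×10 stem, two fire modules:
squeeze 3, expand 1×1 + 1×3 of 8 each) and MobileNets-1D (1×5×10 stem, two
depthwise-separable blocks of 10 and 15 filters; depthwise kernels default
to 1×3).  All four share LiteNet's dense/softmax head, so the PC comparison
— which excludes dense layers — contrasts conv bodies like for like; pooling
placement mirrors LiteNet (after the stem and after the last conv block).

## Training and evaluation

Adam follows the standard bias-corrected form; the test suite locks it to an
independently coded reference trajectory (100 steps on a quadratic,
elementwise 1e-12).  Batches are drawn from a seeded per-epoch shuffle; the
final partial batch is kept (discarding it would silently drop data at small
n).  Cross-validation trains fold f with seed `cfg.seed + f`, keeping folds
independent but the whole run pinned; every segment is tested exactly once.

Multiclass aggregation is macro (unweighted over classes with defined
metrics) — the symmetric default when per-class performance matters equally —
with micro/overall accuracy (trace/total) and the binary normal-vs-arrhythmia
collapse emitted alongside.  Zero-denominator metrics are flagged undefined
(`None`), never NaN.  AUC is the rank-based Mann–Whitney one-vs-rest
statistic with average ranks for ties (equivalent to the trapezoidal ROC
area; the suite cross-checks against scikit-learn to 1e-9), macro-averaged
over classes with at least one positive and one negative.  Rating bands are
half-open on the left with 1.0 included in Excellent and everything below
0.6 — including worse-than-chance — rated Failure.

## Problem sizes and defaults

The bundled separable preset used by the examples and the end-to-end tests
is: 40 beats per class at 360 Hz, noise sd 0.03, drift amplitude 0.05;
half-window 180 (360-sample inputs); balanced to 60 segments/class (300
total); ten folds; Adam, lr 0.005, batch 50, 8 epochs.  Eight epochs is the
point at which training on this preset has converged (first-epoch loss
≈ ln 5, final ≈ 0.1); the epoch count is an explicit configuration knob.
At these sizes a full ten-fold cross-validation takes well under a minute on
one CPU.

## Known limitations

* No beat detection: R-peaks come from annotations (real or synthetic).
* No denoising or resampling — by design the classifier consumes raw
  (Z-scored) windows, noise included.
* Single-lead only; no rhythm-level (multi-beat) context.
* The micro-framework covers exactly the layer vocabulary these
  architectures need; it is not a general autodiff system, has no GPU path,
  and is intended for desk-scale experiments, not full-scale clinical
  training runs (which the same code supports in principle, just slowly).
* Mapping native clinical annotation symbols onto the five AAMI classes is
  the responsibility of the optional WFDB adapter's caller.
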