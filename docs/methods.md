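# Methods

This note records the models, conventions and numerical choices behind
`adhekin`, and what the synthetic experiments do and do not demonstrate.

## Measurement model

An RWG plate reader images 12 wells in a 3 × 4 mosaic; each well is an
80 × 80 px sensor at 25 μm pitch. The per-pixel signal is the resonant
wavelength shift in picometres, roughly proportional to adhered biomass
within ~150 nm of the surface. A recording is a `(T, 240, 320)` video
plus a timeline; cells are pipetted in after a baseline period, which
leaves a large gap in the timeline immediately before the adhesion
phase.

All coordinates in the package are (row, col), 0-based, with pixel
centres at integer positions, on both the biosensor and microscope
planes. A biosensor pixel (r, c) owns the unit square
[r−0.5, r+0.5) × [c−0.5, c+0.5).

## Preprocessing

* **Adhesion start** — index of the first frame after the largest
  timeline gap exceeding `gap_factor` (default 10) × the median
  inter-frame interval. Pipetting pauses are minutes against scans of
  seconds, so the factor is uncritical; if no gap qualifies the user
  must pass the start index explicitly.
* **Reference image** — the per-pixel maximum over time of the
  offset-corrected well. It is used for the 75 pm foreground threshold
  and for outlier statistics; a max projection is robust to cells that
  adhere late, which a single final frame is not.
* **Outlier masking** — pixels of the reference image outside
  mean ± 3σ (computed over unmasked pixels) are excluded from all
  frames. This targets well-boundary artifacts, which are spatial and
  persistent. A degenerate σ = 0 masks nothing.
* **Background correction** — up to 100 unmasked pixels with reference
  value < 75 pm, at least 2 px from any foreground pixel and from each
  other, are drawn without replacement with probability decaying with
  distance from the well centre (Gaussian, σ = 20 px, mitigating edge
  effects). The mean of these pixels is subtracted **per frame**: drift
  is temporal, and a per-frame correction removes any common-mode
  offset exactly (verified by differencing a drift-injected pipeline
  run against a drift-free twin). After correction the per-frame
  background mean is zero to float precision by construction.

## Registration

The two planes are related by `m = s·b + t` (no rotation/shear, as the
instruments share the sample orientation). With N picked pairs,
`s` is the mean over all N(N−1)/2 unordered pick pairs of the
microscope/biosensor distance ratio, and `t = mean(m − s·b)`. All-pairs
averaging is the symmetric choice; pairs with coincident biosensor picks
are skipped. With a single pick only `t` is estimated and a nominal
scale from device pixel pitches is required. On noise-free
correspondences the estimator is exact (checked to 1e-9 over scales
2–40); with noisy picks the error decreases with N.

Projecting a microscope mask down: a biosensor pixel belongs to cell k
iff at least one microscope pixel centre of label k inverse-maps into
its unit square ("≥1 mapped centre" cover rule — the simplest rule
consistent with treating mask pixels as point samples). Where two cells
land on one biosensor pixel, both cells' pixel sets keep it, and the
single-valued biosensor label image goes to the cell contributing more
microscope pixels.

## Single-cell selection

* Strategies M/P build one candidate per projected mask label; strategy
  W finds local maxima of the kinetic image within [75 pm, ∞) with a
  2 px minimum separation (plateau ties broken lexicographically,
  keeping the first) and runs a watershed of the negated Euclidean
  distance transform of the 75 pm foreground from those seeds.
* Candidates are filtered by area, maximum adhesion and edge distance
  (default ≥ 4 px, which guarantees the 8 × 8 crop fits).
* The `(t, 8, 8)` crop places the centroid at index (3, 3) (rows
  r−3…r+4). Pixels outside the candidate's own pixel set are kept, not
  zeroed: the networks receive the full neighbourhood. The 30/60/90 min
  variants are frame prefixes of one another.

## Dataset assembly

* Split 64–16.5–16.5% stratified per class. The conventional ratio sums
  to 97%; the remainder goes to the test set, and per-class counts use
  largest-remainder rounding, so every class is within one sample of
  the target fractions.
* Oversampling repeats minority-class training samples (with
  replacement) until every class matches the majority count; originals
  are always retained.
* Standardization statistics (per-frame-per-pixel μ, σ) come from a
  single Welford pass over the training split only — validation and
  test data are transformed with training statistics, never their own.
  The sample (n−1) variance is used, with an ε = 1e-6 floor on σ for
  constant pixels. Time truncation for the 30/60/90 min variants
  happens before the statistics, so each variant owns its μ, σ.

## Classifiers

All four architectures consume standardized `(batch, t, 8, 8)` videos
and emit class probabilities via a softmax; every convolution is
3 × 3 × 3, stride 1, 'same' padding, and every normalization is a layer
norm (per-sample over all features, per-channel affine).

* **CNN** — two blocks of conv → ReLU → dropout → layer norm → max
  pool, channels 8 then 16. The first pool is (2, 2, 2) (halves time and
  space), the second (1, 2, 2), leaving 2 × 2 spatially.
* **ResNet** — stem conv + pool, then two stages of two basic residual
  blocks with channel plans (8, 16) and (16, 32); 1 × 1 × 1 projections
  on channel changes, no bottlenecks; pooling as in the CNN.
* **DenseNet** — stem conv + pool, two dense blocks of 4 layers with
  growth rate 8 (each layer sees the concatenation of all previous
  feature maps), a halving 1 × 1 × 1 transition between them.
* **CNN-LSTM** — three conv blocks with spatial-only pooling
  (8 × 8 → 1 × 1, channels 8/16/32), per-frame features into a 3-layer
  LSTM of hidden size 256; the last hidden state feeds the head.

Before the head, the convolutional models adaptively average the
temporal axis to 4 bins, so one architecture accepts any frame count
(≥ 8) from the timespan variants. The head everywhere is
FC(→64) → ReLU → dropout → FC(→classes) → softmax. Dropout is 0.2
throughout. The FC width, temporal bin count, DenseNet depth/growth and
dropout rate are free design parameters exposed in `ModelConfig`.

Training: Adam (lr 1e-4, weight decay 1e-5 as an L2 term in the
gradient), cross-entropy, batch size 32, up to 250 epochs with early
stopping (patience 25 on validation loss) and restoration of the
best-validation weights. 5-fold stratified cross-validation operates on
the train+validation pool with a fixed held-out test set.

The layers run on a compact numpy backend written for this package
(im2col 3D convolution, explicit-cache backpropagation, BPTT for the
LSTM). The `(t, 8, 8)` inputs are small enough that single-core numpy
matmuls train each model in minutes; analytic gradients are verified
against central differences for all four architectures in the test
suite.

## Evaluation

Matching between predicted and reference cells is greedy one-to-one by
descending pixel intersection; a reference cell counts as detected iff
its match reaches IoU ≥ 0.3 (configurable — there is no single standard
matching rule, so ours is stated explicitly). DE is the fraction
of reference cells left unmatched. DS is reported as 1 − mean Dice over
matched pairs, a dissimilarity (0 = perfect), with the raw mean Dice
emitted alongside so either convention is recoverable; DS is monotone
under mask degradation only while the match set is fixed — a cell
falling below the match threshold moves error from DS into DE.
Classification metrics are accuracy, macro F1, macro one-vs-rest AUC
and macro average precision; classes absent from the truth are skipped
in macro averages with a warning. t-SNE embeddings of probability
vectors use a perplexity of min(30, (n−1)/3) and a fixed seed.

## Synthetic data

Each cell contributes `A·(1 − e^{−k·(t−t₀)})·G(p; c, σ_f)` after its
onset t₀ (adhesion start plus a uniform jitter), with an isotropic
Gaussian footprint (σ_f = 1.3 biosensor px). Default cell types have
plateaus 140/190/240 pm and rates 0.08/0.06/0.05 min⁻¹: amplitudes sit
5 noise-sigmas apart (noise σ = 10 pm), and all three exceed the 75 pm
threshold over ≈3 × 3 pixels, the occupancy the real sensor resolves
for adhered cells. Baseline frames before the pipetting gap carry only
noise; an optional linear baseline drift ramps to `drift_pm` over the
adhesion phase. Microscope images show ellipses (axes ≈ the scaled
75 pm footprint radius, ±10%) on a noisy background, labelled masks
are those ellipses, and the true transform (default scale 10,
translation (6, 9)) links the planes exactly.

Default recordings are temporally downsampled relative to the real
instrument: 40 adhesion frames at 135 s cover 90 minutes (the device
scans every few seconds; the downsampling keeps desk-scale training
while preserving the kinetic shapes). The pipetting gap default is
1800 s, comfortably above the 10× median-interval detection factor.

What the synthetic data does **not** emulate: cell migration and
detachment, multi-cell superposition on one sensor pixel, non-Gaussian
sensor noise, well-boundary artifacts (hence outlier masking is skipped
in the noiseless segmentation experiments — a 3σ rule on an
artifact-free plate would flag genuine cells), spatially structured
backgrounds, and real cell-type kinetic diversity. Passing the
synthetic experiments therefore demonstrates the pipeline's
correctness and internal consistency, not field performance on real
recordings.

## Reference experiment sizes

The experiments in `adhekin.experiments` use: 100 random transforms;
200 samples for the Welford check; 6 noiseless wells × 20 cells for
segmentation scoring; 600 labelled cells (200 per type, 40 frames) for
class recovery, trained for up to 35 epochs with patience 5 — the
synthetic classes are separated by several noise-sigmas and every
architecture converges within a few epochs, so the short schedule
measures the same endpoint as the full 250-epoch regime; and a
two-type late-kinetics design (120 pm/0.033 min⁻¹ vs 95 pm/0.06 min⁻¹,
within ~4 pm of each other for the first 30 min, ~19 pm apart at
90 min) for the 30-vs-90-minute comparison.

## Known limitations

* Strategy P (predicted masks) shares the cover-pixel code path with M;
  no trained mask predictor ships with the package — masks come from
  disk, the classical fallback segmenter, or a user plugin.
* The greedy match is not globally optimal for pathological overlap
  patterns (it is verified near-optimal on small random instances).
* The numpy training backend is single-core and eager; it is sized for
  `(t, 8, 8)` inputs, not for larger imagery.
* Watershed DS_b against projected-mask references is inherently
  nonzero (~0.3 on the synthetic plates): the watershed region is the
  75 pm superlevel set, while the cover of the drawn ellipse is
  slightly larger — the same direction of disagreement the metrics are
  designed to expose.
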