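# Methods

This note records the scientific and numerical choices behind
`histoclust`: what the pipeline computes, which conventions were fixed
where more than one reading was possible, and what the synthetic testbed
does and does not establish.

## Pipeline

A labelled set of 32×32×3 RGB tiles (intensities in [0, 1]) is optionally
transformed by per-image colour clustering, split stratified 70/30,
and classified by one of three networks under one of two decision
regimes.  Evaluation is image-level on the held-out split.  One global
seed fans out (via `numpy.random.SeedSequence`) into independent
per-stage seeds — generation, clustering, split, weight initialization,
batching/dropout — so a manifest reproduces a run bit-for-bit on one CPU
thread.

## Cluster transform

Pixels are clustered as bare RGB triples; spatial coordinates are
deliberately excluded, which makes the transform a colour quantization
(the 0.2 default Mean-Shift bandwidth is only meaningful on the
normalized colour scale).  Fitting is per image: each tile's own colour
structure is summarized, and no information flows between images, so the
transform cannot leak labels across a train/test split.

* **K-Means** is Lloyd's algorithm with k-means++ seeding, `tol = 1e-4`
  on the maximum centroid movement, at most 300 iterations.  An empty
  cluster is re-seeded at the point farthest from its assigned centroid —
  a deterministic repair that keeps exactly K centroids alive.  Inertia
  is recorded per iteration and is non-increasing (asserted in tests).
* **Mean-Shift** uses a flat (uniform) kernel: each seed is repeatedly
  replaced by the mean of all points within the bandwidth until it moves
  less than `tol = 1e-4`.  Seeds come from a one-bandwidth grid binning
  of the data (one seed per occupied bin), converged modes closer than
  `bandwidth/2` are merged with the better-supported mode winning, and
  every pixel is assigned to its nearest surviving mode.  This makes the
  procedure deterministic given the input order, with no seed parameter.

Re-quantizing an already-quantized tile is a fixed point *when the
surviving modes are separated by more than the bandwidth* (each mode then
re-attracts exactly its own support).  On unstructured colour clouds a
second pass can merge further — that is a property of mode seeking, not a
defect, and the idempotence test therefore uses a modal image.

The transform order is resize-to-32×32 first, then cluster (the cheaper
order, and the one that preserves the stated model input); the pipeline
applies clustering before the split purely for efficiency, which is safe
because fitting is per-image.

## Architectures and parameter accounting

The layer engine is written in numpy with analytic backpropagation;
every gradient path (convolution via im2col, max/average pooling, dense,
LSTM through time, the bidirectional wrapper, dropout) is verified
against central finite differences in `tests/test_layers.py` at
tolerance 1e-4 in float64.

Conventions fixed where the architecture family leaves slack:

* Convolutions are 3×3, stride 1, zero-padded 'same' (implemented as
  cross-correlation; with learned kernels the flip is immaterial).
  ReLU throughout.  Feature-map widths not pinned by the reference
  configuration default to 16 per conv layer in Model 1 (the one stated
  count, C5 = 16, extended uniformly) and 32 in Model 3; both are
  configurable.
* The LSTM uses the conventional gate set — sigmoid input/forget/output
  gates, tanh candidate, `c_t = f⊙c' + i⊙g`, `h_t = o⊙tanh(c_t)` — with
  biases in all four gate blocks, giving the count `4·(h·(d+h)+h)`.
  This convention is adopted because it reconciles the reference
  parameter budget exactly (below).
* Dense activations for the 22-, 65- and 512-unit layers default to
  ReLU; the decision layer is linear.  Weights are Glorot-uniform,
  seeded per layer.  Dropout (p = 0.25) is inverted and active only in
  training passes.

**Model 2's second recurrent block.**  The reference budget for the
stacked LSTM across its six (TS, ID) factorizations —
58280, 52904, 47528, 44840, 42152, 40808 — is reproduced exactly by:
L-1 a 42-unit LSTM on ID-dimensional input (`4·(42·(ID+42)+42)`), a
second block contributing *twice* a 42-unit-on-42-input layer (2·14280),
dense 42→22 (946) and 22→2 (46).  Consecutive rows then differ by
4·42·ΔID, a finite-difference law asserted independently.  Two
realizations of the second block have exactly this count: a
bidirectional 42-unit layer with summed directions (the default — it
keeps "two LSTM layers" and "42 output neurons" simultaneously true) and
a stack of two further 42-unit layers (`l2="stacked"`).  The text alone
cannot distinguish them; only the budget constrains the choice, and both
are provided.

Two printed activation identities in the source material are
typographical (a tanh written as an unscaled affine image of the
sigmoid, and a leaky rectifier written as a sum of sigmoid and ReLU
terms); the standard hyperbolic tangent and leaky rectifier
(`x if x>0 else βx`) are implemented.  No model result depends on this:
the architectures use plain ReLU.

Label convention: benign = 0, malignant = 1 (the positive class).  The
decision rule is argmax of the two scores with exact ties — including an
SVM margin of exactly zero — resolved to benign, the "no disease" label,
deterministically.

## Training

Mini-batch Adam (lr 1e-3, β = 0.9/0.999, batch 32) on the mean softmax
cross-entropy, log-sum-exp stabilized; an end-to-end hinge mode trains
the same networks on the score margin instead.  The default SVM regime
is two-stage, matching the "decide on extracted features" reading: train
under softmax, then fit a soft-margin linear SVM (plain hinge, C = 1, no
intercept by default — the objective as stated carries none) on the
penultimate-layer activations.  The optimizer, rate and batch size are
not pinned by the reference description; these defaults are standard and
stable for networks of this size.  Non-finite loss aborts with a
diagnostic rather than continuing.  Per-epoch train/test accuracy, loss
and MCC are recorded, exportable as CSV and a three-panel PNG.

MCC inside training curves uses the 0-when-undefined convention (a
constant predictor has no defined correlation); the full metric report,
by contrast, refuses datasets lacking an actual positive or negative,
and flags undefined precision (no predicted positives) explicitly while
reporting 0.

## Synthetic testbed

The generator emulates the statistical structure of the motivating slide
collections: ~68.6% malignant prevalence (drawn i.i.d. Bernoulli per
tile), and a class signal carried jointly by background colour and
nucleus morphology — malignant tiles have a darker, warmer background,
roughly 2.5× more nuclei (Poisson counts, means 7 vs 18), and more
eccentric elliptical nuclei.  Gaussian pixel noise (σ = 0.03) and
per-tile colour jitter (σ = 0.03) blur the separation; the
`noise_free()` variant removes both, making the classes separable by a
single threshold on the tile-mean intensity (the package ships that
oracle, and tests assert it scores 100%).

What this does *not* emulate: staining variability across laboratories,
tissue texture beyond blob-shaped nuclei, magnification structure,
patient-level correlation between tiles, or the 760×460 native tile
size.  Passing tests on this data therefore demonstrate that the
pipeline's machinery — transforms, gradients, training loop, heads,
metrics — is correct and reproducible, not that the networks would reach
any particular accuracy on real histology.  The published accuracy /
precision / F-measure figures for the real slide collection (best
accuracy 91% at 200× magnification, best precision 96% at 40×) require
the external image download and ~500-epoch stochastic training; the
package reproduces the *structure* of those experiments (the 18-cell
grid, the K ∈ {8,16,24} and bandwidth ∈ {0.2,0.4,0.6} sweeps, the six
(TS, ID) budgets) and leaves the numbers unasserted.

## Problem sizes

The shipped tests and the acceptance script run at desk scale, chosen as
the package's own study conditions: 400 noise-free tiles, 70/30 split
and 50 epochs for the end-to-end CNN check (which reaches ≥95% held-out
accuracy); 160 tiles, a slim 4-map CNN and 15 epochs for the shared test
fixture; 40 tiles and 1 epoch for grid-structure checks, where the
expected behaviour is majority-class prediction, not accuracy.

## Known limitations

* No class weighting, resampling, augmentation or transfer learning; the
  prevalence imbalance is represented, not corrected.
* Splits are image-level; patient-disjoint splitting is out of scope.
* Mean-Shift is O(seeds × points) per iteration with no KD-tree; fine at
  1024 pixels/tile, not tuned for large images.
* The precision/F columns of rate-form result tables cannot be recomputed
  from rates alone without the class prevalence, so no attempt is made
  to invert them.
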