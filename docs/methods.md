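# Methods

This note documents the models, parameter choices and numerical conventions
behind `eogwave`, and what the synthetic protocol does and does not emulate.

## Signal model and synthetic protocol

A session is five consecutive movement periods — down, up, blink, left,
right in time order, labelled with the standard class ids down=0, blink=1,
up=2, left=3, right=4 — of `samples_per_segment` samples each (default
6500 at 650 Hz, i.e. 10 s per period, 32,500 samples total). Segment tables
are normalized to 0-based half-open blocks, which resolves the off-by-one
ambiguities of 1-based inclusive range notations.

Each period superposes three components on the movement's channel:

* **Saccade pulse** — sigmoid onset (~80 ms transition, the physiological
  saccade timescale), plateau, and a slower sigmoid return to rest
  (8 % of the period). Signed peak amplitudes follow the per-movement
  voltage thresholds of the emulated recordings: right +0.25 V / left
  −0.25 V (horizontal), up +0.20 V / down −0.10 V (vertical). The blink
  period instead carries five biphasic difference-of-Gaussians spikes
  (+0.45 V peak) on the vertical channel with 15 % crosstalk onto the
  horizontal channel.
* **Activity carrier** — a 26 Hz sinusoid with class-specific amplitude
  (down 0.020, up 0.070, blink 0.220, left 0.045, right 0.150 V). 26 Hz
  falls inside the level-4 detail band at 650 Hz (≈20–41 Hz), so every
  4-coefficient window carries class information, not only windows
  containing a saccade edge. Amplitudes of classes sharing a channel are
  spaced by a factor ≥ 3, which makes per-window scale discrimination
  essentially error-free: a deterministic carrier's 4-sample RMS varies
  within a bounded phase factor well below 3.
* **Noise** — additive white Gaussian noise (default SD 4 mV per channel).

The acquisition chain is then emulated by a causal 4th-order Butterworth
band-pass (0.5–50 Hz), clipping to the −0.3…0.5 V envelope, and a uniform
mid-tread quantizer with `2^bits` levels across the envelope (11 bits
default, so 0 V is an exact quantizer level and an all-zero configuration
produces an exactly zero recording). The filter is causal rather than
zero-phase on purpose: AC coupling droops sustained plateaus but preserves
the polarity asymmetry of fast deflections, which zero-phase filtering
would symmetrize away. All randomness flows from a single seed;
identical configurations are bit-identical.

**What this does not emulate.** Real EOG has no sustained class-amplitude
carrier: most discriminative information lives at saccade edges, baselines
drift, and amplitudes vary across subjects and sessions. The carrier is an
idealization that makes short windows class-informative so the classifier
stack can be exercised and verified end to end. Passing tests therefore
demonstrate the correctness of the pipeline, not field performance on
recorded EOG.

### Separability control

`perturb_separability(recording, overlap, seed)` interpolates every sample
toward a class-agnostic pool: with fraction *f*, each output sample is
`(1−f)·own + f·pooled`, where the pooled value is drawn from a uniformly
random class at a uniformly random position inside that class's block (the
same draw on both channels, preserving H/V coupling). At *f* = 0 the
recording is untouched; at *f* = 1 all classes share one amplitude
distribution and no temporal alignment survives, so windowed features are
exchangeable across classes and any classifier falls to chance. Drawing a
random *position* (not the aligned position) matters: position-aligned
pooling leaves cross-block correlations that bias nearest-neighbour voting
*below* chance, breaking the chance closed form `a/(2−a)` = 1/9.

## Wavelet stage

Decomposition is the 5-level discrete wavelet transform with **periodized**
boundary handling, so level-k details have length `ceil(n/2^k)`:
32,500 → 16,250 → 8125 → 4063 → 2032 → 1016. The level-4 series (2032
coefficients) is the preprocessed channel; its 4-sample windows give the
508-window geometry of the default protocol.

Candidate families are haar, coif, sym, bior, rbio (PyWavelets filter
banks), fk and meyr. The 4-tap Fejér–Korovkin filter is hard-coded from its
published taps; the discrete Meyer filter is a 102-tap FIR approximation
obtained by sampling the Meyer conjugate mirror filter's frequency response
(C⁶ incomplete-beta transition band) on a 2¹⁶ grid. Both are refined by a
Gauss–Newton projection onto the exact orthogonal-filter constraints (unit
lowpass gain, zero highpass gain, orthonormal even shifts): the projection
moves the taps by ~2·10⁻⁹ (fk4) and ~2·10⁻⁵ (meyr) while reducing perfect-
reconstruction error to ~10⁻¹² and making detail coefficients of constant
signals vanish to machine precision. The explicit zero-highpass-gain
constraint is needed because, numerically, the vanishing moment is only the
square root of the orthogonality residual when left implicit.

Level entropy is Shannon entropy (base 2) of the normalized **squared**
coefficients, `p_i = c_i²/Σc_j²` — the standard energy-share reading of
wavelet entropy; it is permutation- and scale-invariant and undefined for
all-zero levels (rejected explicitly). The mother wavelet minimizes entropy
aggregated over levels 1–5 (default rule: sum; both channels summed when a
full scan is supplied), with ties broken by candidate input order. The
default mother is reverse biorthogonal 3.1; the scan is exposed so the
selection is reproducible rather than hard-coded — on synthetic sessions
the scan may legitimately prefer a different candidate, and the pipeline
accepts an explicit override.

## Feature stage

Windows are non-overlapping and a trailing remainder shorter than the
window is discarded. Per-channel metrics use population (divide-by-n)
conventions throughout, giving exact identities used as test invariants:
`Power = RMS²`, `AMP = Max − Min`, `Variance = Power − Average²`.
Covariance is the population covariance of a channel's window with the
*other* channel's window — a covariance of a window with itself would
duplicate the variance column — and is therefore identical for the H and V
copies. `Pspectrum` is the maximum of the window's periodogram
`|FFT|²/width` (a `sum` reducer is available; `max` is the default).
Window labels are the majority class over the window's receptive field of
`width·2^level` original samples (64 by default), ties toward the lower
class id; with 6500-sample blocks the first 102 windows are class 0 because
the boundary window contains 36 down-samples against 28 up-samples.

## Classifiers

All three are implemented on numpy alone; scikit-learn appears only as an
independent oracle in the test suite.

* **KNN** (default K=4): Euclidean distance on z-scored features
  (train-set statistics). Vote ties break toward the tied class containing
  the nearest neighbour, then the lower class id; distance ties resolve by
  training order (stable sort).
* **SVM** (default C=14.5, polynomial kernel with γ = 1/n_features, r = 1,
  degree = 3, z-scored features): one one-vs-rest binary machine per class,
  trained by simplified SMO on a precomputed kernel matrix with KKT
  tolerance 10⁻⁴ and a random second working variable (seeded). Pairwise
  updates keep the box constraints 0 ≤ α ≤ C and Σαᵢyᵢ = 0 exact by
  construction. Iteration stops on a KKT-clean sweep; because each pair
  update solves its two-variable subproblem exactly, the dual objective is
  monotone, so three consecutive sweeps with relative objective gain below
  10⁻⁷ are also accepted as converged (this matters on deliberately
  unseparable data, where strict KKT cleanliness is slow to reach). The
  10,000-sweep cap is reported as non-convergence via a warning, never
  silently. Prediction is the argmax of decision values, ties to the
  lowest class id.
* **Decision tree** (default budget 10 nodes, internal + leaves, hence at
  most 4 splits / 5 leaves — exactly enough for five cleanly separated
  classes): exhaustive search over features and midpoint thresholds
  minimizing weighted child Gini impurity, grown best-first by impurity
  decrease; ties prefer the lower feature index, then the lower threshold.
  Growth stops at the budget, purity, or no improving split. Leaves predict
  the majority class and expose class proportions for ROC scores.

Models serialize to versioned JSON (hyperparameters plus parameters).

## Evaluation

The split is stratified: the global train size is `round(n·fraction)`
(default 0.8, seed 4), apportioned to classes by largest-remainder
rounding, so 508 windows split 406/102 and every class's train share is
within one row of its target. Per-class one-vs-rest confusion counts derive
sensitivity, specificity, accuracy and precision as percentages; a zero
denominator yields an explicit `None`, never NaN. `ConfusionCounts`
accepts real-valued entries so published averaged rows can be re-derived
as worked examples (`worked_examples.py`; rows whose printed values are
inconsistent with their own counts are listed but not asserted). ROC curves
are micro-averaged one-vs-rest (per-class scores: KNN vote fractions,
logistic-squashed SVM decision values, tree leaf proportions), with
trapezoidal AUC, tie groups collapsed to single points (constant scores
give AUC 0.5), and the 0.5-cutoff operating point reported. The Jaccard
index defaults to micro (pooled IoU); macro (unweighted per-class mean over
classes present in either sequence) is available.

## Problem sizes and determinism

Default test and acceptance runs use the full 32,500-sample protocol for
the headline checks and a shortened 5×1664-sample session for pipeline
plumbing tests; reconstruction properties use 4096-sample random signals.
Every stochastic component (generator, pooling perturbation, split
shuffling, SMO working-pair choice) draws from explicit seeds, and a full
pipeline run with a fixed config produces byte-identical artifacts.

## Known limitations

* The synthetic carrier makes window-level classification much easier than
  on recorded EOG; results quantify pipeline correctness, not clinical
  performance.
* The blink model is a fixed five-spike train; real blink rate and shape
  vary.
* Only the 4-tap member of the Fejér–Korovkin family is provided.
* The SVM uses simplified SMO without shrinking or error caching beyond
  the margin vector; it is adequate for hundreds of training vectors, not
  tens of thousands.
* No k-fold cross-validation: evaluation reproduces a single stratified
  train/test split by design.
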