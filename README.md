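# eogwave

Wavelet preprocessing and supervised classification of two-channel
electrooculography (EOG) eye-movement recordings.

## The problem

The human eye is a corneo-retinal dipole: shifting gaze rotates the dipole
and produces a signed voltage deflection on skin electrodes — positive on
the horizontal channel for rightward saccades, negative for leftward, and
correspondingly on the vertical channel for up/down movements, with blinks
appearing as large biphasic spikes on the vertical channel. Classifying
these five movements (down, blink, up, left, right; class ids 0–4) from a
two-channel EOG recording is the basis of gaze-driven assistive interfaces
for users with motor disabilities.

`eogwave` implements that classification pipeline end to end, for people
who want a tested, reproducible reference implementation rather than a
notebook:

1. **Signal model / synthesis** — a generator emulating a five-period
   acquisition protocol (10 s per movement, 6500 samples at 650 Hz,
   0.5–50 Hz band, 11-bit quantization, −0.3…0.5 V envelope), plus readers
   and writers for delimited text and MAT-style containers.
2. **Entropy-guided mother-wavelet selection** — each channel is decomposed
   to five levels (periodized discrete wavelet transform) for each
   candidate family (haar, coif, sym, fk, meyr, bior, rbio); every level's
   detail coefficients are scored by the Shannon entropy of their
   normalized energy distribution,
   `S = −Σ p_i log₂ p_i` with `p_i = c_i² / Σ c_j²`,
   and the candidate with the least total entropy becomes the mother
   wavelet (reverse biorthogonal 3.1 by default).
3. **Windowed features** — the level-4 detail series (length
   `ceil(n/2⁴)` = 2032 for a 32,500-sample session) is cut into 508
   non-overlapping 4-sample windows; nine metrics per channel (RMS,
   peak-to-peak amplitude, variance, average, median, cross-channel
   covariance, maximum, periodogram peak, power) give 18-dimensional
   labelled feature vectors.
4. **From-scratch classifiers** — K-nearest neighbours (Euclidean
   distance, majority vote, K=4), a one-vs-rest soft-margin SVM with the
   polynomial kernel `K(x_i,x_j) = (γ x_iᵀx_j + r)^d` trained by simplified
   SMO (C=14.5), and a binary decision tree grown by exhaustive Gini-index
   split search (`gdi = 1 − Σ p_i²`) under a 10-node budget.
5. **Evaluation** — stratified 80/20 split, confusion matrices with
   per-class sensitivity/specificity/accuracy/precision, micro-averaged
   one-vs-rest ROC curves, and the Jaccard similarity
   `J(A,B) = |A∩B| / |A∪B|` (micro: pooled TP/(TP+FP+FN); for single-label
   predictions this equals `a/(2−a)` with `a` the accuracy).

## Worked example

```bash
python examples/04_train_and_evaluate.py
```

```
train windows: 406, test windows: 102
algorithm   train J   test J  test acc  ROC AUC
knn          0.9902   1.0000    1.0000   1.0000
svm          0.9951   0.9806    0.9902   0.9998
dt           1.0000   0.9806    0.9902   0.9939

With fully overlapped classes the same pipeline falls to chance:
  knn  test Jaccard 0.0737 (chance closed form 0.1111)
  svm  test Jaccard 0.0794 (chance closed form 0.1111)
  dt   test Jaccard 0.0968 (chance closed form 0.1111)
```

The five movement classes of the default synthetic session are recovered
almost perfectly by all three classifiers (a Jaccard index of 0.98 means a
single misclassified test window out of 102). After the separability
perturbation pools the classes' amplitude distributions, every classifier
falls to the chance closed form 1/9 for five balanced classes — the
pipeline's performance tracks the information actually present in the
signal, not an artifact of the tooling. The remaining examples generate and
describe a session (`01`), reproduce the entropy scan tables (`02`), the
window-count arithmetic (`03`), and re-derive published per-feature metric
rows from their raw confusion counts (`05`).

There is also a thin CLI over the same library:

```bash
eogwave synth --seed 4 --out rec.csv
eogwave wavelet-scan rec.csv
eogwave features rec.csv --mother rbio3.1 --out feats.csv
eogwave evaluate feats.csv --seed 4
eogwave run --config run.yaml     # full pipeline with persisted artifacts
```

## Layout

```
src/eogwave/
  io.py               recording data model, CSV/MAT readers and writers
  synth.py            synthetic acquisition protocol + separability control
  wavelets.py         decomposition, level entropy, mother-wavelet selection
  features.py         windowing and the 18 per-window metrics
  classifiers.py      KNN, SMO-trained polynomial SVM, Gini tree (from scratch)
  evaluation.py       splits, confusion counts, derived metrics, ROC, Jaccard
  worked_examples.py  published per-feature confusion-count rows
  pipeline.py, cli.py orchestration and the eogwave command
docs/methods.md       model assumptions, parameter choices, limitations
examples/             one narrative script per capability
```
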