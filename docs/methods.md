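# Methods

`sungkit` implements an end-to-end analysis workflow for SUNG corpora —
field-recorded collections of animal vocalizations that are **S**mall,
**U**nbalanced, **N**oisy, but **G**enuine. The workflow has four parts:
multi-space acoustic parameterization of calls, supervised-embedding
diagnostics, classifier benchmarking with chance baselines, and
leakage-aware train/test splitting. A synthetic corpus generator with
known ground truth makes every part testable without recordings.

## Data model

A *call* is one vocalization: identity labels (individual, call type, vocal
sequence), an f0 contour as (time, Hz) pairs with call-relative times, a
duration (s), a harmonics-to-noise ratio (dB), and optionally a waveform.
A *vocal sequence* is a run of calls from one recording bout; all calls of a
sequence share an emitter and a soundscape, which is the crux of the leakage
analysis below. Corpora are plain text on disk: a delimited call table plus
one contour file per call (two-column TSV or Praat PitchTier text).

Corpus selection follows the standard repertoire-study rule: restrict to the
focal call types first, then keep individuals with at least a minimum number
of calls among those types (the reference corpus uses 5 types and a
70-call minimum, yielding 1,560 calls from 10 individuals).

Missing feature cells (in practice: f0-trace descriptors that could not be
measured) are imputed by an iterative random-forest regressor trained on the
co-observed features; which columns are imputable is configuration
(`table.F0_IMPUTABLE` by default in the corpus pipeline; any column when
called directly). Standardization is plain z-scoring; in every evaluation
the *training* partition supplies the statistics, so the transform can never
leak test information.

## Feature spaces

**Bioacoustic (20 columns).** Expert landmarks of the f0 contour — onset,
offset, mid, mean, max and its time, and four piecewise slopes (onset→max,
max→offset, first half, second half) — plus energy-distribution descriptors
(frequency and time quartiles of summed spectral energy, and the
frequency/time of maximal energy), duration and HNR. The energy block uses a
Hamming spectrogram (1024-sample FFT, 50% overlap) band-limited to
500–12000 Hz; quartiles are invariant to global amplitude scaling by
construction. A monotone contour has an empty ascending or descending
segment; its slope is reported as 0 with a quality flag so downstream tables
stay complete. `f0.sta`/`f0.end` (contour values at the exact call
boundaries) are computed but excluded from the default 20-column set as
near-duplicates of onset/offset; membership is configurable
(`features.BIOACOUSTIC_SET`).

**DCT (7 columns).** The first five orthonormal DCT-II amplitudes of the f0
contour, plus duration and HNR. The contour is linearly resampled at 64
*midpoint* grid times ((k+½)/64 · T), which aligns the samples with the
DCT-II basis so a half-cycle cosine contour maps onto a single coefficient.
Odd-order coefficients are sign-flipped so that dct1 > 0 means a rising
contour; dct0 is proportional to the contour mean and dct2 tracks curvature.
Unvoiced gaps are bridged by the interpolation.

**MFCC (192 columns).** Mel-frequency cepstra from a 33-filter triangular
filterbank over 500–12000 Hz, ~23 ms Hamming frames with 50% overlap, 32
coefficients per frame (the zeroth, pure-energy coefficient excluded), plus
delta and delta-delta regression derivatives (width-2 window, edge-padded).
The call-level vector is the per-coefficient mean and standard deviation
over frames: 2 × 3 × 32 = 192 values. The spectral front-end (framing, mel
filterbank, cepstral lifter-free DCT) is implemented in-package on
numpy/scipy primitives. Calls must contain at least two frames (~35 ms at
44.1 kHz) and the sampling rate must cover the 12 kHz band edge.

The union of the three sets deduplicates the shared duration and HNR
columns: 20 + 7 + 192 − 2 = 217 features.

**f0 templates.** A call type's template is the pointwise mean of its
contours after each is linearly time-rescaled to the type's mean duration
and resampled on a common grid (100 points by default), with central 50% and
80% pointwise percentile bands. Templates commute with global time scaling.

## Supervised embedding diagnostics

Feature tables are projected to 2-D with supervised UMAP (Euclidean
neighbor metric, 100 neighbors, min_dist 0.01, labels passed as the
categorical supervision target, supervision weight at the library default).
Because the projection is stochastic, cluster quality is profiled over
repeated embeddings: repetition *r* uses seed `master + r`, silhouettes are
computed per call in each 2-D embedding, then averaged per call, per class
(average silhouette width, with sd) and overall (the size-weighted mean of
class means). Classes with one member are excluded with a warning.

*Caveat, asserted in the test suite:* a supervised embedding imposes the
labels on the layout, so even randomly assigned labels embed as separated
clusters with high silhouettes. The profile is therefore a **comparative**
diagnostic — contrast labelings, feature sets, or classes against each other
— not an absolute test against zero. The silhouette statistic itself is
centered on zero for uninformative labels when computed on the data directly.

## Metrics and evaluation protocol

Four metrics, all checked against brute-force oracles in the tests:

* **balanced accuracy** — mean per-class recall from the confusion matrix
  (reference classes on rows); empty reference rows are excluded with a
  warning. Chance level is 1/k (0.200 for 5 classes, 0.100 for 10).
* **multi-class log loss** — mean −log p(true class), probabilities clipped
  to [1e-15, 1−1e-15]; rows must sum to 1 within 1e-6.
* **prior-weighted one-vs-one AUC** — for every class pair, the symmetrized
  Mann–Whitney AUC over the rows of the two classes, weighted by the product
  of class frequencies; ties contribute ½; reduces exactly to the rank AUC
  for two classes.
* **accuracy** — kept for comparability; biased on unbalanced data.

**Repeated holdout.** Metrics are averaged over repeated (default 100)
stratified 80/20 splits: per repetition, draw a split (per-class test share
within ±1 call of 20%), z-score with training statistics, fit, score, and
row-normalize the confusion matrix; confusion matrices are averaged after
row-normalization. Repetition seeds derive deterministically from the master
seed. A repetition whose training draw lost a class is redrawn (≤10 tries).

**Nested permutation null.** The chance baseline shuffles the predicted
variable *within* each level of a secondary variable (e.g. call type within
individual), preserving per-level label multisets (asserted on every
permutation); each permutation runs one full standardize/fit/score split.
The empirical p is count/n (minimum 0), with "at least as good" meaning ≤
for log loss and ≥ otherwise.

**Permutation feature importance.** The model is fit once; each test-feature
column is shuffled 50 times (default) and the mean performance drop and its
sd are reported.

## Classifier families

* **DFA** — linear discriminant analysis on a *balanced* per-class random
  subsample of the training pool: exactly ⌊2/3 × smallest class count⌋
  calls per class (floor rounding), making the prior uniform under
  imbalance. Collinearity front-ends: stepwise VIF reduction (drop the
  largest-VIF feature, recompute, repeat until all VIFs < 5; ties go to the
  later-listed column so a duplicated column loses to its original), or a
  PCA projection whose component count minimizes the lowess-smoothed
  cross-validated log-loss curve (spans ≥ 1 are clamped to use every point —
  consistent with the observation that larger spans stop moving the
  minimum). For MFCC inputs to DFA only the 96 frame-mean columns are used;
  the per-call sd columns act as near-constants for the discriminant and are
  dropped.
* **SVM** — C-SVC with linear/polynomial/radial kernels; class weights
  w_c ∝ 1/n_c as misclassification costs; probability outputs via Platt
  scaling (a `probability=False` fast path returns one-hot votes when only
  ranking-free metrics like balanced accuracy are needed).
* **XGBoost** — gradient-boosted trees, histogram method, single-threaded
  for determinism; class weights as per-sample weights.
* **Dense network** — an in-package numpy implementation: 1–3 ReLU hidden
  layers, inverted dropout on the input and every hidden layer,
  glorot-uniform initialization, softmax output with sample-weighted
  cross-entropy, Adam at lr 0.001, mini-batches of 128, epochs as a tuned
  hyperparameter (no early stopping). Implemented directly because the
  protocol requires both dropout and class-weighted training.

**Hyperparameter tuning** is decoupled from the 100-repetition evaluation:
a configuration's score is its mean log loss under 5×-repeated stratified
5-fold cross-validation (configurable), and the search (default budget 25)
is a random-forest surrogate optimizer with a lower-confidence-bound infill
over the declared ranges (power-of-two parameters sampled on the log2
scale); budgets below 5 fall back to random search. Log loss is the tuning
metric because it is probability-aware and usable for every family.

**Stacked ensembles.** Base (classifier, feature set) configurations produce
out-of-fold class probabilities over the training set (5-fold); the
super-learner — multinomial logistic regression with an L2 penalty, strength
chosen by internal cross-validation — trains on those. At test time bases
are refit on the full training set. The seven benchmark ensembles (three
per-classifier stacks, three per-feature-set stacks, one 9-base stack) are
constructible from configuration alone. Stacking needs calibrated base
probabilities; feeding it one-hot votes degrades the super-learner.

## Leakage-aware splitting

**Overlap count.** For a partition, Σ over sequences of min(#train, #test)
— the number of call moves needed for every sequence to lie wholly in one
set, counted regardless of the 80/20 size constraint. 0 = leakage-fair.

**GA splitter.** Candidates are test-membership masks evolved under weighted
rules, each normalized to [0, 1] before weighting: match class proportions
(total-variation distance between test and corpus class mix), minimize or
maximize normalized sequence overlap, or keep (individual, type) cells
unsplit. The population (50) starts from stratified random splits; each
generation every candidate spawns a mutant by swapping one train call with
one test call *of the same class* — preserving set sizes and class
proportions exactly — parents and offspring compete (μ+λ selection, 500
generations), the best-ever candidate is kept, and there is no
recombination. Deterministic per seed.

**Scenarios.** `default` = stratified random (no sequence control); `fair` =
GA with the overlap-minimizing rule; `skewed` = GA with the
overlap-maximizing rule (still an exact partition). Fair ≤ default ≤ skewed
in overlap by construction on corpora with multi-call sequences.

**Type-disjoint stress split.** The corpus is first reduced to the largest
complete (individual × type) grid in which every cell has ≥ 18 calls
(configurable), over at least two types and at least as many individuals as
types — individuals are the classes of the signature task, so a grid wider
in types than individuals would trade classes for predictors; on the
reference composition this rule keeps 902/1560 calls (57.8%) over 5
individuals × 4 types. Whole cells are then assigned to train or test by the
same GA machinery (bit-flip mutations, hard penalty on individuals confined
to one set, soft pull of the test share toward 20%), so that every
individual appears in both sets with disjoint call-type sets.

## Synthetic corpus generator

The generator targets the *statistical* structure of a SUNG corpus, not
acoustic realism:

* **Call types** — raised-cosine f0 bells forming a graded continuum; the
  five defaults rise in peak (1200→1800 Hz), excursion (150→750 Hz) and
  duration (0.10→0.35 s) from P to SCB, with SCB harmonicity 2.2 dB below B.
  Durations are floored at 50 ms (real tonal calls are longer, and two
  analysis frames must fit in a call).
* **Individual signatures** — per-individual pitch offset (default sd
  80 Hz), lognormal duration scaling (sd 0.10) and per-(individual, type)
  excursion scaling ("idiolect", sd 0.05); all recorded in the ground truth.
* **Imbalance** — per-(individual, type) call counts default to the
  reference 10×5 composition (1,560 calls); scaled corpora use
  largest-remainder rounding so counts match the profile exactly.
* **Sequences** — each individual's calls (types mixed) are grouped into
  sequences: 45% singletons, 20% doubles, the rest 3 + Poisson(2.4) long
  (mirroring the reference corpus's 259/111/201 breakdown with mean long
  length ≈ 5.4).
* **Confound** — each sequence draws one N(0, confound_sd) value, stored in
  the ground truth and applied by `apply_sequence_confound` as an additive
  shift of *every* feature in units of that column's sd. This isolates the
  shared-soundscape leakage mechanism in a controllable, assertable form
  (default 0 = off). Injecting at the feature level rather than synthesizing
  correlated background audio keeps the mechanism exact.
* **Waveforms** (optional) — additive harmonic synthesis from the contour
  with 1/h rolloff plus white noise at the power ratio implied by the
  target HNR; sufficient for the MFCC and spectrogram paths.

What passing tests on this generator do **not** show about real data: there
is no reverberation, no overlapping callers, no pitch-tracking error, no
nonlinear phenomena beyond the HNR proxy, and the confound is a clean 1-D
shift rather than a structured soundscape. Results on synthetic corpora
validate the machinery and the leakage mechanism, not field performance.

## Numerical and design choices

* Repetition/permutation seeds derive from the master seed (`seed·100003 +
  rep` and similar); nothing relies on global RNG state.
* Probability rows are renormalized after clipping to [0, 1]; class columns
  are aligned to the sorted training-class order everywhere.
* Empirical p uses the count/n convention (minimum 0), not (count+1)/(n+1).
* Zero-variance columns standardize to 0 with a warning rather than NaN.
* VIF of a perfectly collinear pair is ∞; the later-listed column drops.
* The GA's same-class swap mutation makes the class-proportion rule exactly
  conserved, so overlap rules optimize inside the stratified family.
* Scaled-down problem sizes in the test suite and acceptance script (corpora
  of 200–1,500 calls, 2–20 evaluation repetitions, reduced GA budgets) are
  the package's choice of desk-scale study conditions; the qualitative
  results they check (chance anchors, leakage ordering, null and signal
  recovery) are size-stable.

## Known limitations

* The artifact consumes f0 contours; it does not pitch-track noisy audio.
* S-UMAP silhouettes are comparative (see caveat above).
* The skewed/default contrast shrinks as sequences lengthen (with long
  sequences a plain stratified split is already near-maximal overlap);
  demonstrating all pairwise scenario gaps therefore uses a corpus whose
  multi-call sequences are short (mean ≈ 3.5) with a strong confound.
* No resampling-based imbalance treatments (class weights only), no
  spectrogram-input deep models, no GPU paths.
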