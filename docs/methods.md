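# Methods

This note documents the model implemented by the package, the numerical
choices it makes, what the synthetic benchmark does and does not emulate,
and the known limitations.

## The representation

A multivariate instance (an n × v matrix, typically a tri-axial
accelerometer segment, v = 3) is turned into a sparse bag-of-words feature:

1. **Windowing.** Every sliding window of length w (all n − w + 1 start
   offsets) of each axis is extracted. By default each window is
   z-normalized to mean 0 and population standard deviation 1, which makes
   the words invariant to amplitude and offset; windows whose std falls
   below 1e−8 are treated as flat and mapped to the all-zero window. A
   whole-series normalization mode is available through
   `SFAParams(normalize_series=True)` for pipelines that prefer to
   normalize once before windowing.
2. **Fourier approximation.** Each window is reduced to its first l/2
   complex DFT coefficients under the convention
   X_u = (1/n) Σ_x T(x) e^(−j2πux/n), interleaved into l real values.
   Because X0 equals the window mean, it is dropped by default
   (`drop_first_coeff=True`) and the l values come from X1…X_{l/2}; this
   buys offset invariance even when window normalization is off. When X0
   is dropped the implementation also subtracts the window mean before the
   FFT — mathematically a no-op for the kept bins, but it removes the
   offset exactly instead of up to FFT cancellation error. The 1/n factor
   cancels in equi-depth binning, so words do not depend on it; it is kept
   for fidelity to the printed convention.
3. **Quantization (MCB).** For each of the l coefficient positions, an
   equi-depth table of c intervals is fitted on the coefficients of *all*
   sliding windows of all training instances: interior breakpoint a of a
   column is the sorted column value at 0-based rank ceil(a·N/c) (the
   first element of the next bin). Membership is half-open — a value equal
   to a breakpoint joins the upper interval — evaluated by binary search.
   Ties in the training column can collapse duplicate breakpoints and
   empty a bin; the interval rule stays well defined. Alphabet symbols are
   lowercase letters a…z in interval order.
4. **Words and histograms.** Each window becomes a length-l word; each
   word is prefixed with its source-axis index ("2" + "ab" → "2ab"; axes
   beyond 9 use a delimited "10|" prefix). Numerosity reduction counts a
   word only when it differs from the immediately preceding window's word,
   suppressing runs from stable signal stretches; the comparison is reset
   at each axis boundary (the prefix already guarantees inequality there,
   but the explicit reset keeps the invariant independent of the prefix
   encoding). The per-axis histograms are fused by disjoint union into the
   multivariate feature.

The per-window sliding transform used by the pipeline is a batched FFT
over a strided window view; an incremental sliding-DFT variant
(`mft_sliding_coefficients`, the O(l)-per-window recursive update with a
full recomputation every 256 windows to bound floating-point drift) is
provided and held to a 1e−8 agreement contract with the direct per-window
DFT.

## Classification: tf-idf vectors and asymmetric cosine

Each class C is summarized by one sparse vector over the training
vocabulary with weights

    tf(p, C)  = 1 + ln( Σ_{T∈C} B_T(p) )       (0 if the word is absent)
    idf(p)    = ln( |CLASSES| / #classes containing p )
    weight    = tf(p, C) · idf(p)

A query histogram is represented by its own tf vector, tf(p, Q) = 1 +
ln B_Q(p), with no idf on the query side. The similarity is the asymmetric
cosine: the dot product over the query's words divided by the query norm
(over the query's words only) and the model norm (over the class's full
vector). This is exactly the form the method defines; it is not a true
cosine over a shared vocabulary, and the package implements it as printed.
Natural logarithms are used throughout: any fixed base rescales tf and idf
by constants, but the cross-base factors do not cancel in the mixed
products of the similarity, so one base had to be fixed and documented.

Predicted label = argmax over classes; ties go to the earlier class in
lexicographic order (deterministic confusion matrices). An empty or fully
out-of-vocabulary query scores 0 everywhere, is assigned the first class,
and is flagged as degenerate in the prediction object.

## Fitting: grid search with cross-validation

Window candidates form an arithmetic progression from 10 to n with step
round(√(n−10)) — about √n candidates; candidates too small to host the
maximum word length (w < l_max + 2 with the dropped first coefficient) are
filtered. For each candidate w the instances are transformed once at
l_max = 16; each smaller word length in the grid {4, 6, …, 16} is derived
by truncating words to their first l symbols, which is exactly equivalent
to refitting at that length because MCB columns are fitted per coefficient
position (the equivalence is asserted by a dedicated oracle test). A
stratified, seeded k-fold (default 10) cross-validation counts correct
held-out predictions; the (w, l) with the highest total wins, ties going
to the smaller l and then the smaller w (cheaper models). Notable choices:

- **MCB is fitted once per candidate w on the full training set**, outside
  the fold loop, mirroring the training algorithm's structure where the
  transform precedes cross-validation. The mild information sharing across
  folds is inherited from the method and documented here.
- **Final models are refit on the entire training set** at the chosen
  (w, l). The pseudocode returns the tf-idf tables of the last CV fold
  (9/10 of the data); this is read as a pseudocode artifact, and refitting
  on everything dominates.
- **Folds are stratified** with a fixed, config-overridable seed. Classes
  smaller than the fold count reduce it (never below 2); singleton classes
  are pinned to the training side with a warning.
- Inside the grid search, histograms live as integer word codes in sparse
  count matrices and the per-fold tf-idf/cosine arithmetic is vectorized;
  a dual-route test asserts the fast path agrees fold-by-fold with the
  dictionary-level `build_class_models`/`predict` route, which is what the
  final refit and prediction use.

## Evaluation protocols

- **Personalized**: per subject, stratified k-fold where each test fold is
  predicted by a classifier fit (including parameter selection) on the
  subject's other folds. Reports per-subject accuracies, a pooled
  confusion matrix, and the mean/median across subjects.
- **Generalized (LOSO)**: one fold per subject; fit on all other subjects,
  score on the held-out one. Same report shape.

Accuracy is trace/total of the pooled confusion matrix (rows = truth,
columns = predicted, order = lexicographic class order).

## Segmentation

Fixed-size sliding windows with fractional overlap (starts every
round(seg_len·(1−overlap)) samples, trailing partial windows discarded —
no padding), or, for impact-like events, windows centered on upward
magnitude-threshold crossings: a peak at t is valid iff mag(t) > θ and
mag(t−1) < θ, with θ = 1.5 by default under the assumption that data are
expressed in g. "Centered" places floor((len−1)/2) samples before the
peak; windows that would cross the recording bounds are skipped.

## The synthetic benchmark

The generator emulates the structure of smartphone HAR datasets at desk
scale. The frozen default: 6 classes — four dynamic (walking 1.2 Hz,
stairs_up 1.6 Hz, stairs_down 2.3 Hz, jogging 3.2 Hz, each a per-axis
harmonic stack plus a gravity-projection offset) and two static postural
classes (sitting: 0.7 Hz sway; standing: 4.2 Hz micro-sway) — 10 subjects,
50 Hz, 128-sample segments, 4 instances per class per subject (240
total), Gaussian noise std 0.2 g, and 5% multiplicative per-subject
amplitude/frequency jitter. Phases and jitter factors are drawn once per
(subject, class), so zero-noise instances of a class are identical for a
subject; a single root seed with stable spawn keys makes every stream
reproducible and insensitive to adding subjects.

Calibration note: class fundamentals are spread (≥ 0.4 Hz apart after
jitter) and all classes are clearly tonal. Two failure modes observed
during design drove this: (i) classes with near-noise-level tones develop
enormous vocabularies and act as similarity sponges for slightly
out-of-distribution queries under the asymmetric cosine; (ii) very low
noise makes the per-class coefficient clouds so tight that a few percent
of subject frequency jitter pushes an entire held-out subject across MCB
breakpoints, collapsing vocabulary overlap. Moderate noise (0.2 g) widens
the clouds and is what makes leave-one-subject-out transfer reliable here.
The configuration was calibrated once against the ≥95% LOSO design point
and then frozen.

What passing tests on this benchmark do **not** show: robustness to real
gait variability, device orientation changes, sensor drift, class
imbalance, or label noise — real LOSO accuracies on public HAR datasets
are substantially lower than on this deliberately separable benchmark.
The generator makes no attempt at biomechanical realism.

## Baseline features

Per axis: mean, median, min, max, population variance and std, zero
crossing rate (strict sign flips / (n−1)), RMS; DC magnitude, the sum of
the magnitudes of the first five non-DC Fourier coefficients, spectral
energy (mean squared magnitude over the non-DC half-spectrum), and
spectral entropy (Shannon entropy in nats of the normalized non-DC power
spectrum, with 0·log 0 = 0). Frequency features use raw windows — on
z-normalized windows the DC component would always be 0. 36 features
total, axis-major, frozen names.

## Memory accounting

Raw footprint = instances × n × v × 8 bytes (doubles). Symbolic footprint
= Σ over histograms of (UTF-8 word length + 4 bytes per count). Reduction
= 100·(1 − symbolic/raw). On the default benchmark the reduction at
(w = 30, c = 4) is strongly word-length dependent: short words (l = 4)
compress well, long words (l = 16) on noisy data can exceed the raw size
because numerosity reduction finds no stable runs; the package reports
whatever the data give.

## Problem sizes and determinism

The bundled benchmark and the reproduction script use the frozen default
configuration (240 instances); the full grid search over ~10 window sizes
× 7 word lengths with 10-fold CV fits in a few seconds per training set,
and the complete LOSO + personalized evaluation in a couple of minutes on
one CPU. Every source of randomness (generator, fold shuffling,
permutation controls) flows from a single integer seed; repeated runs with
the same seed and configuration produce byte-identical model and report
files (timings are logged to stderr, never written into output files).

## Known limitations

- The asymmetric cosine inherits the method's sensitivity to vocabulary
  size imbalance between classes (small-norm classes attract weakly
  matching queries).
- MCB fitted on the full training set inside the grid search shares
  quantization information across CV folds (inherited from the method).
- Words beyond ~9 axes use a delimited prefix; mixed-axis-count datasets
  are rejected rather than padded.
- No resampling, gap imputation, calibration, or gravity/body-component
  filtering; inputs are assumed clean, regularly sampled, and in g.
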