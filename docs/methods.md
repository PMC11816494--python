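# Methods

## Scope and data model

The package operates on fixed-length multichannel epochs (rows = time
samples, columns = channels), each carrying a class label and a subject
identifier. Epoch payloads are headerless CSV or `.npy`; datasets are
indexed by a manifest CSV (`epoch_id,subject_id,label,path`). Continuous
EDF recordings can be read (via the optional `mne` dependency) and cut
into non-overlapping epochs of `floor(epoch_seconds × fs)` samples, with
the trailing remainder dropped. No filtering, re-referencing or artifact
rejection is applied; missing values are rejected rather than imputed.
Channel indices in user-facing formulas are 1-based; all internal arrays
are 0-based, translated once at module boundaries.

## Feature extraction

At each time sample the channel vector is ranked by a *stable* descending
argsort: ties keep ascending channel order. Tie handling matters for
quantized EEG, where equal samples occur; the stable rule makes extraction
deterministic and matches the common default of numerical environments.
Each consecutive rank triplet becomes a base-n code and the epoch feature
vector is the dense length-n³ histogram of all `ln × (n − 2)` codes. Dense
storage is deliberate: at the largest supported montage (n = 32) a vector
is 32,768 int64 entries, small enough that sparse bookkeeping would only
add complexity. Counts are used raw, with no normalization — epochs of
equal length are directly comparable, and the downstream selector is
scale-aware.

Consequences used as test oracles: counts sum to `ln × (n − 2)`; with no
ties at a time sample, only codes with pairwise-distinct base-n digits can
occur (at most `n(n−1)(n−2)` nonzero bins); any strictly increasing
elementwise transform or any permutation of time samples leaves the vector
bit-identical.

## Feature weighting (diagonal NCA)

Per-feature relevance is learned by a neighborhood component analysis
restricted to a diagonal metric, the feature-weighting variant of NCA:
with `d_w(i,j) = Σ_r w_r² |x_ir − x_jr|` and softmax neighbor
probabilities `p_ij ∝ exp(−d_ij)` (self excluded), maximize

    F(w) = Σ_i Σ_{j ∈ class(i)} p_ij − λ Σ_r w_r²,

with λ = 1/n_samples by default, solved by L-BFGS from `w = 1`
(gradient tolerance 1e−6, iteration cap 100, both configurable). The
softmax is computed with the usual max-shift stabilization, which is
exact. Constant columns are excluded from the fit and reported with
weight exactly 0. The optimizer runs on the magnitude parametrization
(the distance uses w², so signs are irrelevant); reported weights are
absolute values, clipped at zero. The fit is deterministic — there is no
random component.

Two numerical regimes are worth knowing about. On standardized or
unit-scale features the kernel is immediately sensitive and weights
differentiate quickly. On raw count features the initial distances are
large and `exp(−d)` saturates to a hard nearest-neighbor assignment; the
quadratic penalty then contracts all weights until the kernel
de-saturates, after which the data term takes over. This auto-scaling is
why the selector works on raw histograms; a `standardize` flag is
available but off by default (raw features are the package's stated
input). Pairwise computations are chunked (~2×10⁷ elements per chunk) to
bound memory.

## Selection range and greedy search

Weights are sorted descending (ties broken by ascending feature index)
and normalized to sum 1. The loop range is `sv` = smallest prefix whose
cumulative weight ≥ 0.75 and `fv` = smallest prefix ≥ 0.99 — the two
thresholds are the model's fixed operating points, exposed as parameters.
An epsilon of 1e−12 guards exact-threshold cases against float summation
error. Every prefix size in [sv, fv] is scored by the inner evaluator —
1-NN with Euclidean distance under 10-fold stratified CV with a fixed
shuffle seed; k and metric are configurable, and the simplest kNN is the
default since the design only fixes "kNN with 10-fold CV" — and the
smallest prefix achieving the maximum accuracy is selected (first maximum
on ties, favoring parsimony). Selected sets are nested by construction
(prefixes of one ranking).

## Ensemble classification

The 30-point grid is ordered k-major (k = 1…5, then distance, then
weighting); the order fixes candidate indexing and therefore tie-breaks.
Predictions are out-of-fold under either 10-fold stratified CV (shuffled,
seeded; the design is silent on stratification, which is adopted as the
standard safeguard for unbalanced labels) or LOSO CV grouped by
subject_id. When a training fold is smaller than k, k is truncated with a
warning. Inverse-distance weighting follows the usual convention that an
exact-distance-0 neighbor takes all weight — which is why k = 1 inverse
and equal weighting coincide.

Voting sorts the 30 outcome vectors by overall accuracy (descending,
stable) and emits the per-sample mode of the top q for q = 3…30. A bare
mode needs a tie rule: ties go to the label predicted by the most
accurate participating outcome. The final outcome is the first maximum
over the 58 candidate accuracies (30 parameter + 28 voted, in that
order), so the ensemble's accuracy is ≥ every single configuration's by
construction. Vote-sorting accuracies are computed on the same folds as
the candidates themselves.

The geometric mean is the per-class recall product to the power
1/n_classes; F1 is reported per class and macro-averaged (a single-class
F1 on the majority class can exceed accuracy, so the per-class values are
the ones to compare against majority-class figures).

## Pipeline order, leakage and seeds

The default pipeline runs selection once on the full feature matrix and
then cross-validates the classifier on the selected features — the
model's literal stage order. This leaks selection information into the CV
estimate: features chosen using all labels retain chance correlations
with them, and on label-independent data the estimate can sit far above
chance. `nested=True` therefore re-runs weighting, range computation and
prefix search inside every training fold and scores the held-out fold
with the inner 1-NN; this is the leak-free estimate (the 58-candidate
argmax is defined on whole out-of-fold prediction vectors and has no
per-fold analogue, so the nested mode uses the inner classifier). The
selection evaluator and the final classifier intentionally use different
fold seeds (seed, seed + 1) so a prefix size tuned on one set of folds is
not scored on the same folds.

## Directed-Lobish readout

Selected feature indices (0-based bins; +1 gives the 1-based identity)
are digit-separated into their three channels. The digit formula yields
the triplet in reverse encoding order; by default the digits are
re-reversed so symbols appear in ranking order. The histogram and entropy
are order-independent; the transition table is not, so the order is an
explicit, configurable choice. Montage tables map channels to lobe
symbols; the built-in 32- and 14-channel tables are locked by golden
tests, and custom tables can be supplied as symbol lists. Entropy is
Shannon entropy in bits of the *symbol histogram* (not of the transition
matrix), and the complexity ratio is 100·H/log₂(alphabet size). The
connectome graph has the used symbols as nodes and transition counts as
directed edge weights, exported as GraphML or DOT.

## Synthetic benchmark

The generator emulates the target recordings' shape — 14 channels at
128 Hz (or 32 at 256 Hz), 15 s epochs, binary labels, several epochs per
subject — with epoch

    x[t, c] = (m[t] + ε[t, c]) · g_class[c] · exp(subject_sd · z[s, c]),

where `m` is a three-sinusoid mixture (10, 6, 22 Hz with amplitudes 1.0,
0.7, 0.5 and per-epoch random phases), ε is white Gaussian noise
(sd 1.0), and one class's gain is multiplied by `1 + effect_size` on four
channels spread across the montage. Defaults: 10 subjects per class, 10
epochs each (200 epochs), effect_size 1.0 (a 2× amplitude contrast),
subject_sd 0.2. The class signal is planted in channel *gain order*
because the features are pure rank statistics — a spectral-only contrast
would be invisible to them and make end-to-end tests vacuous. The
log-normal per-subject channel gain makes subjects identifiable, giving
LOSO a genuine generalization gap relative to 10-fold CV.

What passing tests show: the pipeline recovers a strong amplitude-order
contrast essentially perfectly, and a leak-free evaluation of
label-independent data stays at chance. What they do not show: behavior
under real EEG nonstationarity, artifacts, volume conduction, or
spectral (rather than amplitude-order) class differences — white noise
plus sinusoids is not physiological EEG.

## Problem sizes and caps used by the shipped tests

The end-to-end tests run the study-shaped default (200 epochs × 1920
samples × 14 channels). The no-signal control uses the nested leak-free
mode with the NCA iteration cap lowered to 8: the control's conclusion is
independent of selection quality (any selection made without test labels
is unbiased), and the cap keeps the ten per-fold NCA fits inexpensive.
The subject-gap trend test uses a reduced 1-NN readout over ten seeds for
the same reason — it probes the generator, not the ensemble.

## Known limitations

- Diagonal NCA is non-convex; L-BFGS finds a local optimum. The fixed
  initialization makes it reproducible, not globally optimal.
- With the default (non-nested) order, reported CV accuracy on small
  datasets is optimistic; use `nested=True` when an unbiased estimate
  matters.
- The transition table depends on the symbol emission order within each
  feature triplet; comparisons across tools must fix the same convention.
- Binary labels are assumed by the generator and the geometric-mean
  metric's usual interpretation; the voting and metrics code itself is
  written for the general case but is only exercised on binary problems.
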