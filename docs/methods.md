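# Methods

This note documents the models and procedures `sposekit` implements, the
assumptions they make, the defaults and why, what the synthetic generators
do and do not emulate, and the numerical choices that matter.

## The choice model

Every object `i` is a non-negative vector `x_i ∈ R^d_{≥0}`. For a triplet
`{i, j, k}`, similarity of a pair is the dot product `s_ij = x_i · x_j`, and
the probability that the remaining object is picked as the odd-one-out is
the softmax over the three pair similarities (no temperature):

    P(k odd-one-out | i, j, k) = exp(s_ij) / (exp(s_ij) + exp(s_ik) + exp(s_jk))

The pair judged "most similar in this context" thus excludes the third
object. All downstream quantities — training loss, held-out accuracy,
choice-probability similarity matrices — derive from this one equation.
Softmax terms are computed after subtracting the per-triplet maximum score,
so probabilities are exact for any finite weights.

The model assumes the generative noise behind human odd-one-out choices is
exactly the softmax of dot products. Nothing in the estimation requires
that assumption to hold for real observers, but the synthetic choices are
self-consistent with it by construction, so simulated Bayes accuracies are
attainable bounds rather than conjectures.

## Embedding estimation (SPoSE)

Training minimizes the mean cross-entropy of the observed choices plus an
L1 penalty:

    L(X) = −(1/B) Σ log P(observed choice) + λ · ‖X‖₁ / n_objects

* **λ** (`TrainingConfig.lam`, default 0.00385): trade-off between fit and
  sparsity. The per-object normalization `‖X‖₁ / n_objects` keeps λ
  comparable across object-set sizes; the default is the cross-validated
  value established for the full-scale (1854-object, 4.1M-trial) setting
  and is a reasonable starting point, but `select_lambda` should be re-run
  for differently sized problems (desk-scale 50-object recovery selects
  λ ≈ 0.02).
* **Initialization**: `init_dims` = 90 dimensions uniform on [0, 1),
  seeded.
* **Optimizer**: minibatch Adam (batch 100, step 0.001, β = 0.9/0.999,
  ε = 1e−8) with projection to the non-negative orthant (clip at 0) after
  every update — the simplest projected-gradient scheme consistent with a
  sparse positive embedding. The L1 subgradient is λ/n_objects wherever a
  weight is positive; weights at zero are handled by the projection.
* **Stopping**: fixed `max_epochs` (default 500 for desk-scale data).
  Validation-loss early stopping is available (`early_stop_patience`) but
  off by default: the cross-entropy on held-out triplets flattens within a
  few dozen epochs while the L1 term is still shrinking redundant
  dimensions, so stopping on validation loss leaves the embedding
  under-sparsified (in the 50-object recovery experiment: 13 retained
  dimensions when stopped on validation loss with patience 10, versus the
  generating 5 when trained to 300+ epochs).
* **Pruning and ordering**: after training, any dimension whose weights are
  exclusively below 0.1 is removed, and the survivors are sorted by
  descending column sum.
* **Restart selection**: the optimization is stochastic, so the standard
  protocol fits many restarts (72 in the full-scale setting) and keeps the
  one whose dimensions are most reproducible: for each dimension, the best
  matching dimension (max Pearson r, matching with replacement) is found in
  every other restart, the correlations are Fisher-z transformed (clipped
  to ±(1−1e−7)), averaged, and back-transformed to r; an embedding's score
  is the mean over its dimensions. Back-transforming to r is a monotone
  (ranking-preserving) choice made for interpretability.

Two implementation backends exist for the inner minibatch loop: a
numba-JIT-compiled kernel (default when numba is importable) and a pure
NumPy reference; they agree to ~1e−15 per epoch and the test suite asserts
it. One numerical subtlety: the Adam moments of weights pinned at zero
decay geometrically and eventually become subnormal floats, which degrades
throughput by an order of magnitude; both backends flush moments below
1e−30 to zero, far beneath any meaningful moment magnitude.

Minibatches are reshuffled every epoch and the 90–10 train/test split is
uniform over trials (not stratified by pair); both choices are seeded.

## Noise ceilings

**Explainable-variance ceiling** (per measurement channel): with repeats of
the same images, noise variance is the mean over images of the unbiased
variance across repeats, and signal variance is the unbiased variance of
the image-wise mean responses. The ceiling after averaging n repeats is

    NC(n) = σ²_signal / (σ²_signal + σ²_noise / n)

The literal signal-variance recipe is upward-biased because the image means
still contain noise; `bias_correct=True` subtracts `σ²_noise / n_repeats`
(floored at 0). The default is the literal (uncorrected) form, matching the
common description; simulations in the tests quantify the bias. The pooled
noise variance is an unweighted mean over images, which is the pooled
estimator when every image has the same number of repeats (true by design
here).

**Choice-consistency ceiling**: for triplets judged repeatedly, the
consistency of one triplet is the modal choice's share of its repeats (in
percent), and the ceiling is the mean over triplets. Because it is always
based on the most consistent choice in the sample, this overestimates the
true ceiling slightly; no corrected estimator is implemented, and the
caveat string (`BEHAVIORAL_CEILING_CAVEAT`) travels with CLI output.
`expected_modal_fraction` provides the exact finite-sample expectation
under a known trinomial for validation.

## Dimensionality extrapolation

Mean retained dimensionality as a function of trial count x is fitted with
`a + b·e^(−c·x)` (c > 0) by nonlinear least squares from four starting
points (`a₀ ∈ {y_last, y_last + (y_last−y_first)/4}`, `b₀ = y_first − a₀`,
`c₀ ∈ {1/range, 5/range}`); the best residual sum of squares wins. The
asymptote is `a`. Uncertainty comes from a percentile bootstrap: each draw
resamples the replicate dimensionalities at every size with replacement,
takes their means, and refits (warm-started from the observed fit); the
95% CI is the (2.5, 97.5) percentile interval of the bootstrap asymptotes.
Failed refits are skipped with a logged count (an error if >10% fail)
rather than imputed, to avoid biasing the interval.

Known limitation: with only 4 replicates per size, resampling-with-
replacement understates the standard error of the per-size mean by a
factor √(3/4), so the percentile interval undercovers — measured ~89% at a
nominal 95% in the coverage simulation (100 synthetic curves, replicate
noise sd 2). This is intrinsic to the percentile-bootstrap-of-small-
replicate-sets design, not a fitting defect; a BCa or replicate-count-
corrected interval would mitigate it but is deliberately out of scope.

## Choice-probability similarity and RSA

The behavioral similarity of objects i and j is the probability that a
third object k is the odd-one-out of `{i, j, k}`, averaged over all k in a
context set (all objects by default, or e.g. one superordinate category).
Because the softmax renormalizes within each triplet, similarity is
context dependent: computing within a restricted context is *not* the same
as sub-setting the full-context matrix, and the tests assert this on a
fixture. The implementation vectorizes over k and is checked to 1e−10
against exhaustive triple enumeration for n ≤ 12.

Dissimilarity is `1 − similarity` (similarity is a probability), diagonal
stored as 1 (similarity) / 0 (dissimilarity) and excluded from all
statistics. RSA correlates strictly-lower-triangular parts (row-major
order, fixed so results are reproducible bit-for-bit) with Pearson's r.

Object-level bootstrap: rows sharing an underlying concept are resampled
as one unit; duplicated-copy pairs are retained except exact self-pairs
(same matrix row twice), whose dissimilarity is the undefined diagonal.
Draws with fewer than 3 distinct objects are redrawn. The multi-dataset
improvement test counts, per aligned bootstrap draw, how many datasets
improved; a draw is an improvement if and only if strictly more than half
did (ties are non-improvements), and the p-value is the fraction of
non-improvement draws.

## Time-resolved sensor-to-region regression (fusion)

For each region of interest and each timepoint, ordinary least squares
(with intercept — harmless when data are centered, necessary otherwise)
maps the trial-wise sensor pattern to the region's scalar response under
leave-one-session-out cross-validation; the per-fold statistic is the
Pearson correlation between predicted and true responses on the held-out
session. Folds with constant held-out truth give an undefined correlation,
recorded as missing and excluded from means and bootstraps (never
zero-filled). When a fold has fewer training rows than sensors the
minimum-norm least-squares solution is used with a warning. The fold-mean
series is smoothed with a centered moving average of 5 timepoints,
truncated at the edges (interior points are exact window means, asserted
in the tests).

The onset/offset of region information is the largest contiguous run of
timepoints whose smoothed correlation exceeds the maximum observed during
the pre-stimulus baseline (ties → earliest run; an empty window is a valid
result). Confidence bands resample fold-wise correlations with replacement
(folds are the exchangeable unit; values are sorted before resampling so
fold order cannot matter); region contrasts resample fold-paired
differences, significant where the 95% percentile interval excludes 0.

Known limitation: cross-validation folds share training data, so fold-wise
correlations are positively correlated (measured inter-fold r ≈ 0.07 under
a pure-noise null), and the independent-resampling bootstrap understates
the standard error of the fold mean. Under a null simulation the CI
excludes zero at ~20–25% of timepoints rather than 5%. The bands are
therefore descriptive rather than calibrated tests; the onset-ordering
conclusions validated in the experiments do not depend on this
calibration.

## Synthetic generators: what they emulate, and what they do not

All generators draw from `numpy.random.Generator` (PCG64); a fixed seed
plus `GENERATOR_VERSION` gives bit-identical output.

* `make_ground_truth_embedding`: entries are zero with probability
  `sparsity`, otherwise exponential with mean `scale` — right-skewed and
  non-negative, matching the qualitative shape of fitted sparse positive
  embedding weights.
* `sample_triplet_tasks(balanced=True)`: shuffled enumeration of all
  C(n, 3) triples with cyclic refill (reshuffled each pass); complete
  passes cover every pair exactly n−2 times, emulating the near-uniform
  pair coverage of the full-scale design.
* `simulate_choices`: the fitted choice model run forward; deterministic
  mode picks the argmax with lowest-object-index tie-breaking.
* `simulate_repeated_measures`: Gaussian signal-plus-noise,
  `response = μ_{channel,image} + ε_{repeat}`.
* `simulate_fusion_data`: one latent standard-normal feature per trial per
  region; sensors carry a fixed random unit-norm linear image of each
  region's feature scaled by `snr`, switched on only at timepoints at or
  after that region's onset, on top of unit-variance sensor noise; region
  responses are the feature plus Gaussian noise (`roi_noise_sd`). Sessions
  are contiguous near-equal trial blocks, mirroring session-blocked
  acquisition.

Not emulated (so passing tests say nothing about): participant
heterogeneity, response times, worker-exclusion screening, non-softmax
choice noise, temporally autocorrelated sensor noise, trial-order or
adaptation effects, and any acquisition-level artifact (motion, filtering,
hemodynamics). Conversion of real recordings into the fusion container is
a documented stub (`io.convert_neuro_recording`); the open trial-matching
and subject-averaging choices it describes are deliberately not decided
here.

## Study-scale-down problem sizes

The validation experiments run at sizes chosen to give clear recovery
signal on a single CPU within minutes, as the package's own test scale:

* Embedding recovery: 50 objects, 5 generating dimensions, sparsity 0.6,
  scale 1.5, 50,000 trials (90–10 split), λ by 2-fold CV on a coarse grid
  at a reduced epoch budget (the held-out ranking of λ stabilizes long
  before sparsification completes), then 10 restarts at 500 epochs. The
  generator scale 1.5 puts the Bayes accuracy near 66%, the regime human
  odd-one-out data occupy (model accuracy ~64%, consistency ceilings
  ~68–86%).
* Extrapolation: the 14 full-scale sizes (100k…1.4M) with 4 replicates of
  noise sd 2 around a true asymptote of 67.54; 100-curve coverage
  simulation with 300 bootstrap draws per curve.
* Fusion: 240 trials, 20 sensors, 6 sessions, onsets 100/180 ms,
  snr 0.7, 2000-draw fold bootstraps, 20 seeded repetitions.

The full-scale defaults remain in the API where the protocol fixes them
(72 restarts in the CLI trainer, 1000 extrapolation bootstraps, 100,000
within-category RSA bootstraps, 10,000 fusion bootstraps, 5-timepoint
smoothing).
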